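"""Hypergeometric over-representation testing with multiple-test correction."""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    universe_size: int      # N
    term_universe: int      # K: universe genes carrying the term
    study_size: int         # n
    term_study: int         # k: study genes carrying the term
    p: float
    q: float
    significant: bool


def read_annotation(path: str | Path) -> dict[str, set[str]]:
    """Gene -> GO term set from a TSV of (gene_id, pipe-separated term ids)."""
    annot: dict[str, set[str]] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            gene = row[0].strip()
            terms = {t for t in row[1].split("|") if t} if len(row) > 1 else set()
            annot.setdefault(gene, set()).update(terms)
    return annot


def upper_tail_p(universe_size: int, term_universe: int, study_size: int,
                 term_study: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n) — the per-term test statistic."""
    return float(hypergeom.sf(term_study - 1, universe_size, term_universe,
                              study_size))


def hypergeom_enrich(study: set[str], annot: dict[str, set[str]],
                     universe: set[str] | None = None, alpha: float = 0.05,
                     method: str = "fdr_bh") -> list[EnrichmentResult]:
    """Upper-tail hypergeometric test per term, BH-corrected, sorted by p.

    The universe defaults to all annotated genes. Terms absent from the study
    set are skipped (their upper-tail p from k=0 is 1 by definition).
    """
    if universe is None:
        universe = set(annot)
    offenders = study - universe
    if offenders:
        raise ValueError(f"study genes outside the universe: {sorted(offenders)}")
    big_n = len(universe)
    n = len(study)

    term_universe: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene in universe:
        for term in annot.get(gene, ()):
            term_universe[term] = term_universe.get(term, 0) + 1
            if gene in study:
                term_study[term] = term_study.get(term, 0) + 1

    tested = sorted(t for t, k in term_study.items() if k >= 1)
    if not tested:
        return []
    pvals = [upper_tail_p(big_n, term_universe[t], n, term_study[t])
             for t in tested]
    reject, qvals, _, _ = multipletests(pvals, alpha=alpha, method=method)

    results = [
        EnrichmentResult(term_id=t, universe_size=big_n,
                         term_universe=term_universe[t], study_size=n,
                         term_study=term_study[t], p=p, q=min(q, 1.0),
                         significant=bool(r))
        for t, p, q, r in zip(tested, pvals, qvals, reject)
    ]
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def write_results(results: list[EnrichmentResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("term_id\tN\tK\tn\tk\tp\tq\tsignificant\n")
        for r in results:
            fh.write(f"{r.term_id}\t{r.universe_size}\t{r.term_universe}\t"
                     f"{r.study_size}\t{r.term_study}\t{r.p:.6g}\t{r.q:.6g}\t"
                     f"{int(r.significant)}\n")
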