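"""Relative quantification by the comparative-Ct (2^-ddCt) method.

Technical replicates are averaged first; dCt = Ct_target - Ct_reference per
biological replicate; ddCt contrasts treatment against the control condition;
fold change = 2^-ddCt with a two-sample t-test on the replicate dCt values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ("gene", "genotype", "condition", "bio_replicate",
                    "tech_replicate", "ct")


@dataclass(frozen=True)
class FoldResult:
    gene: str
    genotype: str
    condition: str
    delta_ct_control: float
    delta_ct_treat: float
    fold: float
    p: float
    significant: bool


def _delta_ct(table: pd.DataFrame, gene: str, genotype: str, condition: str,
              reference_gene: str) -> np.ndarray:
    """Per-biological-replicate dCt values (tech replicates averaged first)."""
    sel = table[(table.genotype == genotype) & (table.condition == condition)]
    target = sel[sel.gene == gene].groupby("bio_replicate")["ct"].mean()
    ref = sel[sel.gene == reference_gene].groupby("bio_replicate")["ct"].mean()
    missing = target.index.difference(ref.index)
    if len(missing):
        raise ValueError(
            f"no reference-gene Ct for {gene}/{genotype}/{condition} "
            f"bio replicate(s) {list(missing)}")
    if len(target) < 2:
        raise ValueError(
            f"{gene}/{genotype}/{condition}: need >=2 biological replicates")
    return (target - ref.loc[target.index]).values


def ddct_fold(table: pd.DataFrame, reference_gene: str = "Actin",
              control_condition: str = "control_4h", alpha: float = 0.05,
              equal_var: bool = True) -> list[FoldResult]:
    """Fold changes and t-test p-values for every (gene, genotype, condition).

    The control condition anchors ddCt; conditions equal to the control are
    skipped. ``equal_var=False`` switches to Welch's t-test.
    """
    missing_cols = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing_cols:
        raise ValueError(f"Ct table missing columns: {sorted(missing_cols)}")
    if (table.ct <= 0).any():
        raise ValueError("Ct values must be positive")

    results = []
    genes = sorted(set(table.gene) - {reference_gene})
    for genotype in sorted(table.genotype.unique()):
        conditions = sorted(
            table[table.genotype == genotype].condition.unique())
        if control_condition not in conditions:
            raise ValueError(
                f"control condition {control_condition!r} absent for {genotype!r}")
        for gene in genes:
            sub = table[(table.genotype == genotype) & (table.gene == gene)]
            if sub.empty:
                continue
            dct_control = _delta_ct(table, gene, genotype, control_condition,
                                    reference_gene)
            for condition in conditions:
                if condition == control_condition:
                    continue
                dct_treat = _delta_ct(table, gene, genotype, condition,
                                      reference_gene)
                ddct = dct_treat.mean() - dct_control.mean()
                fold = float(2.0 ** (-ddct))
                if np.ptp(np.concatenate([dct_control, dct_treat])) == 0:
                    p = 1.0   # identical values: zero t statistic
                elif dct_control.var() == 0 and dct_treat.var() == 0:
                    p = 0.0   # zero within-group variance, distinct means
                else:
                    p = float(stats.ttest_ind(dct_treat, dct_control,
                                              equal_var=equal_var).pvalue)
                results.append(FoldResult(
                    gene=gene, genotype=genotype, condition=condition,
                    delta_ct_control=float(dct_control.mean()),
                    delta_ct_treat=float(dct_treat.mean()),
                    fold=fold, p=p, significant=p <= alpha))
    return results


def read_ct_tsv(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return table


def write_results(results: list[FoldResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tgenotype\tcondition\tdct_control\tdct_treat\tfold\tp\tstars\n")
        for r in results:
            stars = "*" if r.significant else ""
            fh.write(f"{r.gene}\t{r.genotype}\t{r.condition}\t"
                     f"{r.delta_ct_control:.4f}\t{r.delta_ct_treat:.4f}\t"
                     f"{r.fold:.4f}\t{r.p:.4g}\t{stars}\n")
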