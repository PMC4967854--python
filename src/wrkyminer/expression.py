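"""TMM normalization, FPKM computation and stage-preferential calling."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CountsMatrix:
    """Gene-by-sample raw counts with per-gene lengths.

    ``counts`` is a genes x samples DataFrame of non-negative integers;
    ``gene_lengths`` a Series aligned on the gene index, in bp.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.shape[1] < 2:
            raise ValueError("need at least two samples")
        lengths = self.gene_lengths.reindex(self.counts.index)
        if lengths.isna().any() or (lengths <= 0).any():
            raise ValueError("every gene needs a positive length")


@dataclass(frozen=True)
class NormalizationFactors:
    factors: pd.Series          # per-sample f_j, product 1
    reference: str
    m_trim: float = 0.30
    a_trim: float = 0.05


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
              m_trim: float, a_trim: float) -> float:
    """Trimmed, precision-weighted mean of M-values for one sample vs the reference."""
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        return 1.0
    p_obs = obs[keep] / lib_obs
    p_ref = ref[keep] / lib_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # precision (inverse asymptotic variance of M) weights
    w = (lib_obs - obs[keep]) / (lib_obs * obs[keep]) \
        + (lib_ref - ref[keep]) / (lib_ref * ref[keep])
    if np.allclose(m, m[0]):
        # all M equal (e.g. scalar-scaled libraries): factor is exactly 2^M
        return float(2.0 ** m[0])
    n = m.size
    m_lo, m_hi = np.floor(n * m_trim) + 1, n - np.floor(n * m_trim)
    a_lo, a_hi = np.floor(n * a_trim) + 1, n - np.floor(n * a_trim)
    m_rank = pd.Series(m).rank(method="first").values
    a_rank = pd.Series(a).rank(method="first").values
    keep2 = (m_rank >= m_lo) & (m_rank <= m_hi) & (a_rank >= a_lo) & (a_rank <= a_hi)
    if not keep2.any():
        return 1.0
    inv_w = 1.0 / w[keep2]
    return float(2.0 ** (np.sum(inv_w * m[keep2]) / np.sum(inv_w)))


def tmm_factors(cm: CountsMatrix, m_trim: float = 0.30,
                a_trim: float = 0.05) -> NormalizationFactors:
    """Trimmed-mean-of-M-values scaling factors, geometric-mean centred.

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the mean across samples. Genes with a zero count in either the
    sample or the reference are dropped pairwise; M values are double-trimmed
    (30% on M, 5% on A by default) and combined with precision weights.
    """
    counts = cm.counts
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        empty = list(lib.index[lib == 0])
        raise ValueError(f"samples with zero total counts: {empty}")
    q75 = counts.apply(lambda col: np.percentile(col[col > 0], 75)
                       if (col > 0).any() else 0.0) / lib
    reference = (q75 - q75.mean()).abs().idxmin()
    ref = counts[reference].values.astype(float)

    raw = {}
    for sample in counts.columns:
        if sample == reference:
            raw[sample] = 1.0
        else:
            raw[sample] = _tmm_pair(counts[sample].values.astype(float), ref,
                                    lib[sample], lib[reference], m_trim, a_trim)
    f = pd.Series(raw)[counts.columns]
    f = f / np.exp(np.log(f).mean())   # centre so the product is 1
    return NormalizationFactors(factors=f, reference=reference,
                                m_trim=m_trim, a_trim=a_trim)


def fpkm(cm: CountsMatrix, norm: NormalizationFactors | None = None) -> pd.DataFrame:
    """fpkm[g, j] = counts[g, j] * 1e9 / (length_bp[g] * libsize_j * f_j)."""
    lib = cm.counts.sum(axis=0).astype(float)
    f = norm.factors if norm is not None else pd.Series(1.0, index=cm.counts.columns)
    lengths = cm.gene_lengths.reindex(cm.counts.index).astype(float)
    denom = lengths.values[:, None] * (lib * f).values[None, :]
    return pd.DataFrame(cm.counts.values * 1e9 / denom,
                        index=cm.counts.index, columns=cm.counts.columns)


def preferential_stage(expr: pd.DataFrame) -> pd.Series:
    """Stage of maximum expression per gene; ties and all-zero rows unassigned.

    Returns a Series of stage labels with NaN for unassigned genes.
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least two stages")
    vals = expr.values
    out = []
    for row in vals:
        if np.all(row == 0):
            out.append(None)
            continue
        top = row.max()
        winners = np.flatnonzero(row == top)
        out.append(expr.columns[winners[0]] if winners.size == 1 else None)
    return pd.Series(out, index=expr.index, dtype=object)


def read_counts_tsv(path) -> CountsMatrix:
    """Counts TSV with a ``length`` column plus one column per sample."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "length" not in df.columns:
        raise ValueError("counts TSV must have a 'length' column")
    lengths = df["length"]
    counts = df.drop(columns=["length"])
    return CountsMatrix(counts=counts, gene_lengths=lengths)
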