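"""Strand-aware upstream-region extraction and IUPAC degenerate motif scanning."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .io_formats import (IUPAC_CODES, GeneModel, MotifDef, SequenceRecord,
                         reverse_complement)


@dataclass(frozen=True)
class PromoterSeq:
    gene_id: str
    seq: str                 # 5'->3' relative to the gene; may be empty
    requested_bp: int
    obtained_bp: int
    truncated: bool

    def __post_init__(self) -> None:
        if self.obtained_bp != len(self.seq) or self.obtained_bp > self.requested_bp:
            raise ValueError("inconsistent promoter length bookkeeping")


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    motif_name: str
    offset: int              # 0-based, forward strand of the promoter
    strand: str              # + | -
    matched_seq: str         # as read on the hit's strand


@dataclass
class MotifSummary:
    n_promoters: int
    n_genes_with: dict[str, int] = field(default_factory=dict)
    n_total_occurrences: dict[str, int] = field(default_factory=dict)
    per_gene_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    word_frequency: Counter = field(default_factory=Counter)


def extract_upstream(scaffold: SequenceRecord, gene: GeneModel,
                     length: int = 2000) -> PromoterSeq:
    """The up-to-``length`` bases upstream of a gene, 5'->3' on the gene strand.

    For '+' genes this is the window immediately before the gene start; for
    '-' genes the window immediately after the gene end, reverse-complemented.
    Truncation at scaffold edges is recorded rather than raised.
    """
    if gene.scaffold_id != scaffold.id:
        raise ValueError(
            f"gene {gene.gene_id!r} is on {gene.scaffold_id!r}, not {scaffold.id!r}")
    start1, end1 = gene.gene_span
    if gene.strand == "+":
        # promoter occupies [start1-length, start1-1] in 1-based terms
        lo = max(0, start1 - 1 - length)
        seq = scaffold.seq[lo:start1 - 1]
    else:
        seq = reverse_complement(scaffold.seq[end1:end1 + length])
    return PromoterSeq(gene_id=gene.gene_id, seq=seq, requested_bp=length,
                       obtained_bp=len(seq), truncated=len(seq) < length)


def _matches_at(seq: str, pos: int, pattern: str) -> bool:
    for j, code in enumerate(pattern):
        if seq[pos + j] not in IUPAC_CODES[code]:
            return False
    return True


def iupac_scan(seq: str, motif: MotifDef, gene_id: str = "",
               both_strands: bool = True) -> list[MotifHit]:
    """All (possibly overlapping) IUPAC pattern matches on one or both strands.

    An N in the sequence matches nothing. Minus-strand hits are reported at
    the forward-strand offset of the matched segment, with ``matched_seq``
    read on the minus strand.
    """
    hits: list[MotifHit] = []
    w = len(motif.pattern)
    rc_pattern = reverse_complement(motif.pattern)
    for i in range(len(seq) - w + 1):
        if _matches_at(seq, i, motif.pattern):
            hits.append(MotifHit(gene_id=gene_id, motif_name=motif.name,
                                 offset=i, strand="+",
                                 matched_seq=seq[i:i + w]))
        if both_strands and _matches_at(seq, i, rc_pattern):
            hits.append(MotifHit(gene_id=gene_id, motif_name=motif.name,
                                 offset=i, strand="-",
                                 matched_seq=reverse_complement(seq[i:i + w])))
    return hits


def scan_promoters(promoters: list[PromoterSeq], motifs: list[MotifDef],
                   both_strands: bool = True) -> list[MotifHit]:
    hits = []
    for p in promoters:
        if not p.seq:
            continue
        for m in motifs:
            hits.extend(iupac_scan(p.seq, m, gene_id=p.gene_id,
                                   both_strands=both_strands))
    return hits


def summarize_motifs(hits: list[MotifHit], n_promoters: int) -> MotifSummary:
    """Per-motif gene counts, occurrence totals and the word-frequency table."""
    summary = MotifSummary(n_promoters=n_promoters)
    for h in hits:
        summary.per_gene_counts.setdefault(h.motif_name, {})
        gcounts = summary.per_gene_counts[h.motif_name]
        gcounts[h.gene_id] = gcounts.get(h.gene_id, 0) + 1
        summary.word_frequency[h.matched_seq] += 1
    for name, gcounts in summary.per_gene_counts.items():
        summary.n_genes_with[name] = len(gcounts)
        summary.n_total_occurrences[name] = sum(gcounts.values())
        assert summary.n_total_occurrences[name] >= summary.n_genes_with[name]
        assert summary.n_genes_with[name] <= n_promoters
    return summary


def hits_to_bed(hits: list[MotifHit], pattern_widths: dict[str, int]) -> list[str]:
    """BED6 lines (0-based half-open, promoter-relative)."""
    lines = []
    for h in hits:
        w = pattern_widths[h.motif_name]
        lines.append(f"{h.gene_id}\t{h.offset}\t{h.offset + w}\t"
                     f"{h.motif_name}\t0\t{h.strand}")
    return lines
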