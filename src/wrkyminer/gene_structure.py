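"""Exon/intron statistics per gene model."""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import GeneModel


@dataclass(frozen=True)
class StructureStats:
    gene_id: str
    n_exons: int
    n_introns: int
    gene_length_bp: int
    mrna_length_bp: int
    max_exon_bp: int
    intron_lengths: tuple[int, ...]


def exon_intron_stats(gene: GeneModel,
                      exons: tuple[tuple[int, int], ...] | None = None) -> StructureStats:
    """Exon/intron statistics for one gene (longest-mRNA exon track by default).

    Intervals are 1-based inclusive; introns are the gaps between consecutive
    exons. Exon and intron lengths always sum to the exon-track span.
    """
    exons = exons if exons is not None else gene.exons
    if not exons:
        raise ValueError(f"gene {gene.gene_id!r} has no exons")
    prev_end = None
    introns = []
    for s, e in exons:
        if prev_end is not None:
            if s <= prev_end:
                raise ValueError(f"gene {gene.gene_id!r}: overlapping exons")
            introns.append(s - prev_end - 1)
        prev_end = e
    exon_lengths = [e - s + 1 for s, e in exons]
    span = exons[-1][1] - exons[0][0] + 1
    assert sum(exon_lengths) + sum(introns) == span
    return StructureStats(
        gene_id=gene.gene_id,
        n_exons=len(exons),
        n_introns=len(introns),
        gene_length_bp=gene.gene_span[1] - gene.gene_span[0] + 1,
        mrna_length_bp=sum(exon_lengths),
        max_exon_bp=max(exon_lengths),
        intron_lengths=tuple(introns),
    )


def structure_table(genes: list[GeneModel], per_mrna: bool = False) -> list[StructureStats]:
    """Stats for many genes; optionally one row per mRNA instead of per gene."""
    rows = []
    for g in genes:
        if per_mrna and g.mrna_exons:
            for mid in g.mrna_ids:
                stats = exon_intron_stats(g, g.mrna_exons[mid])
                rows.append(StructureStats(gene_id=mid, **{
                    f: getattr(stats, f) for f in
                    ("n_exons", "n_introns", "gene_length_bp", "mrna_length_bp",
                     "max_exon_bp", "intron_lengths")}))
        else:
            rows.append(exon_intron_stats(g))
    return rows
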