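"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of (seed, parameters) and returns both the
artifact and a ground-truth table, so every analysis stage can be tested
without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (IUPAC_CODES, GeneModel, MotifDef, SequenceRecord,
                         reverse_complement)

#: backbone alphabet excludes C and H so zinc fingers appear only where planted
BACKBONE_AA = "ADEFGIKLMNPQRSTVWY"
DNA = "ACGT"

CANONICAL_VARIANTS = ("WRKYGQK", "WRKYGKK")

#: relative offsets of coordinating residues inside a planted 60-residue domain
C2H2_LAYOUT = {20: "C", 25: "C", 48: "H", 50: "H"}
C2HC_LAYOUT = {20: "C", 28: "C", 52: "H", 54: "C"}

GROUP_GRAMMAR = {
    "Ia": (2, C2H2_LAYOUT), "Ib": (2, C2HC_LAYOUT),
    "II": (1, C2H2_LAYOUT), "III": (1, C2HC_LAYOUT),
    "IV": (1, None),
}


def _rand_aa(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BACKBONE_AA), size=n))


def _rand_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(DNA), size=n))


def _planted_domain(rng: np.random.Generator, width: int, layout: dict | None,
                    variant: str, mutation_rate: float) -> str:
    residues = list(_rand_aa(rng, width))
    residues[:7] = list(variant)
    anchors = set(range(7))
    if layout:
        for pos, aa in layout.items():
            residues[pos] = aa
            anchors.add(pos)
    if mutation_rate > 0:
        for i in range(width):
            if i not in anchors and rng.random() < mutation_rate:
                residues[i] = rng.choice(list(BACKBONE_AA))
    return "".join(residues)


def _contains_variant(seq: str, variants=CANONICAL_VARIANTS) -> bool:
    return any(v in seq for v in variants)


def simulate_family_proteome(seed: int, group_counts: dict[str, int],
                             mutation_rate: float = 0.05, decoys: int = 10,
                             width: int = 60,
                             ) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Proteome with planted family members per group grammar plus decoys.

    Members carry exact heptapeptide cores anchoring full domains with the
    group's zinc-finger layout; decoys carry only near-miss (one-substitution)
    7-mers in otherwise random backbones.
    """
    if not 0 <= mutation_rate < 1:
        raise ValueError("mutation rate must be in [0, 1)")
    unknown = set(group_counts) - set(GROUP_GRAMMAR)
    if unknown:
        raise ValueError(f"unknown groups: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    records, truth = [], []
    idx = 0
    for group in sorted(group_counts):
        n_domains, layout = GROUP_GRAMMAR[group]
        for _ in range(group_counts[group]):
            idx += 1
            pid = f"SYN{idx:05d}"
            variant = "WRKYGQK"
            parts = [_rand_aa(rng, int(rng.integers(20, 60)))]
            starts = []
            pos = len(parts[0])
            for _ in range(n_domains):
                dom = _planted_domain(rng, width, layout, variant, mutation_rate)
                starts.append(pos)
                parts.append(dom)
                linker = _rand_aa(rng, int(rng.integers(15, 40)))
                parts.append(linker)
                pos += width + len(linker)
            seq = "".join(parts)
            records.append(SequenceRecord(id=pid, seq=seq))
            truth.append({"protein_id": pid, "is_member": True, "group": group,
                          "n_domains": n_domains,
                          "domain_starts": ",".join(map(str, starts))})
    for _ in range(decoys):
        idx += 1
        pid = f"SYN{idx:05d}"
        while True:
            backbone = list(_rand_aa(rng, int(rng.integers(80, 200))))
            variant = CANONICAL_VARIANTS[int(rng.integers(len(CANONICAL_VARIANTS)))]
            near = list(variant)
            mpos = int(rng.integers(7))
            near[mpos] = rng.choice([a for a in BACKBONE_AA if a != variant[mpos]])
            if _contains_variant("".join(near)):
                continue
            at = int(rng.integers(0, len(backbone) - 7))
            backbone[at:at + 7] = near
            seq = "".join(backbone)
            if not _contains_variant(seq):
                break
        records.append(SequenceRecord(id=pid, seq=seq))
        truth.append({"protein_id": pid, "is_member": False, "group": "",
                      "n_domains": 0, "domain_starts": ""})
    for row in truth:
        if not row["is_member"]:
            assert not _contains_variant(
                next(r.seq for r in records if r.id == row["protein_id"]))
    return records, pd.DataFrame(truth)


@dataclass
class PlantedPromoter:
    gene_id: str
    strand: str
    #: motif name -> list of promoter-relative 0-based offsets (forward strand)
    planted: dict[str, list[int]] = field(default_factory=dict)
    promoter_bp: int = 2000


def simulate_genome_annotation(seed: int, n_genes: int = 6,
                               motifs: list[MotifDef] | None = None,
                               plants_per_gene: int = 3,
                               promoter_bp: int = 2000,
                               edge_cases: bool = True,
                               ) -> tuple[list[SequenceRecord], list[GeneModel],
                                          pd.DataFrame]:
    """Scaffolds + gene models with motif instances written into promoters.

    Genes alternate strands, each on its own scaffold. With ``edge_cases``,
    the last two genes are placed so that zero and ~half of the requested
    upstream length are available (scaffold-edge truncation).
    """
    if motifs is None:
        motifs = [MotifDef(name="WBOX", pattern="TTGAC")]
    if plants_per_gene < 0:
        raise ValueError("planted counts must be >= 0")
    rng = np.random.default_rng(seed)
    scaffolds, genes, truth = [], [], []
    for gi in range(n_genes):
        gene_id = f"g{gi + 1:03d}"
        scaf_id = f"scaf{gi + 1:03d}"
        strand = "+" if gi % 2 == 0 else "-"
        gene_len = int(rng.integers(900, 2000))
        avail = promoter_bp
        if edge_cases and gi == n_genes - 1:
            avail = 0
        elif edge_cases and gi == n_genes - 2:
            avail = promoter_bp // 2 + int(rng.integers(0, 200))
        pad = int(rng.integers(50, 300))   # non-promoter margin on the far side
        if strand == "+":
            scaf_seq = list(_rand_dna(rng, avail + gene_len + pad))
            gene_start = avail + 1
            gene_end = avail + gene_len
            prom_lo = 0                    # 0-based scaffold offset of promoter
        else:
            scaf_seq = list(_rand_dna(rng, pad + gene_len + avail))
            gene_start = pad + 1
            gene_end = pad + gene_len
            prom_lo = gene_end             # promoter occupies [gene_end, gene_end+avail)

        planted: dict[str, list[int]] = {}
        if avail >= 40 and plants_per_gene > 0:
            w_max = max(len(m.pattern) for m in motifs)
            slots = sorted(rng.choice(avail // (w_max + 2), size=min(
                plants_per_gene, avail // (w_max + 2)), replace=False))
            for k, slot in enumerate(slots):
                motif = motifs[int(rng.integers(len(motifs)))]
                inst = "".join(rng.choice(sorted(IUPAC_CODES[c]))
                               for c in motif.pattern)
                offset = slot * (w_max + 2)
                w = len(inst)
                if strand == "+":
                    lo = prom_lo + offset
                    scaf_seq[lo:lo + w] = list(inst)
                else:
                    lo = prom_lo + avail - offset - w
                    scaf_seq[lo:lo + w] = list(reverse_complement(inst))
                planted.setdefault(motif.name, []).append(offset)
                truth.append({"gene_id": gene_id, "motif": motif.name,
                              "offset": offset, "instance": inst,
                              "strand": strand})
        scaffolds.append(SequenceRecord(id=scaf_id, seq="".join(scaf_seq),
                                        alphabet="dna"))
        n_exons = int(rng.integers(1, 4))
        bounds = sorted(rng.choice(np.arange(1, gene_len - 1), size=2 * (n_exons - 1),
                                   replace=False)) if n_exons > 1 else []
        cuts = [0] + [int(b) for b in bounds] + [gene_len - 1]
        exons = tuple((gene_start + cuts[2 * i], gene_start + cuts[2 * i + 1])
                      for i in range(n_exons))
        mid = f"{gene_id}.t1"
        genes.append(GeneModel(gene_id=gene_id, scaffold_id=scaf_id,
                               strand=strand, gene_span=(gene_start, gene_end),
                               exons=exons, mrna_ids=(mid,),
                               mrna_exons={mid: exons}))
    return scaffolds, genes, pd.DataFrame(
        truth, columns=["gene_id", "motif", "offset", "instance", "strand"])


def simulate_expression(seed: int, n_genes: int = 200,
                        stages: tuple[str, ...] = ("leaf", "root", "bark",
                                                   "male_flower", "winter_bud"),
                        preferential_fraction: float = 0.2, fold: float = 8.0,
                        dispersion: float = 0.05,
                        ) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Negative-binomial counts with planted stage-preferential genes.

    Returns (counts genes x stages, gene lengths, truth table).
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if fold < 1:
        raise ValueError("preferential fold must be >= 1")
    rng = np.random.default_rng(seed)
    gene_ids = [f"gene{i + 1:05d}" for i in range(n_genes)]
    lengths = pd.Series(rng.integers(500, 3001, size=n_genes), index=gene_ids,
                        name="length")
    base = rng.uniform(50, 500, size=n_genes)
    n_pref = int(round(preferential_fraction * n_genes))
    pref_idx = rng.choice(n_genes, size=n_pref, replace=False)
    pref_stage = rng.integers(len(stages), size=n_pref)

    mean = np.tile(base[:, None], (1, len(stages)))
    for gi, si in zip(pref_idx, pref_stage):
        mean[gi, si] *= fold
    # counts scale with gene length (reads per transcript kb)
    mean = mean * lengths.values[:, None] / 1000.0
    if dispersion > 0:
        shape = 1.0 / dispersion
        p = shape / (shape + mean)
        counts = rng.negative_binomial(shape, p)
    else:
        counts = rng.poisson(mean)
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=list(stages))
    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "preferential": [i in set(pref_idx) for i in range(n_genes)],
        "stage": [""] * n_genes,
    }).set_index("gene_id")
    for gi, si in zip(pref_idx, pref_stage):
        truth.iloc[gi, truth.columns.get_loc("stage")] = stages[si]
    return counts_df, lengths, truth


def simulate_qpcr(seed: int, planted_folds: dict[str, dict[str, float]],
                  genotype: str = "MI", control_condition: str = "control_4h",
                  ct_noise_sd: float = 0.1, n_bio: int = 2, n_tech: int = 3,
                  reference_gene: str = "Actin",
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ct table with planted fold changes: ``{gene: {condition: fold}}``.

    The reference gene sits at a constant Ct; treated targets shift their Ct
    by -log2(fold). Noise of the given sd applies per technical measurement.
    """
    if ct_noise_sd < 0:
        raise ValueError("ct noise sd must be >= 0")
    if n_bio < 2:
        raise ValueError("need >= 2 biological replicates")
    rng = np.random.default_rng(seed)
    rows, truth = [], []
    conditions = sorted({c for folds in planted_folds.values() for c in folds})
    ref_ct, base_ct = 20.0, 25.0
    for condition in [control_condition] + conditions:
        for bio in range(1, n_bio + 1):
            for tech in range(1, n_tech + 1):
                rows.append({"gene": reference_gene, "genotype": genotype,
                             "condition": condition, "bio_replicate": bio,
                             "tech_replicate": tech,
                             "ct": ref_ct + rng.normal(0, ct_noise_sd)})
    for gene in sorted(planted_folds):
        for condition in [control_condition] + conditions:
            fold = planted_folds[gene].get(condition, 1.0)
            true_ct = base_ct if condition == control_condition \
                else base_ct - np.log2(fold)
            for bio in range(1, n_bio + 1):
                for tech in range(1, n_tech + 1):
                    rows.append({"gene": gene, "genotype": genotype,
                                 "condition": condition, "bio_replicate": bio,
                                 "tech_replicate": tech,
                                 "ct": true_ct + rng.normal(0, ct_noise_sd)})
            if condition != control_condition:
                truth.append({"gene": gene, "condition": condition,
                              "fold": fold})
    table = pd.DataFrame(rows)
    table["ct"] = table["ct"].round(4)
    return table, pd.DataFrame(truth, columns=["gene", "condition", "fold"])
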