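"""End-to-end orchestration with a validated config and a run manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import classify as _classify
from . import domain_scan, enrichment, expression, gene_structure
from . import phylo, promoter_scan, protein_props, qpcr
from .io_formats import (default_motif_library, read_fasta, read_gff3,
                         read_motif_library)

STAGES = ("identify", "classify", "tree", "props", "structure", "promoters",
          "enrich", "express", "qpcr")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 1
    stages: tuple[str, ...] = STAGES
    inputs: dict[str, str] = field(default_factory=dict)
    params: dict[str, dict] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(out_dir=Path(raw.get("out_dir", "miner_out")),
                  seed=int(raw.get("seed", 1)),
                  stages=tuple(raw.get("stages", STAGES)),
                  inputs={k: str(v) for k, v in (raw.get("inputs") or {}).items()},
                  params=raw.get("params") or {})
        cfg.validate()
        return cfg

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        required = {"identify": ["proteome"], "classify": ["proteome"],
                    "tree": ["proteome"], "props": ["proteome"],
                    "structure": ["gff"], "promoters": ["genome", "gff"],
                    "enrich": ["annotation"], "express": ["counts"],
                    "qpcr": ["ct_table"]}
        for stage in self.stages:
            for key in required.get(stage, []):
                if key not in self.inputs:
                    raise ConfigError(f"stage {stage!r} needs input {key!r}")
                if not Path(self.inputs[key]).exists():
                    raise ConfigError(
                        f"input {key!r}: no such file {self.inputs[key]!r}")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages in dependency order; write a manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": cfg.seed,
        "stages": list(cfg.stages),
        "params": cfg.params,
        "inputs": {k: {"path": v, "sha256": _sha256(v)}
                   for k, v in cfg.inputs.items()},
        "outputs": {},
    }

    family = None
    proteome = None
    current = "(validation)"
    try:
        if {"identify", "classify", "tree", "props"} & set(cfg.stages):
            proteome = read_fasta(cfg.inputs["proteome"], alphabet="protein")

        if "identify" in cfg.stages:
            current = "identify"
            p = cfg.params.get("identify", {})
            params = domain_scan.SearchParams(
                variants=tuple(p.get("variants", domain_scan.DEFAULT_VARIANTS)),
                width=int(p.get("width", 60)),
                pseudocount=float(p.get("alpha", 0.5)),
                margin_bits=float(p.get("margin_bits", 8.0)))
            family = domain_scan.iterative_search(proteome, params)
            path = out / "members.tsv"
            with open(path, "w") as fh:
                fh.write("protein_id\tdomain_start\tdomain_end\tbit_score\tvariant\n")
                for mid in sorted(family.members):
                    for h in family.hits[mid]:
                        fh.write(f"{mid}\t{h.start}\t{h.end}\t{h.bit_score:.3f}\t"
                                 f"{h.core.variant if h.core else ''}\n")
            manifest["outputs"]["members"] = str(path)

        if "classify" in cfg.stages:
            current = "classify"
            if family is None:
                raise ConfigError("classify requires the identify stage")
            labels = _classify.classify_family(proteome, family)
            by_id = {r.id: r for r in proteome}
            path = out / "groups.tsv"
            with open(path, "w") as fh:
                fh.write("protein_id\tgroup\tbasis\tsignature_positions\n")
                for mid, label in sorted(labels.items()):
                    sig = _classify.detect_signature(by_id[mid].seq)
                    fh.write(f"{mid}\t{label.group}\t{label.basis}\t"
                             f"{','.join(map(str, sig))}\n")
            manifest["outputs"]["groups"] = str(path)

        if "tree" in cfg.stages:
            current = "tree"
            if family is None or not family.members:
                raise ConfigError("tree requires identified members")
            p = cfg.params.get("tree", {})
            domains = {}
            for mid in sorted(family.members):
                hits = family.hits[mid]
                if hits:
                    rec = next(r for r in proteome if r.id == mid)
                    h = hits[0]
                    domains[mid] = rec.seq[h.start:h.end]
            if len(domains) >= 3:
                aligned = domains  # fixed-width anchored windows are aligned
                tree = phylo.bootstrap_support(
                    aligned, replicates=int(p.get("bootstrap", 1000)),
                    seed=cfg.seed)
                path = out / "tree.nwk"
                path.write_text(phylo.to_newick(tree) + "\n")
                manifest["outputs"]["tree"] = str(path)

        if "props" in cfg.stages:
            current = "props"
            scope = sorted(family.members) if family else [r.id for r in proteome]
            by_id = {r.id: r for r in proteome}
            path = out / "protein_props.tsv"
            with open(path, "w") as fh:
                fh.write("protein_id\tlength\tmw_da\tpi\n")
                for pid in scope:
                    pp = protein_props.protein_properties(pid, by_id[pid].seq,
                                                          allow_x=True)
                    fh.write(f"{pid}\t{pp.length}\t{pp.mw_da:.2f}\t{pp.pi:.2f}\n")
            manifest["outputs"]["props"] = str(path)

        genes = None
        if {"structure", "promoters"} & set(cfg.stages):
            genes = read_gff3(cfg.inputs["gff"])

        if "structure" in cfg.stages:
            current = "structure"
            stats = gene_structure.structure_table(genes)
            path = out / "gene_structure.tsv"
            with open(path, "w") as fh:
                fh.write("gene_id\tn_exons\tn_introns\tgene_length_bp\t"
                         "mrna_length_bp\tmax_exon_bp\tintron_lengths\n")
                for s in stats:
                    fh.write(f"{s.gene_id}\t{s.n_exons}\t{s.n_introns}\t"
                             f"{s.gene_length_bp}\t{s.mrna_length_bp}\t"
                             f"{s.max_exon_bp}\t"
                             f"{','.join(map(str, s.intron_lengths))}\n")
            manifest["outputs"]["structure"] = str(path)

        if "promoters" in cfg.stages:
            current = "promoters"
            p = cfg.params.get("promoters", {})
            length = int(p.get("length", 2000))
            scaffolds = {r.id: r for r in read_fasta(cfg.inputs["genome"],
                                                     alphabet="dna")}
            motifs = (read_motif_library(cfg.inputs["motifs"])
                      if "motifs" in cfg.inputs else default_motif_library())
            promoters = []
            for g in genes:
                if g.scaffold_id not in scaffolds:
                    raise ConfigError(f"gene {g.gene_id}: scaffold "
                                      f"{g.scaffold_id!r} not in genome FASTA")
                promoters.append(promoter_scan.extract_upstream(
                    scaffolds[g.scaffold_id], g, length))
            hits = promoter_scan.scan_promoters(promoters, motifs)
            summary = promoter_scan.summarize_motifs(
                hits, n_promoters=sum(1 for p_ in promoters if p_.obtained_bp))
            widths = {m.name: len(m.pattern) for m in motifs}
            (out / "motif_hits.bed").write_text(
                "\n".join(promoter_scan.hits_to_bed(hits, widths)) + "\n")
            with open(out / "motif_summary.tsv", "w") as fh:
                fh.write("motif\tn_genes_with\tn_total_occurrences\n")
                for name in sorted(widths):
                    fh.write(f"{name}\t{summary.n_genes_with.get(name, 0)}\t"
                             f"{summary.n_total_occurrences.get(name, 0)}\n")
            with open(out / "word_frequency.tsv", "w") as fh:
                fh.write("word\tcount\n")
                for word, count in summary.word_frequency.most_common():
                    fh.write(f"{word}\t{count}\n")
            manifest["outputs"]["promoters"] = str(out / "motif_summary.tsv")

        if "enrich" in cfg.stages:
            current = "enrich"
            annot = enrichment.read_annotation(cfg.inputs["annotation"])
            study_path = cfg.inputs.get("study_set")
            if study_path:
                study = {line.strip() for line in open(study_path)
                         if line.strip()}
            elif family:
                study = set(family.members)
            else:
                raise ConfigError("enrich needs a study_set input or identify stage")
            results = enrichment.hypergeom_enrich(study & set(annot), annot)
            enrichment.write_results(results, out / "enrichment.tsv")
            manifest["outputs"]["enrichment"] = str(out / "enrichment.tsv")

        if "express" in cfg.stages:
            current = "express"
            cm = expression.read_counts_tsv(cfg.inputs["counts"])
            norm = expression.tmm_factors(cm)
            mat = expression.fpkm(cm, norm)
            mat.round(4).to_csv(out / "fpkm.tsv", sep="\t")
            pref = expression.preferential_stage(mat)
            pref.to_csv(out / "preferential_stage.tsv", sep="\t",
                        header=["stage"])
            manifest["outputs"]["expression"] = str(out / "fpkm.tsv")

        if "qpcr" in cfg.stages:
            current = "qpcr"
            p = cfg.params.get("qpcr", {})
            table = qpcr.read_ct_tsv(cfg.inputs["ct_table"])
            results = qpcr.ddct_fold(
                table, reference_gene=p.get("reference_gene", "Actin"),
                control_condition=p.get("control_condition", "control_4h"))
            qpcr.write_results(results, out / "qpcr_folds.tsv")
            manifest["outputs"]["qpcr"] = str(out / "qpcr_folds.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage {current!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
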