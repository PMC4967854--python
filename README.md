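# wrkyminer

A toolkit for genome-wide identification, classification and characterization
of WRKY-type transcription-factor gene families:

- **domain mining** — heptapeptide-core seeding (`WRKYGQK`/`WRKYGKK`),
  anchored position-specific log-odds (PSSM) scoring, and an iterative
  build-profile / rescan-proteome loop that runs to a fixpoint;
- **classification** — zinc-finger typing (C2H2 / C2HC) and architecture-based
  group assignment (Ia/Ib, II, III, IV), plus the Group-Ia signature motif;
- **phylogeny** — BLOSUM62 pairwise p-distances, an in-house neighbor-joining
  implementation with deterministic tie-breaking, bootstrap supports, and
  clade-based Group-II subgroup assignment;
- **gene/protein descriptors** — exon/intron statistics from GFF3, average
  molecular weight and isoelectric point;
- **promoters** — strand-aware 2-kb upstream extraction from scaffolds and
  IUPAC degenerate cis-element scanning (bundled 14-motif PLACE-style library);
- **enrichment** — hypergeometric GO over-representation with
  Benjamini–Hochberg correction;
- **expression** — TMM normalization (verified against edgeR), FPKM, and
  stage-preferential calling;
- **qPCR** — 2^−ΔΔCt relative quantification with Student's t-test;
- **synthetic data** — seeded generators for every input (proteome, genome +
  GFF3, counts matrix, Ct table) with ground-truth sidecars.

## CLI

The `miner` entry point mirrors the library modules:

```sh
miner simulate proteome --seed 1 --out synthetic/
miner identify --proteome synthetic/proteome.fasta --out members.tsv
miner tree --proteome synthetic/proteome.fasta -B 1000 --seed 7 --out tree.nwk
miner promoters --genome scaffolds.fasta --gff genes.gff3 -L 2000
miner express --counts counts.tsv --out-dir out/
miner qpcr --table ct.tsv --ref Actin --control control_4h
miner run --config pipeline.yaml       # all stages + run manifest
```

`miner run` consumes a YAML config:

```yaml
out_dir: out
seed: 1
stages: [identify, classify, tree, props, structure, promoters, enrich, express, qpcr]
inputs:
  proteome: proteome.fasta
  genome: scaffolds.fasta
  gff: genes.gff3
  counts: counts.tsv
  ct_table: ct.tsv
  annotation: annot.tsv
params:
  identify: {width: 60, alpha: 0.5}
  tree: {bootstrap: 1000}
```

Exit codes: 0 ok, 1 user/input error, 2 internal error. A `manifest.json`
records the seed, parameters and input checksums; reruns with the same config
are byte-identical.

## Tests

```sh
python -m pytest tests/
```

The suite includes property tests (hypothesis) and independent oracles
(brute-force window scoring, exhaustive hypergeometric enumeration,
exhaustive quartet-topology fits, a frozen edgeR TMM reference) plus
`tests/test_acceptance.py`, one test per desk-scale acceptance criterion.

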