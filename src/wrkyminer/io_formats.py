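"""Readers and writers for the plain-text formats the toolkit consumes.

Coordinate convention: external files keep their native conventions (GFF3 is
1-based inclusive, emitted BED is 0-based half-open); all internal arithmetic
uses 0-based half-open intervals, converted exactly once at the boundary.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
DNA_ALPHABET = set("ACGTN")

#: IUPAC nucleotide code -> set of concrete bases it matches.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    seq: str
    description: str = ""
    alphabet: str = "protein"

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.seq:
            raise FormatError(f"sequence record {self.id!r} has empty sequence")
        alpha = PROTEIN_ALPHABET if self.alphabet == "protein" else DNA_ALPHABET
        bad = set(self.seq) - alpha
        if bad:
            raise FormatError(
                f"record {self.id!r}: illegal {self.alphabet} residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneModel:
    """A gene with its exon structure in scaffold coordinates.

    ``gene_span`` and ``exons`` are 1-based inclusive intervals as read from
    GFF3.  Exons are stored in ascending scaffold order regardless of strand.
    """

    gene_id: str
    scaffold_id: str
    strand: str
    gene_span: tuple[int, int]
    exons: tuple[tuple[int, int], ...]
    mrna_ids: tuple[str, ...] = ()
    #: exons per mRNA, same convention; populated when mRNAs are present.
    mrna_exons: dict[str, tuple[tuple[int, int], ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        prev_end = 0
        for s, e in self.exons:
            if e < s:
                raise FormatError(f"gene {self.gene_id!r}: exon end {e} < start {s}")
            if s <= prev_end:
                raise FormatError(f"gene {self.gene_id!r}: exons overlap or unsorted")
            prev_end = e


@dataclass(frozen=True)
class MotifDef:
    name: str
    pattern: str
    description: str = ""

    def __post_init__(self) -> None:
        bad = set(self.pattern) - set(IUPAC_CODES)
        if bad:
            raise FormatError(
                f"motif {self.name!r}: non-IUPAC characters {sorted(bad)} in pattern"
            )
        if len(self.pattern) < 4:
            raise FormatError(f"motif {self.name!r}: pattern shorter than 4 bases")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA/IUPAC string."""
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path, alphabet: str = "protein") -> list[SequenceRecord]:
    """Read a FASTA file into validated records.

    Sequences are uppercased; wrapped lines are joined; record order is
    preserved. Duplicate ids and empty files are format errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(
            SequenceRecord(id=rec.id, seq=str(rec.seq).upper(),
                           description=desc, alphabet=alphabet)
        )
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise FormatError(f"malformed GFF3 attribute {chunk!r}")
        key, value = chunk.split("=", 1)
        attrs[key] = value
    return attrs


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse canonical GFF3 gene/mRNA/exon features into gene models.

    Requires ``ID`` on gene and mRNA features and ``Parent`` on mRNA and exon
    features.  Exons are grouped under genes via their parent mRNAs and stored
    sorted in ascending scaffold coordinates.
    """
    genes: dict[str, dict] = {}
    mrna_to_gene: dict[str, str] = {}
    mrna_exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns")
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = fields
            start, end = int(start_s), int(end_s)
            if end < start:
                raise FormatError(f"{path}:{lineno}: end {end} < start {start}")
            attrs = _parse_gff_attributes(attr_s)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise FormatError(f"{path}:{lineno}: gene feature without ID")
                genes[gid] = {"scaffold": seqid, "strand": strand,
                              "span": (start, end), "mrnas": []}
                order.append(gid)
            elif ftype == "mRNA":
                mid, parent = attrs.get("ID"), attrs.get("Parent")
                if mid is None or parent is None:
                    raise FormatError(f"{path}:{lineno}: mRNA needs ID and Parent")
                if parent not in genes:
                    raise FormatError(
                        f"{path}:{lineno}: mRNA {mid!r} references unknown gene {parent!r}")
                mrna_to_gene[mid] = parent
                genes[parent]["mrnas"].append(mid)
                mrna_exons[mid] = []
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None:
                    raise FormatError(f"{path}:{lineno}: exon without Parent")
                for pid in parent.split(","):
                    if pid not in mrna_exons:
                        raise FormatError(
                            f"{path}:{lineno}: exon references unknown mRNA {pid!r}")
                    mrna_exons[pid].append((start, end))

    models: list[GeneModel] = []
    for gid in order:
        info = genes[gid]
        per_mrna = {mid: tuple(sorted(mrna_exons[mid])) for mid in info["mrnas"]}
        merged = sorted({iv for exons in per_mrna.values() for iv in exons})
        # gene-level exon track: the longest mRNA's exons (paper-style single
        # structure per gene); falls back to the union for mRNA-less genes.
        if per_mrna:
            longest = max(per_mrna, key=lambda m: sum(e - s + 1 for s, e in per_mrna[m]))
            gene_exons = per_mrna[longest]
        else:
            gene_exons = tuple(merged)
        models.append(GeneModel(
            gene_id=gid, scaffold_id=info["scaffold"], strand=info["strand"],
            gene_span=info["span"], exons=gene_exons,
            mrna_ids=tuple(info["mrnas"]), mrna_exons=per_mrna,
        ))
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            s, e = g.gene_span
            fh.write(f"{g.scaffold_id}\tminer\tgene\t{s}\t{e}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id}\n")
            mrnas = g.mrna_ids or (f"{g.gene_id}.t1",)
            for mid in mrnas:
                fh.write(f"{g.scaffold_id}\tminer\tmRNA\t{s}\t{e}\t.\t{g.strand}\t.\t"
                         f"ID={mid};Parent={g.gene_id}\n")
                exons = g.mrna_exons.get(mid, g.exons)
                for xs, xe in exons:
                    fh.write(f"{g.scaffold_id}\tminer\texon\t{xs}\t{xe}\t.\t"
                             f"{g.strand}\t.\tParent={mid}\n")


def read_motif_library(path: str | Path) -> list[MotifDef]:
    """Read a PLACE-style motif library: TSV of name, IUPAC pattern[, description]."""
    motifs: list[MotifDef] = []
    seen: set[str] = set()
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise FormatError(f"motif row needs >=2 columns: {row!r}")
            name, pattern = row[0].strip(), row[1].strip().upper()
            if name in seen:
                raise FormatError(f"duplicate motif name {name!r}")
            seen.add(name)
            desc = row[2].strip() if len(row) > 2 else ""
            motifs.append(MotifDef(name=name, pattern=pattern, description=desc))
    if not motifs:
        raise FormatError(f"no motifs found in {path}")
    return motifs


def default_motif_library() -> list[MotifDef]:
    """The bundled 14-motif cis-element library."""
    return read_motif_library(Path(__file__).parent / "data" / "place_motifs.tsv")
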