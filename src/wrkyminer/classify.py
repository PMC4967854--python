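"""Architecture-based group assignment and the conserved signature motif.

Group system: two domains with two C2H2 fingers -> Ia; two domains with two
C2HC fingers -> Ib; one domain with C2H2 -> II (subgroup resolved later from
clade evidence); one domain with C2HC -> III; domains with no finger at all
-> IV; anything else -> unresolved.
"""

from __future__ import annotations

from dataclasses import dataclass

from .domain_scan import (DEFAULT_ZF_PATTERNS, FamilySet, ZincFingerHit,
                          detect_zinc_finger)
from .io_formats import SequenceRecord

DEFAULT_SIGNATURE = "GGDFDDNEPEAKRWKGE"


@dataclass(frozen=True)
class Architecture:
    protein_id: str
    n_domains: int
    zf_types: tuple[str, ...]
    signature_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.zf_types) != self.n_domains:
            raise ValueError("one zinc-finger call required per domain")


@dataclass(frozen=True)
class GroupLabel:
    group: str   # Ia | Ib | IIa..IIe | II | III | IV | unresolved
    basis: str   # architecture | clade | mixed


def assign_group(arch: Architecture) -> GroupLabel:
    """Map a domain/zinc-finger architecture to its family group."""
    if arch.n_domains == 0:
        raise ValueError(f"{arch.protein_id}: no domains — not a family member")
    zf = arch.zf_types
    if all(t == "none" for t in zf):
        return GroupLabel(group="IV", basis="architecture")
    if arch.n_domains == 2:
        if zf == ("C2H2", "C2H2"):
            return GroupLabel(group="Ia", basis="architecture")
        if zf == ("C2HC", "C2HC"):
            return GroupLabel(group="Ib", basis="architecture")
        return GroupLabel(group="unresolved", basis="architecture")
    if arch.n_domains == 1:
        if zf == ("C2H2",):
            return GroupLabel(group="II", basis="architecture")
        if zf == ("C2HC",):
            return GroupLabel(group="III", basis="architecture")
    return GroupLabel(group="unresolved", basis="architecture")


def detect_signature(seq: str, motif: str = DEFAULT_SIGNATURE,
                     max_mismatch: int = 0) -> list[int]:
    """Offsets of all motif occurrences with at most ``max_mismatch`` substitutions."""
    if not motif:
        raise ValueError("signature motif must be non-empty")
    if max_mismatch >= len(motif):
        raise ValueError("max_mismatch must be smaller than the motif length")
    hits = []
    for i in range(len(seq) - len(motif) + 1):
        window = seq[i:i + len(motif)]
        if sum(a != b for a, b in zip(window, motif)) <= max_mismatch:
            hits.append(i)
    return hits


def build_architecture(record: SequenceRecord, family: FamilySet,
                       zf_window: int = 80,
                       zf_patterns=DEFAULT_ZF_PATTERNS,
                       signature: str = DEFAULT_SIGNATURE) -> Architecture:
    """Assemble the architecture of one family member from its domain hits.

    The zinc finger for each domain is searched downstream of that domain's
    heptapeptide anchor, within ``zf_window`` residues.
    """
    hits = family.hits.get(record.id, [])
    zf_types = []
    for hit in hits:
        anchor = hit.core.start if hit.core is not None else hit.start
        zf: ZincFingerHit = detect_zinc_finger(record.seq, search_start=anchor,
                                               window=zf_window,
                                               patterns=zf_patterns,
                                               protein_id=record.id)
        zf_types.append(zf.zf_type)
    return Architecture(
        protein_id=record.id, n_domains=len(hits), zf_types=tuple(zf_types),
        signature_positions=tuple(detect_signature(record.seq, signature)),
    )


def classify_family(proteome: list[SequenceRecord], family: FamilySet,
                    **kwargs) -> dict[str, GroupLabel]:
    """Group label for every family member."""
    by_id = {rec.id: rec for rec in proteome}
    labels = {}
    for mid in sorted(family.members):
        arch = build_architecture(by_id[mid], family, **kwargs)
        labels[mid] = assign_group(arch)
    return labels
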