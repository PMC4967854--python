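"""Profile-based WRKY domain mining.

Detects heptapeptide cores, scores fixed-width candidate domains with a
position-specific log-odds matrix (PSSM) anchored at the core, types the
downstream zinc finger, and iterates profile building and proteome rescanning
until the member set reaches a fixpoint.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

from .io_formats import SequenceRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
DEFAULT_VARIANTS = ("WRKYGQK", "WRKYGKK")

#: zinc-finger spacing grammars: (type, regex). C2H2 is tried before C2HC.
DEFAULT_ZF_PATTERNS: tuple[tuple[str, str], ...] = (
    ("C2H2", r"C.{4,5}C.{22,23}H.H"),
    ("C2HC", r"C.{5,8}C.{22,28}H.{1,2}C"),
)


@dataclass(frozen=True)
class CoreHit:
    """An exact (or admitted near-exact) heptapeptide occurrence."""

    protein_id: str
    start: int          # 0-based offset in the protein
    variant: str        # the matched 7-mer as observed

    def __post_init__(self) -> None:
        if len(self.variant) != 7:
            raise ValueError("heptapeptide variant must be 7 residues")


@dataclass(frozen=True)
class ProfileMatrix:
    """Ungapped position-specific log-odds matrix (bits).

    ``scores[col][r] = log2(((count + alpha*bg_r) / (N + alpha)) / bg_r)``
    where ``count`` is the residue count in the column, ``N`` the number of
    training sequences and ``bg_r`` the background frequency of ``r``.
    """

    width: int
    scores: tuple[dict[str, float], ...]
    background: dict[str, float]
    pseudocount: float

    def score_window(self, window: str) -> float:
        """Total bit score of one window; residue X contributes 0 per column."""
        total = 0.0
        for col, res in zip(self.scores, window):
            total += col.get(res, 0.0)
        return total


@dataclass(frozen=True)
class DomainHit:
    protein_id: str
    start: int          # 0-based half-open window on the protein
    end: int
    bit_score: float
    core: CoreHit | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.bit_score):
            raise ValueError("bit_score must be finite")


@dataclass(frozen=True)
class ZincFingerHit:
    protein_id: str
    zf_type: str                                # C2H2 | C2HC | none
    residue_positions: tuple[int, ...] = ()     # 4 coordinating offsets


@dataclass
class FamilySet:
    """Result of the iterative search: members with their evidence."""

    members: set[str] = field(default_factory=set)
    hits: dict[str, list[DomainHit]] = field(default_factory=dict)
    rounds: int = 0
    threshold: float = 0.0
    profile: ProfileMatrix | None = None


def uniform_background() -> dict[str, float]:
    return {aa: 1.0 / len(AMINO_ACIDS) for aa in AMINO_ACIDS}


def find_heptapeptide(seq: str, variants=DEFAULT_VARIANTS,
                      protein_id: str = "") -> list[CoreHit]:
    """All exact, possibly overlapping occurrences of any variant, left to right."""
    for v in variants:
        if len(v) != 7:
            raise ValueError(f"variant {v!r} is not a 7-mer")
    hits = []
    for i in range(len(seq) - 6):
        window = seq[i:i + 7]
        if window in variants:
            hits.append(CoreHit(protein_id=protein_id, start=i, variant=window))
    return hits


def build_pssm(domain_seqs: list[str], pseudocount: float = 0.5,
               background: dict[str, float] | None = None) -> ProfileMatrix:
    """Per-column log-odds matrix from equal-length ungapped domain sequences."""
    if not domain_seqs:
        raise ValueError("cannot build a profile from zero sequences")
    width = len(domain_seqs[0])
    if any(len(s) != width for s in domain_seqs):
        raise ValueError("domain sequences must all have the same length")
    bg = background or uniform_background()
    if abs(sum(bg.values()) - 1.0) > 1e-9:
        raise ValueError("background frequencies must sum to 1")
    n = len(domain_seqs)
    alpha = pseudocount
    cols = []
    for j in range(width):
        counts: dict[str, int] = {}
        for s in domain_seqs:
            if s[j] in bg:
                counts[s[j]] = counts.get(s[j], 0) + 1
        col = {}
        for r, bg_r in bg.items():
            freq = (counts.get(r, 0) + alpha * bg_r) / (n + alpha)
            col[r] = math.log2(freq / bg_r) if freq > 0 else -math.inf
        cols.append(col)
    return ProfileMatrix(width=width, scores=tuple(cols),
                         background=dict(bg), pseudocount=alpha)


def scan_profile(seq: str, pssm: ProfileMatrix, threshold: float,
                 protein_id: str = "") -> list[DomainHit]:
    """Every window scoring >= ``threshold`` bits, left to right."""
    hits = []
    for i in range(len(seq) - pssm.width + 1):
        score = pssm.score_window(seq[i:i + pssm.width])
        if score >= threshold:
            hits.append(DomainHit(protein_id=protein_id, start=i,
                                  end=i + pssm.width, bit_score=score))
    return hits


def detect_zinc_finger(seq: str, search_start: int = 0, window: int = 80,
                       patterns=DEFAULT_ZF_PATTERNS,
                       protein_id: str = "") -> ZincFingerHit:
    """Type the zinc finger in ``seq[search_start:search_start+window]``.

    Patterns are tried in order; the first match wins. Coordinating residue
    positions are reported in protein coordinates.
    """
    region = seq[search_start:search_start + window]
    for zf_type, pattern in patterns:
        m = re.search(pattern, region)
        if m:
            coords = []
            for i, ch in enumerate(m.group(0)):
                if ch in "CH":
                    coords.append(search_start + m.start() + i)
            # keep only the 4 grammar-coordinating residues: the first two and
            # last two C/H positions of the match
            if len(coords) >= 4:
                coords = coords[:2] + coords[-2:]
            return ZincFingerHit(protein_id=protein_id, zf_type=zf_type,
                                 residue_positions=tuple(coords))
    return ZincFingerHit(protein_id=protein_id, zf_type="none")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _anchor_core(seq: str, start: int, variants, max_mismatch: int,
                 protein_id: str) -> CoreHit | None:
    """Accept the 7-mer at ``start`` if within ``max_mismatch`` of a variant."""
    sevenmer = seq[start:start + 7]
    if len(sevenmer) < 7:
        return None
    best = min((_hamming(sevenmer, v) for v in variants), default=8)
    if best <= max_mismatch:
        return CoreHit(protein_id=protein_id, start=start, variant=sevenmer)
    return None


def _member_domains(record: SequenceRecord, width: int, variants) -> list[tuple[int, str]]:
    """Full-width candidate windows anchored at each exact core hit."""
    out = []
    for core in find_heptapeptide(record.seq, variants, record.id):
        if core.start + width <= len(record.seq):
            out.append((core.start, record.seq[core.start:core.start + width]))
    return out


@dataclass(frozen=True)
class SearchParams:
    variants: tuple[str, ...] = DEFAULT_VARIANTS
    width: int = 60
    pseudocount: float = 0.5
    #: round threshold = max(0, mu - max(2*sigma, margin_bits)) over member scores
    margin_bits: float = 8.0
    #: admitted profile hits may deviate from a variant by this many residues
    core_max_mismatch: int = 1
    max_rounds: int = 50


def _round_threshold(scores: list[float], margin_bits: float) -> float:
    n = len(scores)
    mu = sum(scores) / n
    var = sum((s - mu) ** 2 for s in scores) / n
    sigma = math.sqrt(var)
    return max(0.0, mu - max(2.0 * sigma, margin_bits))


def iterative_search(proteome: list[SequenceRecord],
                     params: SearchParams = SearchParams(),
                     seed_members: set[str] | None = None) -> FamilySet:
    """Iterate profile building and rescanning until no new members appear.

    Seeding: proteins carrying an exact heptapeptide variant with room for a
    full-width domain window (or an explicit ``seed_members`` set). Each round
    builds a PSSM from all member domain windows, sets the admission threshold
    from the member score distribution, rescans the whole proteome, and admits
    proteins whose best passing window is anchored by a near-variant core.
    Membership grows monotonically, so termination is guaranteed.
    """
    if not proteome:
        raise ValueError("empty proteome")
    by_id = {rec.id: rec for rec in proteome}

    def _has_near_anchor(rec: SequenceRecord) -> bool:
        return any(_anchor_core(rec.seq, i, params.variants,
                                params.core_max_mismatch, rec.id)
                   for i in range(len(rec.seq) - params.width + 1))

    if seed_members is None:
        members = {rec.id for rec in proteome
                   if _member_domains(rec, params.width, params.variants)}
    else:
        # re-seeding with a previous result must keep near-variant members
        members = {m for m in seed_members
                   if m in by_id and (_member_domains(by_id[m], params.width,
                                                      params.variants)
                                      or _has_near_anchor(by_id[m]))}
    if not members:
        return FamilySet(members=set(), rounds=0)

    rounds = 0
    threshold = 0.0
    pssm: ProfileMatrix | None = None
    while rounds < params.max_rounds:
        rounds += 1
        training = []
        for mid in sorted(members):
            training.extend(w for _, w in _member_domains(by_id[mid], params.width,
                                                          params.variants))
        # members admitted via near-variant cores train the profile too
        for mid in sorted(members):
            rec = by_id[mid]
            if not _member_domains(rec, params.width, params.variants):
                for i in range(len(rec.seq) - params.width + 1):
                    if _anchor_core(rec.seq, i, params.variants,
                                    params.core_max_mismatch, mid):
                        training.append(rec.seq[i:i + params.width])
        pssm = build_pssm(training, params.pseudocount)
        member_scores = [pssm.score_window(w) for w in training]
        threshold = _round_threshold(member_scores, params.margin_bits)

        new_members = set()
        for rec in proteome:
            if rec.id in members:
                continue
            for hit in scan_profile(rec.seq, pssm, threshold, rec.id):
                if _anchor_core(rec.seq, hit.start, params.variants,
                                params.core_max_mismatch, rec.id):
                    new_members.add(rec.id)
                    break
        if not new_members:
            break
        members |= new_members

    assert rounds <= len(proteome) or rounds <= params.max_rounds
    # Recorded evidence: exact-core anchored windows are kept regardless of
    # score (the core is the verification criterion); near-variant anchors
    # must additionally clear the admission threshold.
    hits: dict[str, list[DomainHit]] = {}
    for mid in sorted(members):
        rec = by_id[mid]
        mhits = []
        for start, window in _member_domains(rec, params.width, params.variants):
            mhits.append(DomainHit(
                protein_id=mid, start=start, end=start + params.width,
                bit_score=pssm.score_window(window),
                core=CoreHit(protein_id=mid, start=start,
                             variant=rec.seq[start:start + 7])))
        exact_starts = {h.start for h in mhits}
        for hit in scan_profile(rec.seq, pssm, threshold, mid):
            if hit.start in exact_starts:
                continue
            core = _anchor_core(rec.seq, hit.start, params.variants,
                                params.core_max_mismatch, mid)
            if core is not None:
                mhits.append(DomainHit(protein_id=mid, start=hit.start,
                                       end=hit.end, bit_score=hit.bit_score,
                                       core=core))
        hits[mid] = _deoverlap(mhits)
    return FamilySet(members=members, hits=hits, rounds=rounds,
                     threshold=threshold, profile=pssm)


def _deoverlap(hits: list[DomainHit]) -> list[DomainHit]:
    """Greedy best-score-first selection of non-overlapping domain hits."""
    chosen: list[DomainHit] = []
    for h in sorted(hits, key=lambda h: (-h.bit_score, h.start)):
        if all(h.end <= c.start or h.start >= c.end for c in chosen):
            chosen.append(h)
    return sorted(chosen, key=lambda h: h.start)
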