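import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wrkyminer.domain_scan import (SearchParams, build_pssm,
                                   detect_zinc_finger, find_heptapeptide,
                                   iterative_search, scan_profile)
from wrkyminer.io_formats import SequenceRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_scan(seq, pssm, threshold):
    """Independent oracle: score every window from the raw score table."""
    out = []
    for i in range(len(seq) - pssm.width + 1):
        total = 0.0
        for j in range(pssm.width):
            total += pssm.scores[j].get(seq[i + j], 0.0)
        if total >= threshold:
            out.append((i, total))
    return out


class TestFindHeptapeptide:
    def test_exact_match(self):
        hits = find_heptapeptide("MAWRKYGQKA")
        assert [(h.start, h.variant) for h in hits] == [(2, "WRKYGQK")]

    def test_both_variants(self):
        hits = find_heptapeptide("WRKYGKKXXWRKYGQK")
        assert [h.variant for h in hits] == ["WRKYGKK", "WRKYGQK"]

    def test_non_variant_rejected(self):
        assert find_heptapeptide("WRKYGEK") == []

    def test_empty_sequence(self):
        assert find_heptapeptide("") == []


class TestBuildPssm:
    def test_identical_columns_alpha_zero(self):
        pssm = build_pssm(["A", "A"], pseudocount=0.0)
        assert pssm.scores[0]["A"] == pytest.approx(math.log2(20), abs=1e-9)

    def test_large_alpha_washes_out(self):
        pssm = build_pssm(["A", "A"], pseudocount=1e9)
        assert abs(pssm.scores[0]["A"]) < 1e-6
        assert abs(pssm.scores[0]["C"]) < 1e-6

    def test_split_column_closed_form(self):
        pssm = build_pssm(["A", "C"], pseudocount=0.0)
        assert pssm.scores[0]["A"] == pytest.approx(math.log2(10), abs=1e-9)

    def test_ragged_error(self):
        with pytest.raises(ValueError):
            build_pssm(["AA", "A"])

    def test_empty_error(self):
        with pytest.raises(ValueError):
            build_pssm([])


class TestScanProfile:
    def test_consensus_scores_width_log2_20(self):
        dom = "WRKYGQK"
        pssm = build_pssm([dom, dom], pseudocount=0.0)
        hits = scan_profile(dom, pssm, threshold=0.0)
        assert len(hits) == 1
        assert hits[0].bit_score == pytest.approx(7 * math.log2(20), abs=1e-9)

    def test_infinite_threshold(self):
        pssm = build_pssm(["WRKYGQK", "WRKYGQK"])
        assert scan_profile("WRKYGQKWRKYGQK", pssm, math.inf) == []

    def test_short_sequence(self):
        pssm = build_pssm(["WRKYGQK", "WRKYGQK"])
        assert scan_profile("WRK", pssm, -1e9) == []

    def test_unknown_residue_scores_zero(self):
        pssm = build_pssm(["AA", "AA"], pseudocount=0.0)
        hits = scan_profile("AX", pssm, -1e9)
        assert hits[0].bit_score == pytest.approx(math.log2(20))

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            seq = "".join(rng.choice(list(AA), size=40))
            training = ["".join(rng.choice(list(AA), size=7)) for _ in range(3)]
            pssm = build_pssm(training, pseudocount=0.5)
            got = [(h.start, h.bit_score) for h in scan_profile(seq, pssm, -50.0)]
            expected = brute_force_scan(seq, pssm, -50.0)
            assert [s for s, _ in got] == [s for s, _ in expected]
            for (_, a), (_, b) in zip(got, expected):
                assert a == pytest.approx(b, abs=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(seq=st.text(alphabet=AA + "X", min_size=0, max_size=60),
           thr=st.floats(-40, 40))
    def test_property_equals_oracle(self, seq, thr):
        pssm = build_pssm(["WRKYGQK", "WRKYGKK", "WRKYGEK"])
        got = [(h.start, round(h.bit_score, 9)) for h in scan_profile(seq, pssm, thr)]
        exp = [(s, round(v, 9)) for s, v in brute_force_scan(seq, pssm, thr)]
        assert got == exp


class TestDetectZincFinger:
    def test_c2h2(self):
        seq = "C" + "A" * 4 + "C" + "A" * 22 + "H" + "A" + "H"
        hit = detect_zinc_finger(seq)
        assert hit.zf_type == "C2H2"
        assert hit.residue_positions == (0, 5, 28, 30)

    def test_c2hc(self):
        seq = "C" + "A" * 7 + "C" + "A" * 23 + "H" + "A" + "C"
        hit = detect_zinc_finger(seq)
        assert hit.zf_type == "C2HC"
        assert hit.residue_positions == (0, 8, 32, 34)

    def test_none(self):
        assert detect_zinc_finger("A" * 80).zf_type == "none"

    def test_window_limits_search(self):
        seq = "A" * 50 + "C" + "A" * 4 + "C" + "A" * 22 + "H" + "A" + "H"
        assert detect_zinc_finger(seq, search_start=0, window=40).zf_type == "none"
        assert detect_zinc_finger(seq, search_start=50).zf_type == "C2H2"


class TestIterativeSearch:
    def test_fixpoint_on_fixture(self, convergence_proteome):
        fam = iterative_search(convergence_proteome)
        assert fam.members == {"A", "B", "C"}
        assert fam.rounds == 2

    def test_fixpoint_verified_by_exhaustive_rescan(self, convergence_proteome):
        fam = iterative_search(convergence_proteome)
        # oracle: rescan every non-member with the final profile/threshold;
        # no anchored window may clear the admission threshold
        from wrkyminer.domain_scan import _anchor_core
        for rec in convergence_proteome:
            if rec.id in fam.members:
                continue
            for hit in scan_profile(rec.seq, fam.profile, fam.threshold, rec.id):
                assert _anchor_core(rec.seq, hit.start,
                                    ("WRKYGQK", "WRKYGKK"), 1, rec.id) is None

    def test_idempotent(self, convergence_proteome):
        fam = iterative_search(convergence_proteome)
        again = iterative_search(convergence_proteome, seed_members=fam.members)
        assert again.members == fam.members

    def test_no_heptapeptide(self):
        proteome = [SequenceRecord(id="p", seq="MKVLAAAA" * 20)]
        fam = iterative_search(proteome)
        assert fam.members == set() and fam.rounds == 0

    def test_every_member_has_core_hit(self, family_bundle):
        records, _ = family_bundle
        fam = iterative_search(records)
        for mid in fam.members:
            assert fam.hits[mid], mid
            assert all(h.core is not None for h in fam.hits[mid])

    def test_rounds_bounded_by_proteome(self, family_bundle):
        records, _ = family_bundle
        fam = iterative_search(records)
        assert fam.rounds <= len(records)

    def test_empty_proteome_error(self):
        with pytest.raises(ValueError):
            iterative_search([])

    def test_deterministic(self, convergence_proteome):
        a = iterative_search(convergence_proteome)
        b = iterative_search(convergence_proteome)
        assert a.members == b.members and a.threshold == b.threshold


class TestSearchParams:
    def test_custom_variants(self):
        seq = "AA" + "WRKYGEK" + "A" * 60
        rec = SequenceRecord(id="p", seq=seq)
        fam = iterative_search([rec], SearchParams(variants=("WRKYGEK",), width=30))
        assert fam.members == {"p"}
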