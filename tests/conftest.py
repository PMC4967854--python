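from __future__ import annotations

import numpy as np
import pytest

from wrkyminer.io_formats import SequenceRecord

BACKBONE = "ADEFGIKLMNPQRSTVWY"


def _rand_aa(rng, n):
    return "".join(rng.choice(list(BACKBONE), size=n))


@pytest.fixture(scope="session")
def convergence_proteome():
    """Four proteins: consensus A, 1-mismatch B, 2-mismatch C (one mismatch
    inside the heptapeptide, so seeding misses it), and a decoy D carrying
    only a near-miss 7-mer. The iterative search must converge to {A, B, C}
    in two rounds."""
    rng = np.random.default_rng(42)
    cons = "WRKYGQK" + _rand_aa(rng, 53)
    split = 30
    dom_b = cons[:split] + ("A" if cons[split] != "A" else "D") + cons[split + 1:]
    dom_c = cons[:4] + "A" + cons[5:split] + dom_b[split] + cons[split + 1:]

    def prot(pid, dom):
        return SequenceRecord(id=pid,
                              seq=_rand_aa(rng, 20) + dom + _rand_aa(rng, 20))

    decoy = _rand_aa(rng, 120)
    decoy = decoy[:40] + "WRKYAQK" + decoy[47:]
    return [prot("A", cons), prot("B", dom_b), prot("C", dom_c),
            SequenceRecord(id="D", seq=decoy)]


@pytest.fixture(scope="session")
def family_bundle():
    """Synthetic proteome with planted groups, plus its truth table."""
    from wrkyminer.synthetic_data import simulate_family_proteome
    records, truth = simulate_family_proteome(
        seed=1, group_counts={"Ia": 3, "III": 2, "IV": 1}, decoys=10)
    return records, truth
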