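import numpy as np
import pytest

from raftcrac.motifs import MotifPattern, ProteinRecord, TMTopology


@pytest.fixture
def tm2_fragment():
    """The printed TM2 sub-segment carrying three overlapping CRAC motifs."""
    return ProteinRecord("TM2-frag", "mouse", "VFLSSIFGYCK", offset=780)


@pytest.fixture
def tm4_fragment():
    """The printed TM4 sub-segment carrying one CRAC motif."""
    return ProteinRecord("TM4-frag", "mouse", "LLYLQR", offset=850)


def brute_force_scan(sequence: str, offset: int, pattern: MotifPattern,
                     region=None):
    """Independent oracle: exhaustively test every (i, j, k) residue triple.

    Checks residue-class membership and the strict between-anchor gap bounds
    directly, with no shared code with the scanner.
    """
    lo = offset
    hi = offset + len(sequence) - 1
    if region is not None:
        lo, hi = max(lo, region[0]), min(hi, region[1])
    triples = []
    for i in range(lo, hi + 1):
        for j in range(i + 1, hi + 1):
            for k in range(j + 1, hi + 1):
                a, b, c = (sequence[p - offset] for p in (i, j, k))
                if a not in pattern.apolar_set:
                    continue
                if b not in pattern.aromatic_set:
                    continue
                if c not in pattern.basic_set:
                    continue
                gap1 = j - i - 1
                gap2 = k - j - 1
                if pattern.gap_min <= gap1 <= pattern.gap_max \
                        and pattern.gap_min <= gap2 <= pattern.gap_max:
                    triples.append((i, j, k))
    return sorted(triples)


@pytest.fixture
def brute_scanner():
    return brute_force_scan


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))


@pytest.fixture
def make_random_protein():
    return random_protein


@pytest.fixture
def demo_topology():
    return TMTopology([("TM2", 766, 793), ("TM4", 828, 858)])
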