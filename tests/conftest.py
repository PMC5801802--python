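import numpy as np
import pytest

from plastiq import SimulationConfig, simulate

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def random_cds(rng: np.random.Generator, n_codons: int,
               no_adjacent_repeat: bool = False) -> str:
    """ATG + random stop-free codons + TAA; optionally with no two equal
    adjacent bases anywhere (indel placement is then unambiguous)."""
    stops = {"TAA", "TAG", "TGA"}
    out = ["ATG"]
    while len(out) < n_codons - 1:
        c = "".join(BASES[i] for i in rng.integers(0, 4, size=3))
        if c in stops:
            continue
        joined = out[-1][-1] + c
        if no_adjacent_repeat and any(
            joined[k] == joined[k + 1] for k in range(3)
        ):
            continue
        out.append(c)
    # terminal TAA: ensure the junction base differs when required
    if no_adjacent_repeat and out[-1][-1] == "T":
        out[-1] = out[-1][:2] + ("C" if out[-1][1] != "C" else "G")
    out.append("TAA")
    return "".join(out)


def leftmost_del(ref: str, o: int, L: int) -> int:
    """Leftmost equivalent placement of deleting ref[o:o+L]; an indel's
    position inside a repeat is defined only up to this normalisation."""
    while o > 0 and ref[o - 1] == ref[o + L - 1]:
        o -= 1
    return o


@pytest.fixture(scope="session")
def sim_result():
    """The standard 6-leaf, 5-event simulation (seed 1)."""
    return simulate(SimulationConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
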