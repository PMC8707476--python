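import numpy as np
import pytest

from tertrap.genome import CircularGenome
from tertrap.motif import TerSequence, load_reference
from tertrap.simulate import GenomeSpec, PlantedTer, make_replichore_genome


@pytest.fixture(scope="session")
def terb() -> TerSequence:
    return load_reference("TerB")


@pytest.fixture(scope="session")
def terc() -> TerSequence:
    return load_reference("TerC")


def random_genome(L: int, seed: int, gc_bias: float = 0.0) -> CircularGenome:
    rng = np.random.default_rng(seed)
    p = np.array([0.25, 0.25 - gc_bias, 0.25 + gc_bias, 0.25])
    seq = "".join(rng.choice(list("ACGT"), size=L, p=p))
    return CircularGenome(f"rand{seed}", seq)


@pytest.fixture(scope="session")
def k12_like(terb):
    """Synthetic K12-like chromosome: ten primary Ter sites in the published
    orientation/order plus four pseudo-Ter decoys with degenerate cores.

    Mirrors the real arrangement: the clockwise fork crosses the terminus
    and is arrested by the CW-blocking cluster (TerB, C, F, G, J; displayed
    strand +) just beyond it, TerC first; the anticlockwise fork by the
    CCW-blocking cluster (TerA, D, E, I, H; displayed strand -) on the other
    side, TerA first.  The two innermost sites therefore lie past each other
    and their arcs overlap around the terminus.
    """
    L = 4_000_000
    oriC = 1
    terminus = 2_000_000
    cw = {"TerC": 2_050_000, "TerB": 2_120_000, "TerF": 2_200_000,
          "TerG": 2_400_000, "TerJ": 2_900_000}
    ccw = {"TerA": 1_950_000, "TerD": 1_800_000, "TerE": 1_650_000,
           "TerI": 1_400_000, "TerH": 1_100_000}
    identities = {"TerB": 100.0, "TerC": 100 * 17 / 23, "TerA": 100 * 20 / 23,
                  "TerD": 100 * 19 / 23, "TerE": 100 * 19 / 23,
                  "TerF": 100 * 18 / 23, "TerG": 100 * 18 / 23,
                  "TerH": 100 * 20 / 23, "TerI": 100 * 19 / 23,
                  "TerJ": 100 * 18 / 23}
    planted = []
    for name, pos in cw.items():
        planted.append(PlantedTer(pos, "+", identities[name], True, name))
    for name, pos in ccw.items():
        planted.append(PlantedTer(pos, "-", identities[name], True, name))
    # pseudo-Ter decoys: identity above threshold but degenerate core
    for i, pos in enumerate((400_000, 700_000, 3_200_000, 3_600_000)):
        planted.append(
            PlantedTer(pos, "+" if i % 2 else "-", 100 * 17 / 23, False,
                       f"pseudo{'KLYZ'[i]}")
        )
    spec = GenomeSpec(L=L, oriC=oriC, terminus=terminus, skew_delta=0.04,
                      ter_sites=planted, seed=1234)
    genome, truth = make_replichore_genome(spec)
    return genome, truth, spec
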