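import numpy as np
import pytest

from isomirkit.annotation_model import ArmAnnotation, PrecursorLocus
from isomirkit.synthetic_data import SimulationConfig, simulate


@pytest.fixture
def toy_locus() -> PrecursorLocus:
    """A 64-nt hairpin with a 5p mature window [8, 29) and a 3p star
    window [37, 58); flanks are wide enough for ±5 nt extensions."""
    mature = "UGAGAUCAUCGUGAAAGCUGA"  # 21 nt
    star = "UCAGCUUUCACGAUGAUCACA"  # near-revcomp partner, 21 nt
    loop = "GACUUAGC"
    f5, f3 = "AAGCCUGA", "CGGAUG"
    seq = f5 + mature + loop + star + f3
    return PrecursorLocus(
        locus_id="TOY_001.1_1",
        seq=seq,
        mature=ArmAnnotation("mature", len(f5), len(f5) + 21, "5p"),
        star=ArmAnnotation("star", len(f5) + 21 + len(loop),
                           len(f5) + 21 + len(loop) + 21, "3p"),
    )


@pytest.fixture(scope="session")
def small_library():
    """A compact ground-truthed library shared by the cheaper tests."""
    cfg = SimulationConfig(n_loci=8, total_reads=6000, seed=11)
    return simulate(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
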