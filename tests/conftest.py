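import numpy as np
import pytest

from gapdvh.dvh import DVH, DoseGrid, StructureMask
from gapdvh.radiobiology import TissueParams


@pytest.fixture
def c1_tumor() -> TissueParams:
    return TissueParams(
        name="tumor_c1", alpha_beta=10.0, K=0.9, T_delay=28.0,
        tissue_class="tumor",
    )


@pytest.fixture
def generic_oar() -> TissueParams:
    return TissueParams(
        name="oar", alpha_beta=3.0, repair_half_time=2.0, tissue_class="oar"
    )


@pytest.fixture
def toy_grid() -> DoseGrid:
    # 3 voxels at 2, 5, 5 Gy; 0.5 cm^3 voxels (10 x 10 x 5 mm)
    values = np.array([[[2.0, 5.0, 5.0]]])
    return DoseGrid(values=values, spacing=(10.0, 10.0, 5.0))


@pytest.fixture
def toy_mask(toy_grid) -> StructureMask:
    return StructureMask(
        name="toy", mask=np.ones(toy_grid.values.shape, bool),
        voxel_volume=toy_grid.voxel_volume_cc,
    )


def uniform_dvh(dose: float, volume: float, bin_width: float = 0.01,
                structure: str = "s") -> DVH:
    """Single-occupied-bin DVH with the bin's representative dose set exactly."""
    import math

    n_bins = int(math.floor(dose / bin_width)) + 1
    edges = np.arange(n_bins + 1, dtype=float) * bin_width
    vols = np.zeros(n_bins)
    vols[-1] = volume
    doses = edges[:-1] + bin_width / 2.0
    doses[-1] = dose
    return DVH(structure=structure, bin_edges=edges, differential_volume=vols,
               bin_doses=doses)


@pytest.fixture
def uniform_dvh_factory():
    return uniform_dvh
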