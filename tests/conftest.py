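import numpy as np
import pytest

from tetherlink.star_io import ParticleRecord, ParticleTable

STAR_TWO_ROWS = """
data_particles

loop_
_rlnMicrographName #1
_rlnCoordinateX #2
_rlnCoordinateY #3
mic_001.mrc 100.0 200.0
mic_002.mrc 50.0 60.0
"""

STAR_FOUR_ROWS_TWO_MICS = """
data_particles

loop_
_rlnMicrographName #1
_rlnCoordinateX #2
_rlnCoordinateY #3
mic_001.mrc 10.0 20.0
mic_001.mrc 30.0 40.0
mic_002.mrc 50.0 60.0
mic_002.mrc 70.0 80.0
"""

STAR_WITH_OPTICS = """
data_optics

loop_
_rlnOpticsGroup #1
_rlnImagePixelSize #2
1 0.822

data_particles

loop_
_rlnMicrographName #1
_rlnCoordinateX #2
_rlnCoordinateY #3
_rlnOriginXAngst #4
_rlnOriginYAngst #5
mic_001.mrc 1000.0 2000.0 8.22 -8.22
"""


@pytest.fixture
def star_two_rows():
    return STAR_TWO_ROWS


@pytest.fixture
def star_four_rows_two_mics():
    return STAR_FOUR_ROWS_TWO_MICS


@pytest.fixture
def star_with_optics():
    return STAR_WITH_OPTICS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_table(rng, n_records=100, n_micrographs=10, apix=0.822, population="tauA"):
    """A seeded random particle table used by round-trip and null tests."""
    records = []
    for _ in range(n_records):
        mic = f"mic_{rng.integers(n_micrographs):03d}.mrc"
        records.append(
            ParticleRecord(
                micrograph_id=mic,
                x_px=float(rng.uniform(0, 5000)),
                y_px=float(rng.uniform(0, 4000)),
                origin_x_A=float(rng.uniform(-20, 20)),
                origin_y_A=float(rng.uniform(-20, 20)),
                pixel_size_A=apix,
            )
        )
    return ParticleTable(records=records, population=population)
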