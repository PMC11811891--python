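"""Synthetic tethered-particle micrograph fields with known ground truth.

Generates the particle coordinate tables the pairing pipeline consumes,
emulating a cryo-EM dataset of a two-body complex (tauA tethered to
tauB): each micrograph holds a number of genuine pairs — a tauB particle
at a uniformly placed anchor and its tauA partner displaced by a
flexible tether — plus unlinked background particles of both species,
and each emitted particle survives picking/classification with a
species-specific detection probability.

Tether model: the 3-D displacement of the tethered body is isotropic
Gaussian with per-axis standard deviation sigma; the micrograph records
its 2-D projection, so the in-plane pair distance is Rayleigh(sigma)
with mode sigma and mean sigma*sqrt(pi/2).  Displacements that would
leave the field are re-drawn (truncation, not clipping); the resulting
bias is negligible while sigma is small against the field.

The default field (14,000 x 14,000 A) puts the default particle load
(~28 per species per micrograph) in the tether-resolvable regime: the
expected number of unrelated particles within the 3-sigma tether disc of
any particle, rho * pi * (3 sigma)^2, is ~0.16, so greedy pairing can
isolate genuine partners.  Scenes are reproducible: one global seed
spawns independent per-micrograph substreams, so micrograph i is
identical whether 10 or 10,000 micrographs are simulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from .errors import ParameterError
from .star_io import ParticleRecord, ParticleTable, write_particles

__all__ = [
    "SceneParams",
    "TruePair",
    "sample_projected_separation",
    "simulate_scene",
    "export_scene",
]

# sparse-regime default: ~28 particles/species at rho*pi*(3*200 A)^2 ~ 0.16
DEFAULT_FIELD_W_A = 14_000.0
DEFAULT_FIELD_H_A = 14_000.0

_MAX_REDRAWS = 10_000


@dataclass
class SceneParams:
    """Generative parameters for a synthetic tethered-particle dataset.

    Defaults are the package's standard recovery conditions: 100
    micrographs of 20 tethered pairs with tether scale sigma = 200 A,
    10 free (unlinked) particles per species per micrograph, and 90%
    detection per species.
    """

    field_w_A: float = DEFAULT_FIELD_W_A
    field_h_A: float = DEFAULT_FIELD_H_A
    n_micrographs: int = 100
    pairs_per_micrograph: int = 20
    tether_sigma_A: float = 200.0
    free_a_per_micrograph: int = 10
    free_b_per_micrograph: int = 10
    detect_prob_a: float = 0.9
    detect_prob_b: float = 0.9
    pixel_size_A: float = 0.822
    seed: int = 0

    def __post_init__(self) -> None:
        if self.field_w_A <= 0 or self.field_h_A <= 0:
            raise ParameterError("field extents must be positive")
        if self.n_micrographs < 1:
            raise ParameterError("n_micrographs must be >= 1")
        if self.pairs_per_micrograph < 0:
            raise ParameterError("pairs_per_micrograph must be >= 0")
        if self.tether_sigma_A < 0:
            raise ParameterError("tether_sigma_A must be >= 0")
        if self.free_a_per_micrograph < 0 or self.free_b_per_micrograph < 0:
            raise ParameterError("free particle counts must be >= 0")
        for p in (self.detect_prob_a, self.detect_prob_b):
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"detection probability {p} outside [0, 1]")
        if self.pixel_size_A <= 0:
            raise ParameterError("pixel_size_A must be positive")
        if self.tether_sigma_A > min(self.field_w_A, self.field_h_A) / 2:
            warnings.warn(
                "tether sigma is large against the field; projected "
                "separations will be strongly truncated",
                stacklevel=2,
            )


@dataclass
class TruePair:
    """Ground-truth ledger entry: a genuine pair with both members retained.

    Indices refer to positions within each table's micrograph group, the
    same indexing the pairing algorithm reports.
    """

    micrograph_id: str
    b_index: int
    a_index: int
    true_distance_A: float


def sample_projected_separation(
    sigma_A: float,
    seed: Union[int, np.random.Generator] = 0,
    size: Optional[int] = None,
) -> Union[float, np.ndarray]:
    """Planar norm of an isotropic 3-D Gaussian tether displacement.

    Drawn as a per-axis N(0, sigma^2) vector projected onto the image
    plane, whose norm is Rayleigh(sigma); sigma = 0 returns exactly 0.
    """
    if sigma_A < 0:
        raise ParameterError(f"sigma_A must be >= 0, got {sigma_A}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = 1 if size is None else size
    disp = rng.normal(0.0, sigma_A, size=(n, 3)) if sigma_A > 0 else np.zeros((n, 3))
    r = np.hypot(disp[:, 0], disp[:, 1])
    return float(r[0]) if size is None else r


def _place_partner(
    anchor: np.ndarray,
    sigma_A: float,
    field: Tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Tethered partner position: anchor + projected displacement, re-drawn
    until it lands inside the field."""
    if sigma_A == 0:
        return anchor.copy()
    w, h = field
    for _ in range(_MAX_REDRAWS):
        dx, dy, _dz = rng.normal(0.0, sigma_A, size=3)
        pos = anchor + (dx, dy)
        if 0.0 <= pos[0] < w and 0.0 <= pos[1] < h:
            return pos
    raise ParameterError(
        "could not place a tether endpoint inside the field; "
        "sigma is too large for the field extents"
    )


def simulate_scene(
    params: SceneParams,
) -> Tuple[ParticleTable, ParticleTable, List[TruePair]]:
    """Simulate micrograph fields and return (table_a, table_b, truth).

    Per micrograph: ``pairs_per_micrograph`` anchors uniform in the
    field, each emitting a tauB particle at the anchor and a tauA
    particle displaced by the tether; every emitted particle is kept
    independently with its species' detection probability; free
    particles of both species are placed uniformly.  The truth ledger
    lists the pairs whose two members were both retained, with their
    within-micrograph indices and true planar separation.
    """
    streams = np.random.SeedSequence(params.seed).spawn(params.n_micrographs)
    field = (params.field_w_A, params.field_h_A)
    apix = params.pixel_size_A

    records_a: List[ParticleRecord] = []
    records_b: List[ParticleRecord] = []
    truth: List[TruePair] = []

    def _record(mic: str, pos: np.ndarray) -> ParticleRecord:
        return ParticleRecord(
            micrograph_id=mic,
            x_px=pos[0] / apix,
            y_px=pos[1] / apix,
            origin_x_A=0.0,
            origin_y_A=0.0,
            pixel_size_A=apix,
        )

    for i, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        mic = f"synthetic_{i:05d}.mrc"
        mic_a: List[ParticleRecord] = []
        mic_b: List[ParticleRecord] = []
        pending: List[Tuple[Optional[int], Optional[int], float]] = []

        for _ in range(params.pairs_per_micrograph):
            anchor = rng.uniform((0.0, 0.0), field)
            partner = _place_partner(anchor, params.tether_sigma_A, field, rng)
            keep_b = rng.random() < params.detect_prob_b
            keep_a = rng.random() < params.detect_prob_a
            b_idx = a_idx = None
            if keep_b:
                b_idx = len(mic_b)
                mic_b.append(_record(mic, anchor))
            if keep_a:
                a_idx = len(mic_a)
                mic_a.append(_record(mic, partner))
            if keep_a and keep_b:
                d = float(np.hypot(*(partner - anchor)))
                pending.append((b_idx, a_idx, d))

        for _ in range(params.free_b_per_micrograph):
            mic_b.append(_record(mic, rng.uniform((0.0, 0.0), field)))
        for _ in range(params.free_a_per_micrograph):
            mic_a.append(_record(mic, rng.uniform((0.0, 0.0), field)))

        records_a.extend(mic_a)
        records_b.extend(mic_b)
        truth.extend(
            TruePair(mic, b_idx, a_idx, d) for b_idx, a_idx, d in pending
        )

    table_a = ParticleTable(records=records_a, population="tauA")
    table_b = ParticleTable(records=records_b, population="tauB")
    return table_a, table_b, truth


def export_scene(
    table_a: ParticleTable,
    table_b: ParticleTable,
    path_a: str,
    path_b: str,
) -> None:
    """Write the two population tables as STAR files (coordinates in pixels)."""
    with open(path_a, "w") as fh:
        fh.write(write_particles(table_a))
    with open(path_b, "w") as fh:
        fh.write(write_particles(table_b))


def truth_to_tsv(truth: List[TruePair]) -> str:
    """Serialize a ground-truth ledger as TSV."""
    lines = ["micrograph_id\tb_index\ta_index\ttrue_distance_A"]
    for t in truth:
        lines.append(
            f"{t.micrograph_id}\t{t.b_index}\t{t.a_index}\t{t.true_distance_A:.6f}"
        )
    return "\n".join(lines) + "\n"
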