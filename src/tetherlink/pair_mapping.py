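"""Greedy per-micrograph pairing of two particle populations.

Single-particle cryo-EM of a two-body complex joined by a long flexible
tether yields two independently refined particle sets (here: the tauA and
tauB modules of TFIIIC) that live on the same micrographs.  If the two
bodies are physically linked, each tauB particle should have a tauA
partner nearby, at a separation governed by the tether.

The pairing rule operates micrograph by micrograph:

1. build the N_tauB x N_tauA matrix of Euclidean distances (Angstroms)
   between refined positions;
2. repeatedly take the smallest remaining entry, record that pair, and
   delete its row and column (so no particle is paired twice);
3. stop when either population is exhausted.

This is deliberately a greedy delete-min rule, not a minimum-total-cost
assignment: it mirrors how linked pairs are identified one at a time,
nearest first.  Pooling the paired distances over all micrographs gives
the distance distribution; the significance reference is the same
particle multiplicities with coordinates re-drawn uniformly over the
micrograph field (the randomized null).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ParameterError
from .star_io import ParticleRecord, ParticleTable

__all__ = [
    "PairingResult",
    "build_distance_matrix",
    "greedy_pair",
    "pair_all_micrographs",
    "randomize_coordinates",
    "observed_and_null_distances",
    "field_extent_from_table",
]

Pair = Tuple[int, int, float]


@dataclass
class PairingResult:
    """Matched pairs per micrograph plus the pooled distance list.

    ``pairs_by_micrograph[mic]`` holds ``(row, col, distance_A)`` triples
    in selection order (rows index the tauB population, columns tauA).
    ``pooled_distances_A`` concatenates the per-micrograph distances in
    sorted-micrograph iteration order.  Micrographs present in only one
    table contribute no pairs and are listed in ``skipped_micrographs``.
    """

    pairs_by_micrograph: Dict[str, List[Pair]] = field(default_factory=dict)
    pooled_distances_A: List[float] = field(default_factory=list)
    skipped_micrographs: List[str] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pooled_distances_A)


def build_distance_matrix(
    coords_b: Sequence[Tuple[float, float]],
    coords_a: Sequence[Tuple[float, float]],
) -> np.ndarray:
    """Euclidean distance matrix, tauB rows by tauA columns, in Angstroms.

    Either input may be empty, producing a zero-extent matrix.
    """
    b = np.asarray(coords_b, dtype=float).reshape(-1, 2)
    a = np.asarray(coords_a, dtype=float).reshape(-1, 2)
    if b.size == 0 or a.size == 0:
        return np.zeros((b.shape[0], a.shape[0]), dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ParameterError("coordinates must be finite")
    return cdist(b, a)


def greedy_pair(matrix: np.ndarray) -> List[Pair]:
    """Successive-minimum pairing without replacement.

    Selects the global minimum of the matrix, records ``(row, col,
    value)``, deletes that row and column, and repeats until one
    dimension is exhausted.  Ties are broken by smallest row index, then
    smallest column index (the first occurrence in row-major order).
    Selection-order distances are therefore nondecreasing.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ParameterError(f"distance matrix must be 2-D, got shape {m.shape}")
    n_pairs = min(m.shape)
    if n_pairs == 0:
        return []
    work = m.copy()
    pairs: List[Pair] = []
    for _ in range(n_pairs):
        # argmin on the row-major flattening returns the first occurrence,
        # which is exactly the smallest-row-then-smallest-column tie-break
        flat = int(np.argmin(work))
        row, col = divmod(flat, work.shape[1])
        pairs.append((row, col, float(m[row, col])))
        work[row, :] = np.inf
        work[:, col] = np.inf
    return pairs


def pair_all_micrographs(
    table_b: ParticleTable, table_a: ParticleTable
) -> PairingResult:
    """Run the greedy pairing independently on every shared micrograph.

    Micrographs are visited in sorted-id order so the pooled distance
    list is reproducible regardless of record order.  Zero shared
    micrographs is reported with a warning, not an exception.
    """
    groups_b = table_b.groups()
    groups_a = table_a.groups()
    shared = sorted(set(groups_b) & set(groups_a))
    skipped = sorted(set(groups_b) ^ set(groups_a))
    if not shared:
        warnings.warn(
            "particle tables share no micrograph ids; no pairs produced",
            stacklevel=2,
        )
        return PairingResult(skipped_micrographs=skipped)

    result = PairingResult(skipped_micrographs=skipped)
    for mic in shared:
        matrix = build_distance_matrix(
            table_b.positions(mic), table_a.positions(mic)
        )
        pairs = greedy_pair(matrix)
        result.pairs_by_micrograph[mic] = pairs
        result.pooled_distances_A.extend(d for _, _, d in pairs)
    return result


def observed_and_null_distances(
    table_b: ParticleTable,
    table_a: ParticleTable,
    field_w_A: float,
    field_h_A: float,
    seed: int = 0,
    n_replicates: int = 10,
) -> Tuple[List[float], List[float]]:
    """Pooled pair distances for the data and for the randomized null.

    Runs the greedy pairing once on the observed tables and
    ``n_replicates`` times on randomized-coordinate copies (same
    per-micrograph multiplicities, uniform positions on the field),
    pooling the null distances across replicates.  Each replicate and
    each population gets its own deterministic substream derived from
    ``seed``.
    """
    observed = pair_all_micrographs(table_b, table_a).pooled_distances_A
    null_distances: List[float] = []
    for rep in range(n_replicates):
        null_a = randomize_coordinates(
            table_a, field_w_A, field_h_A, seed=seed * 1000 + rep
        )
        null_b = randomize_coordinates(
            table_b, field_w_A, field_h_A, seed=seed * 1000 + rep + 1_000_003
        )
        null_distances.extend(
            pair_all_micrographs(null_b, null_a).pooled_distances_A
        )
    return list(observed), null_distances


def field_extent_from_table(table: ParticleTable) -> Tuple[float, float]:
    """Data-derived field extents: the maximum refined coordinate per axis.

    Used as a fallback when no physical micrograph dimensions are
    configured; slightly biases the randomized null inward relative to
    the true field.
    """
    coords = np.asarray(
        [pos for mic in table.micrograph_ids() for pos in table.positions(mic)],
        dtype=float,
    )
    if coords.size == 0:
        raise ParameterError("cannot derive field extent from an empty table")
    w, h = coords.max(axis=0)
    if w <= 0 or h <= 0:
        raise ParameterError(f"derived field extent is degenerate: ({w}, {h})")
    return float(w), float(h)


def randomize_coordinates(
    table: ParticleTable,
    field_w_A: Optional[float] = None,
    field_h_A: Optional[float] = None,
    seed: int = 0,
) -> ParticleTable:
    """Randomized-coordinate null: same particle multiplicities, uniform positions.

    Per micrograph, the same number of particles is regenerated with
    refined positions i.i.d. uniform on ``[0, field_w_A) x [0,
    field_h_A)``; everything else about the table (micrograph ids, pixel
    size, population label) is preserved.  Deterministic given ``seed``.

    When field extents are omitted they are derived from the data
    (maximum observed coordinate per axis), with a warning.
    """
    if field_w_A is None or field_h_A is None:
        if len(table) > 0:
            warnings.warn(
                "field extents not given; deriving them from the data "
                "(biases the null slightly inward)",
                stacklevel=2,
            )
            field_w_A, field_h_A = field_extent_from_table(table)
        else:
            field_w_A = field_w_A if field_w_A is not None else 1.0
            field_h_A = field_h_A if field_h_A is not None else 1.0
    if field_w_A <= 0 or field_h_A <= 0:
        raise ParameterError(
            f"field extents must be positive, got ({field_w_A}, {field_h_A})"
        )

    rng = np.random.default_rng(seed)
    records: List[ParticleRecord] = []
    groups = table.groups()
    for mic in sorted(groups):  # sorted: reproducible independent of input order
        recs = groups[mic]
        n = len(recs)
        apix = recs[0].pixel_size_A
        xs = rng.uniform(0.0, field_w_A, size=n)
        ys = rng.uniform(0.0, field_h_A, size=n)
        for x_A, y_A in zip(xs, ys):
            records.append(
                ParticleRecord(
                    micrograph_id=mic,
                    x_px=x_A / apix,
                    y_px=y_A / apix,
                    origin_x_A=0.0,
                    origin_y_A=0.0,
                    pixel_size_A=apix,
                )
            )
    return ParticleTable(records=records, population=table.population)
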