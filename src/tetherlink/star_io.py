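"""Particle coordinate I/O for RELION-style STAR files.

A refinement particle table stores, per particle, the micrograph it was
picked from, the picked coordinate in pixels and (optionally) the origin
shift determined during 3D refinement, in Angstroms.  The refined position
in the micrograph plane is

    x_A = x_px * pixel_size_A - origin_x_A

and likewise for y.  Distances downstream are always computed on refined
positions in Angstroms, never in pixel space.

Parsing is delegated to :mod:`gemmi` (CIF/STAR); writing uses a fixed
RELION-styled text formatter so that seeded synthetic exports are
byte-reproducible.
"""

from __future__ import annotations

import posixpath
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Tuple

import gemmi
import numpy as np

from .errors import ParameterError, StarFormatError, StarParseError

__all__ = [
    "ParticleRecord",
    "ParticleTable",
    "read_particles",
    "refined_position",
    "write_particles",
]

_TAG_MICROGRAPH = "_rlnMicrographName"
_TAG_X = "_rlnCoordinateX"
_TAG_Y = "_rlnCoordinateY"
_TAG_ORIGIN_X_ANGST = "_rlnOriginXAngst"
_TAG_ORIGIN_Y_ANGST = "_rlnOriginYAngst"
_TAG_ORIGIN_X_PX = "_rlnOriginX"  # legacy (pixel units)
_TAG_ORIGIN_Y_PX = "_rlnOriginY"
_TAG_PIXEL_SIZE = "_rlnImagePixelSize"


@dataclass(frozen=True)
class ParticleRecord:
    """One picked/refined particle of a single population.

    Parameters
    ----------
    micrograph_id
        Opaque micrograph key; matching between populations is by this
        verbatim string (no path normalization unless requested at read
        time).
    x_px, y_px
        Picked coordinate in pixels.
    origin_x_A, origin_y_A
        Refinement origin shift in Angstroms; 0 when the refinement did
        not move the particle (or the column is absent).
    pixel_size_A
        Physical pixel size in Angstrom per pixel; must be positive.
    """

    micrograph_id: str
    x_px: float
    y_px: float
    origin_x_A: float = 0.0
    origin_y_A: float = 0.0
    pixel_size_A: float = 1.0

    def __post_init__(self) -> None:
        if not self.pixel_size_A > 0:
            raise ParameterError(
                f"pixel_size_A must be positive, got {self.pixel_size_A}"
            )
        pos = (
            self.x_px * self.pixel_size_A - self.origin_x_A,
            self.y_px * self.pixel_size_A - self.origin_y_A,
        )
        if not all(np.isfinite(pos)):
            raise ParameterError(f"refined position is not finite: {pos}")


def refined_position(record: ParticleRecord) -> Tuple[float, float]:
    """Refined in-plane position in Angstroms.

    RELION convention: refined = picked coordinate x pixel size minus the
    origin shift (origin shifts are stored in Angstroms).
    """
    return (
        record.x_px * record.pixel_size_A - record.origin_x_A,
        record.y_px * record.pixel_size_A - record.origin_y_A,
    )


@dataclass
class ParticleTable:
    """Particles of one population, grouped by micrograph."""

    records: List[ParticleRecord] = field(default_factory=list)
    population: str = "particles"

    def __len__(self) -> int:
        return len(self.records)

    def groups(self) -> Dict[str, List[ParticleRecord]]:
        """Partition of the records by micrograph id (insertion order)."""
        out: Dict[str, List[ParticleRecord]] = {}
        for rec in self.records:
            out.setdefault(rec.micrograph_id, []).append(rec)
        return out

    def micrograph_ids(self) -> List[str]:
        return list(self.groups().keys())

    def positions(self, micrograph_id: str) -> np.ndarray:
        """Refined positions (n, 2) in Angstroms for one micrograph."""
        recs = self.groups().get(micrograph_id, [])
        if not recs:
            return np.empty((0, 2), dtype=float)
        return np.asarray([refined_position(r) for r in recs], dtype=float)


def _find_particles_block(doc: "gemmi.cif.Document") -> "gemmi.cif.Block":
    for block in doc:
        if block.find_loop(_TAG_X):
            return block
    raise StarFormatError(
        f"no data block with a {_TAG_X} particle loop found"
    )


def _optics_pixel_size(doc: "gemmi.cif.Document") -> Optional[float]:
    for block in doc:
        if block.find_loop(_TAG_X):
            continue  # the particles block may itself carry the tag per row
        vals = block.find_values(_TAG_PIXEL_SIZE)
        if vals:
            try:
                return float(vals[0])
            except ValueError as exc:
                raise StarParseError(
                    f"non-numeric {_TAG_PIXEL_SIZE} in optics block: {vals[0]!r}"
                ) from exc
    return None


def _column(block, tag: str, required: bool) -> Optional[list]:
    col = block.find_loop(tag)
    if not col:
        if required:
            raise StarFormatError(f"missing required column {tag}")
        return None
    return list(col)


def read_particles(
    star_text: str,
    pixel_size_A: Optional[float] = None,
    population: str = "particles",
    basename_only: bool = False,
) -> ParticleTable:
    """Parse a particle STAR document into a :class:`ParticleTable`.

    The pixel size is taken from an optics block when present; a value
    passed explicitly must then agree (conflict is an error rather than a
    silent preference).  Origin-shift columns are optional and default to
    0; legacy pixel-unit origin columns are converted to Angstroms.

    Parameters
    ----------
    star_text
        STAR-format text with a particles loop carrying micrograph-name
        and X/Y coordinate tags.
    pixel_size_A
        Pixel size in Angstrom per pixel, required when the document has
        no optics block.
    population
        Label for the population ("tauA", "tauB", ...).
    basename_only
        Reduce micrograph ids to their basename, for matching tables whose
        paths differ.
    """
    doc = gemmi.cif.read_string(star_text)
    block = _find_particles_block(doc)

    optics_apix = _optics_pixel_size(doc)
    if optics_apix is not None and pixel_size_A is not None:
        if abs(optics_apix - pixel_size_A) > 1e-9:
            raise StarFormatError(
                f"pixel size conflict: optics block says {optics_apix}, "
                f"caller says {pixel_size_A}"
            )
    apix = optics_apix if optics_apix is not None else pixel_size_A
    if apix is None:
        raise StarFormatError(
            "pixel size not given and no optics block present"
        )
    if not apix > 0:
        raise ParameterError(f"pixel_size_A must be positive, got {apix}")

    names = _column(block, _TAG_MICROGRAPH, required=True)
    xs = _column(block, _TAG_X, required=True)
    ys = _column(block, _TAG_Y, required=True)
    ox = _column(block, _TAG_ORIGIN_X_ANGST, required=False)
    oy = _column(block, _TAG_ORIGIN_Y_ANGST, required=False)
    ox_px = _column(block, _TAG_ORIGIN_X_PX, required=False)
    oy_px = _column(block, _TAG_ORIGIN_Y_PX, required=False)

    records = []
    for i, name in enumerate(names):
        mic = gemmi.cif.as_string(name)
        if basename_only:
            mic = posixpath.basename(mic)
        try:
            x = float(xs[i])
            y = float(ys[i])
            origin_x = float(ox[i]) if ox is not None else (
                float(ox_px[i]) * apix if ox_px is not None else 0.0
            )
            origin_y = float(oy[i]) if oy is not None else (
                float(oy_px[i]) * apix if oy_px is not None else 0.0
            )
        except ValueError as exc:
            raise StarParseError(
                f"non-numeric coordinate in particle row {i}"
            ) from exc
        records.append(
            ParticleRecord(
                micrograph_id=mic,
                x_px=x,
                y_px=y,
                origin_x_A=origin_x,
                origin_y_A=origin_y,
                pixel_size_A=apix,
            )
        )
    return ParticleTable(records=records, population=population)


def write_particles(table: ParticleTable) -> str:
    """Serialize a table to RELION-styled STAR text.

    The inverse of :func:`read_particles` up to floating-point formatting
    (coordinates survive a round trip to within 1e-6 of a pixel).  All
    records must share one pixel size, which is emitted as an optics
    block.  An empty table yields a valid document with a header and no
    rows.
    """
    apix_values = {r.pixel_size_A for r in table.records}
    if len(apix_values) > 1:
        raise StarFormatError(
            f"records carry {len(apix_values)} distinct pixel sizes; "
            "write one table per optics group"
        )
    apix = apix_values.pop() if apix_values else 1.0

    lines = [
        "",
        "# version 30001",
        "",
        "data_optics",
        "",
        "loop_",
        "_rlnOpticsGroup #1",
        f"{_TAG_PIXEL_SIZE} #2",
        f"1 {apix:.6f}",
        "",
        "data_particles",
        "",
        "loop_",
        f"{_TAG_MICROGRAPH} #1",
        f"{_TAG_X} #2",
        f"{_TAG_Y} #3",
        f"{_TAG_ORIGIN_X_ANGST} #4",
        f"{_TAG_ORIGIN_Y_ANGST} #5",
    ]
    for r in table.records:
        lines.append(
            f"{r.micrograph_id} {r.x_px:.6f} {r.y_px:.6f} "
            f"{r.origin_x_A:.6f} {r.origin_y_A:.6f}"
        )
    return "\n".join(lines) + "\n"
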