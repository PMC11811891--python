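"""Filter-binding quantification and duplex-DNA utilities.

Two small, self-contained analyses around the structural work:

* the nitrocellulose filter-binding curve — retained radioactive counts
  versus protein concentration — normalized and fitted to the hyperbolic
  binding isotherm (Hill equation with the coefficient fixed at 1),

      fraction bound = c / (Kd + c),

  where Kd is the dissociation constant in nM; and

* in-silico annealing and molecular weight of a double-stranded DNA
  promoter construct, by default summing anhydrous nucleoside-5'-
  monophosphate residue masses over both strands with no end-group
  correction.  For the 98-bp human TRR-TCT3-2 tRNA gene duplex this
  convention gives 60.55 kDa, i.e. 61 kDa at integer rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import optimize, stats

from .errors import AlphabetError, ParameterError

__all__ = [
    "TRR_TCT3_2_NONTEMPLATE",
    "BindingCurve",
    "BindingFit",
    "DuplexSequence",
    "hill_fraction",
    "fit_binding",
    "read_binding_table",
    "anneal",
    "duplex_mw",
    "duplex_mw_kda",
]

# Human TRR-TCT3-2 tRNA gene, nontemplate strand (98 nt): the mature-tRNA
# body with its A- and B-box internal promoter elements plus short
# flanking nucleotides, as used for complex reconstitution.
TRR_TCT3_2_NONTEMPLATE = (
    "ACGTGTCTGGCTCTGTGGCGCAATGGATAGCGCATTGGACTTCTAGATAGTTAGAGAAATT"
    "CAAAGGTTGTGGGTTCGAGTCCCACAGAGTCGCTTTT"
)

# anhydrous nucleoside-5'-monophosphate residue masses, Da
_RESIDUE_MASS_DA = {"A": 313.21, "C": 289.18, "G": 329.21, "T": 304.20}
# optional 5'-OH end correction per strand (replace 5'-phosphate by OH)
_FIVE_PRIME_OH_DA = -61.96
_AVG_DA_PER_BP = 650.0  # coarse rule-of-thumb convention


@dataclass
class BindingCurve:
    """A titration: protein concentrations (nM, strictly increasing) and
    raw retained-signal counts; ``fraction_bound`` is filled by the fit."""

    concentrations_nM: np.ndarray
    counts: np.ndarray
    fraction_bound: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.concentrations_nM = np.asarray(self.concentrations_nM, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.concentrations_nM.shape != self.counts.shape:
            raise ParameterError("concentrations and counts differ in length")
        if np.any(self.concentrations_nM <= 0):
            raise ParameterError("concentrations must be positive")
        if np.any(np.diff(self.concentrations_nM) <= 0):
            raise ParameterError("concentrations must be strictly increasing")
        if np.any(self.counts < 0):
            raise ParameterError("counts must be non-negative")


@dataclass
class BindingFit:
    """Result of a Hill (n=1) fit; ``success`` is False when the data show
    no overall binding signal, with the reason in ``message``."""

    kd_nM: Optional[float]
    plateau: Optional[float]
    residual_ss: Optional[float]
    success: bool
    message: str = ""


def hill_fraction(conc_nM: float, kd_nM: float) -> float:
    """Hyperbolic binding isotherm c/(Kd + c); Hill coefficient fixed at 1."""
    if kd_nM <= 0:
        raise ParameterError(f"kd_nM must be positive, got {kd_nM}")
    if conc_nM < 0:
        raise ParameterError(f"conc_nM must be >= 0, got {conc_nM}")
    return conc_nM / (kd_nM + conc_nM)


def fit_binding(curve: BindingCurve) -> Tuple[BindingFit, BindingCurve]:
    """Fit counts = plateau * c/(Kd + c) by least squares and normalize.

    The plateau (saturation signal) is a fitted parameter rather than the
    maximum observed count, so a noisy top point does not distort the
    normalization; fractions bound are reported relative to the fitted
    plateau.  Requires at least 4 points spanning a decade of
    concentration.  Data with no overall increase of signal with
    concentration return a failed fit with a diagnostic, not an
    exception.
    """
    c = curve.concentrations_nM
    y = curve.counts
    if c.size < 4:
        raise ParameterError("need at least 4 titration points")
    if c[-1] / c[0] < 10:
        raise ParameterError(
            "titration must span at least one decade of concentration"
        )
    if np.max(y) == 0:
        return (
            BindingFit(None, None, None, False, "all counts are zero"),
            curve,
        )
    rho = stats.spearmanr(c, y).statistic
    if not rho > 0:
        return (
            BindingFit(
                None, None, None, False,
                "counts do not increase with concentration (no binding)",
            ),
            curve,
        )

    def model(conc, plateau, kd):
        return plateau * conc / (kd + conc)

    p0 = (float(np.max(y)), float(np.sqrt(c[0] * c[-1])))
    try:
        popt, _ = optimize.curve_fit(
            model, c, y, p0=p0,
            bounds=([0.0, 1e-12], [np.inf, np.inf]),
            maxfev=10_000,
        )
    except RuntimeError as exc:
        return BindingFit(None, None, None, False, str(exc)), curve
    plateau, kd = float(popt[0]), float(popt[1])
    resid = y - model(c, plateau, kd)
    fit = BindingFit(
        kd_nM=kd,
        plateau=plateau,
        residual_ss=float(np.sum(resid**2)),
        success=True,
    )
    normalized = BindingCurve(
        concentrations_nM=c,
        counts=y,
        fraction_bound=np.clip(y / plateau, 0.0, 1.0),
    )
    return fit, normalized


def read_binding_table(tsv_text: str) -> BindingCurve:
    """Parse a two-column TSV (concentration with a unit-tagged header, counts).

    The concentration header must carry an explicit unit tag, ``nM`` or
    ``uM``/``µM``; micromolar values are converted to nM.
    """
    df = pd.read_csv(StringIO(tsv_text), sep="\t")
    if df.shape[1] < 2:
        raise ParameterError("binding table needs two columns")
    conc_col = df.columns[0]
    header = conc_col.lower()
    if "nm" in header:
        scale = 1.0
    elif "um" in header or "µm" in header or "μm" in header:
        scale = 1000.0
    else:
        raise ParameterError(
            f"concentration column {conc_col!r} must be tagged with a unit "
            "(nM or uM)"
        )
    return BindingCurve(
        concentrations_nM=df.iloc[:, 0].to_numpy(dtype=float) * scale,
        counts=df.iloc[:, 1].to_numpy(dtype=float),
    )


@dataclass
class DuplexSequence:
    """A blunt double-stranded DNA: nontemplate strand and its reverse
    complement."""

    nontemplate: str
    template: str
    length_bp: int


def anneal(nontemplate: str) -> DuplexSequence:
    """In-silico annealing: pair a strand with its exact reverse complement.

    Input is case-insensitive and restricted to A/C/G/T; ambiguity codes
    are rejected with the 1-based position of the first offending
    character.
    """
    seq = nontemplate.upper()
    if not seq:
        raise AlphabetError("empty sequence")
    for i, ch in enumerate(seq):
        if ch not in "ACGT":
            raise AlphabetError(
                f"non-ACGT character {ch!r} at position {i + 1}"
            )
    template = str(Seq(seq).reverse_complement())
    return DuplexSequence(nontemplate=seq, template=template, length_bp=len(seq))


def duplex_mw(duplex: DuplexSequence, convention: str = "residue") -> float:
    """Molecular weight of the duplex in daltons.

    Conventions:

    * ``"residue"`` (default): sum of anhydrous nucleoside-5'-monophosphate
      residue masses (A 313.21, C 289.18, G 329.21, T 304.20 Da) over both
      strands, no end-group correction;
    * ``"5p-oh"``: as above minus 61.96 Da per strand (5'-OH ends);
    * ``"650-per-bp"``: the coarse 650 Da per base pair rule.
    """
    if duplex.length_bp == 0:
        raise ParameterError("empty duplex")
    if convention == "650-per-bp":
        return _AVG_DA_PER_BP * duplex.length_bp
    total = sum(_RESIDUE_MASS_DA[ch] for ch in duplex.nontemplate)
    total += sum(_RESIDUE_MASS_DA[ch] for ch in duplex.template)
    if convention == "residue":
        return total
    if convention == "5p-oh":
        return total + 2 * _FIVE_PRIME_OH_DA
    raise ParameterError(f"unknown mass convention {convention!r}")


def duplex_mw_kda(duplex: DuplexSequence, convention: str = "residue") -> int:
    """Duplex molecular weight in kDa, rounded to the nearest integer."""
    return int(round(duplex_mw(duplex, convention) / 1000.0))
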