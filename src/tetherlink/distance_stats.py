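"""Distance-distribution statistics: histogram, mode, observed-vs-null.

The readout of the pairing analysis is the pooled histogram of pair
distances.  A flexible tether of fixed anchoring produces a distinct
peak (for a planar projection of an isotropic 3-D Gaussian displacement,
a Rayleigh-shaped bump with mode at the tether scale sigma), whereas
randomly co-occurring particles produce the broad distance distribution
of a uniform spatial point pattern.  The observed histogram is therefore
compared to the randomized-coordinate null: the per-bin excess isolates
the linked-pair signal, and a two-sample Kolmogorov-Smirnov statistic
quantifies the overall difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .errors import ParameterError, UndefinedModeError

__all__ = [
    "DistanceDistribution",
    "NullComparison",
    "histogram",
    "mode_estimate",
    "kde_mode",
    "compare_to_null",
    "fit_excess_peak",
    "bootstrap_mode_ci",
    "ks_critical_value",
]


@dataclass
class DistanceDistribution:
    """Binned pair-distance histogram.

    Bins are half-open ``[k*w, (k+1)*w)`` starting at 0, with enough bins
    to cover the maximum distance.
    """

    bin_width_A: float
    bin_edges_A: np.ndarray
    counts: np.ndarray
    label: str = "observed"
    n_total: int = 0

    @property
    def bin_centers_A(self) -> np.ndarray:
        return self.bin_edges_A[:-1] + self.bin_width_A / 2.0


@dataclass
class NullComparison:
    """Observed-minus-null comparison on a shared binning.

    Two peak readouts are reported.  ``excess_peak_bin_center_A`` is the
    center of the maximal-excess bin — the direct histogram readout.
    ``excess_peak_fit_A`` is the package's headline estimator: the mode
    of a tether-model (Rayleigh plus linear background) least-squares
    fit to the same binned excess.  The distinction matters because a
    Rayleigh is flat to within ~2% over +/-20% of its mode, so with a
    few thousand pairs the maximal 20-A bin wanders over several bins
    from sample to sample, while the shape fit pools all bins and is
    stable to a few Angstroms.
    """

    bin_edges_A: np.ndarray
    excess: np.ndarray  # observed count minus mean null count, per bin
    ks_statistic: float
    excess_peak_bin_center_A: float
    excess_peak_fit_A: float
    n_observed: int
    n_null_mean: float


def _bin_indices(d: np.ndarray, bin_width_A: float) -> np.ndarray:
    return np.floor_divide(d, bin_width_A).astype(int)


def histogram(
    distances: Sequence[float],
    bin_width_A: float,
    label: str = "observed",
    n_bins: Optional[int] = None,
) -> DistanceDistribution:
    """Bin non-negative distances into half-open bins of width ``bin_width_A``.

    ``n_bins`` forces a fixed number of bins (used for shared observed /
    null binning); by default just enough bins cover the maximum.  An
    empty input yields an empty one-bin distribution and a warning.
    """
    if bin_width_A <= 0:
        raise ParameterError(f"bin_width_A must be positive, got {bin_width_A}")
    d = np.asarray(distances, dtype=float)
    if d.size and d.min() < 0:
        raise ParameterError("distances must be non-negative")
    if d.size == 0:
        warnings.warn("empty distance list; empty distribution", stacklevel=2)
        edges = np.array([0.0, bin_width_A])
        return DistanceDistribution(
            bin_width_A=bin_width_A,
            bin_edges_A=edges,
            counts=np.zeros(1, dtype=int),
            label=label,
            n_total=0,
        )
    idx = _bin_indices(d, bin_width_A)
    k = int(idx.max()) + 1 if n_bins is None else n_bins
    counts = np.bincount(idx, minlength=k)
    edges = bin_width_A * np.arange(k + 1, dtype=float)
    return DistanceDistribution(
        bin_width_A=bin_width_A,
        bin_edges_A=edges,
        counts=counts.astype(int),
        label=label,
        n_total=int(d.size),
    )


def mode_estimate(dist: DistanceDistribution) -> float:
    """Center of the maximal-count bin; ties resolve to the smallest center."""
    if dist.n_total == 0:
        raise UndefinedModeError("mode of an empty distribution is undefined")
    return float(dist.bin_centers_A[int(np.argmax(dist.counts))])


def kde_mode(
    distances: Sequence[float],
    grid_step_A: float = 1.0,
    bw_method: Optional[float] = None,
) -> float:
    """Gaussian-KDE mode, a smooth alternative to the histogram mode."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise UndefinedModeError("mode of an empty sample is undefined")
    if np.ptp(d) == 0:
        return float(d[0])
    kde = stats.gaussian_kde(d, bw_method=bw_method)
    grid = np.arange(0.0, d.max() + grid_step_A, grid_step_A)
    return float(grid[int(np.argmax(kde(grid)))])


def fit_excess_peak(excess: np.ndarray, bin_edges_A: np.ndarray) -> float:
    """Tether-model peak of a binned excess curve, in Angstroms.

    Fits ``amp * (r/sigma^2) exp(-r^2 / 2 sigma^2) + c * r`` to the
    excess counts by least squares and returns the fitted mode (sigma of
    the Rayleigh component).  The linear term absorbs the leading-order
    residual between the observed background and the randomized null,
    both of which grow proportionally to r at short distances.  Fitting
    is restricted to bins below three times the running peak estimate
    (two refinement passes), initialized from a 5-bin-smoothed argmax.
    Falls back to the raw argmax bin center if the fit does not
    converge.
    """
    excess = np.asarray(excess, dtype=float)
    edges = np.asarray(bin_edges_A, dtype=float)
    w = edges[1] - edges[0]
    centers = edges[:-1] + w / 2.0
    argmax_center = float(centers[int(np.argmax(excess))])
    if excess.size < 5:
        return argmax_center
    smoothed = np.convolve(excess, np.ones(5) / 5.0, mode="same")
    peak = float(centers[int(np.argmax(smoothed))])

    def model(r, amp, sigma, slope):
        return amp * r / sigma**2 * np.exp(-(r**2) / (2 * sigma**2)) + slope * r

    for _ in range(2):
        window = centers <= 3.0 * peak
        if window.sum() < 4:
            return argmax_center
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, _ = optimize.curve_fit(
                    model,
                    centers[window],
                    excess[window],
                    p0=(max(float(excess[window].sum()) * w, 1.0), peak, 0.0),
                    maxfev=20_000,
                )
        except RuntimeError:
            return argmax_center
        peak = abs(float(popt[1]))
    return peak


def compare_to_null(
    observed: Sequence[float],
    null: Sequence[float],
    bin_width_A: float,
    n_null_replicates: int = 1,
) -> NullComparison:
    """Per-bin excess of observed counts over the (mean) null, plus a KS statistic.

    ``null`` may pool several randomization replicates; its histogram is
    then divided by ``n_null_replicates`` so the excess lives on the
    observed count scale.  The KS statistic is computed on the raw
    samples, not the binned counts.
    """
    obs = np.asarray(observed, dtype=float)
    nul = np.asarray(null, dtype=float)
    if obs.size == 0:
        raise ParameterError("observed sample is empty")
    if nul.size == 0:
        raise ParameterError("null sample is empty")
    if n_null_replicates < 1:
        raise ParameterError("n_null_replicates must be >= 1")

    max_all = max(obs.max(), nul.max())
    k = int(np.floor_divide(max_all, bin_width_A)) + 1
    h_obs = histogram(obs, bin_width_A, label="observed", n_bins=k)
    h_nul = histogram(nul, bin_width_A, label="null", n_bins=k)
    mean_null = h_nul.counts / float(n_null_replicates)
    excess = h_obs.counts - mean_null
    ks = float(stats.ks_2samp(obs, nul).statistic)
    peak = float(h_obs.bin_centers_A[int(np.argmax(excess))])
    return NullComparison(
        bin_edges_A=h_obs.bin_edges_A,
        excess=excess,
        ks_statistic=ks,
        excess_peak_bin_center_A=peak,
        excess_peak_fit_A=fit_excess_peak(excess, h_obs.bin_edges_A),
        n_observed=int(obs.size),
        n_null_mean=float(nul.size) / n_null_replicates,
    )


def bootstrap_mode_ci(
    distances: Sequence[float],
    bin_width_A: float,
    n_boot: int = 200,
    seed: int = 0,
) -> Tuple[float, float]:
    """Percentile 95% interval of the histogram mode over bootstrap resamples.

    Deterministic given ``seed``; refuses samples smaller than 10, for
    which a resampled mode is meaningless.
    """
    d = np.asarray(distances, dtype=float)
    if d.size < 10:
        raise ParameterError(
            f"need at least 10 distances to bootstrap a mode, got {d.size}"
        )
    rng = np.random.default_rng(seed)
    modes = np.empty(n_boot)
    for i in range(n_boot):
        resample = rng.choice(d, size=d.size, replace=True)
        modes[i] = mode_estimate(histogram(resample, bin_width_A))
    lo, hi = np.percentile(modes, [2.5, 97.5])
    return float(lo), float(hi)


def ks_critical_value(n1: int, n2: int, alpha: float = 0.01) -> float:
    """Asymptotic two-sample KS critical value c(alpha)*sqrt((n1+n2)/(n1*n2))."""
    if n1 < 1 or n2 < 1:
        raise ParameterError("sample sizes must be positive")
    c_alpha = np.sqrt(-np.log(alpha / 2.0) / 2.0)
    return float(c_alpha * np.sqrt((n1 + n2) / (n1 * n2)))
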