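# Methods

## Coordinate model

A particle table holds, per particle, a micrograph identifier, a picked
coordinate in pixels, and an origin shift in Å determined during 3-D
refinement. The refined in-plane position is

    x_A = x_px · apix − origin_x_A,    y_A = y_px · apix − origin_y_A,

with `apix` the physical pixel size in Å/px (taken from the optics block
when the STAR file has one; a conflicting caller-supplied value is an
error, never silently preferred). Legacy origin columns in pixel units
are converted by multiplying by `apix`. Micrograph identity is the
verbatim name string; an opt-in flag reduces names to basenames for
tables whose paths differ. The y axis is never flipped: all downstream
quantities are Euclidean distances, which are invariant to axis
orientation. Distances are always computed in Å after refinement-shift
correction; no pixel-space pairing is offered, to prevent unit mix-ups.

## Greedy delete-min pairing

Per micrograph the pairing repeatedly selects the global minimum of the
N_τB × N_τA distance matrix, records the pair, and removes its row and
column, stopping when either population is exhausted. This is
deliberately *not* the minimum-total-cost assignment: molecules are
identified one at a time, nearest first, and a particle is never paired
twice. Consequences used as invariants (and tested): the pair count per
micrograph is exactly min(N_τB, N_τA), and selection-order distances are
nondecreasing, because deleting a row and column cannot decrease the
remaining minimum.

Ties are broken by smallest row index, then smallest column index (the
first occurrence in row-major order). Real-valued coordinates make ties
measure-zero, but synthetic fixtures hit them; the rule makes results
deterministic and order-stable. Micrographs present in only one table
contribute no pairs and are listed in a skip log; zero shared
micrographs warns rather than raises.

## Randomized null

The null keeps every per-micrograph particle multiplicity and re-draws
coordinates i.i.d. uniform on [0, W) × [0, H), then runs the identical
pairing. Field extents come from configuration; when omitted they are
derived from the data as the maximum observed coordinate per axis, with
a warning, since data-derived extents bias the null slightly inward.
The default replicate count is 10; null histograms are pooled by
per-bin mean (not concatenation) so the excess lives on the observed
count scale and total excess equals n_obs − mean n_null exactly.

## Distance readout and the two peak estimators

Distances are binned into half-open bins [k·w, (k+1)·w) starting at 0,
default width 20 Å (configurable). The per-bin excess is the observed
count minus the mean null count on a shared binning spanning both
samples; a two-sample Kolmogorov–Smirnov statistic on the raw samples
summarizes the overall difference.

Two peak readouts are reported, and the distinction is deliberate:

* `excess_peak_bin_center_A` — the center of the maximal-excess bin,
  the direct histogram readout.
* `excess_peak_fit_A` — the mode of a least-squares fit of
  amp · (r/σ²)·exp(−r²/2σ²) + c·r to the same binned excess.

The tether model underlying the fit is the package's displacement model
(below): the planar projection of an isotropic 3-D Gaussian is
Rayleigh(σ), whose mode is σ. A Rayleigh is flat to within ~2% over
±20% of its mode, so with a few thousand pairs the maximal 20-Å bin
wanders over several bins from sample to sample (simulation: even a
perfect Rayleigh(200) sample of n ≈ 1600 puts its maximal bin inside
[180, 220] Å with probability only ≈ 0.4). The shape fit pools all bins
and is stable to a few Å, which is why it is the headline estimator;
the argmax readout is kept for transparency. The linear nuisance term
c·r absorbs the leading-order residual between the observed unlinked
background and the randomized null: both pair-distance densities grow
proportionally to r at short range, with slightly different
coefficients, and without the term this residual compresses the fit's
right flank and biases σ low by ~10–15% at realistic densities. The fit
window is restricted to r ≤ 3× the running peak estimate (two passes,
initialized from a 5-bin-smoothed argmax) and falls back to the argmax
center if the optimizer fails. A Gaussian-KDE mode is available as a
smoothness check; the histogram mode remains the default single-sample
mode estimator, with a percentile bootstrap (default 200 resamples,
seeded) for its 95% interval.

## Synthetic scenes

Each micrograph receives `pairs_per_micrograph` anchor points uniform in
the field; a τB particle sits at the anchor and its τA partner at the
anchor plus the 2-D projection of an isotropic 3-D Gaussian displacement
with per-axis scale σ (`tether_sigma_A`, default 200 Å). The projected
pair distance is therefore Rayleigh(σ): mode σ, mean σ√(π/2).
Displacements leaving the field are re-drawn (truncation, not
clipping); the induced bias is negligible for σ ≪ field. Each emitted
particle survives independently with its species' detection probability
(default 0.9), free unlinked particles of both species are placed
uniformly (default 10 each), and the truth ledger records pairs with
both members retained, with within-micrograph indices matching the
pairing algorithm's. One global seed spawns independent per-micrograph
substreams, so micrograph i is identical whether 10 or 10,000
micrographs are generated.

Default geometry: 100 micrographs of 14,000 × 14,000 Å. The field size
is the one genuinely free parameter and was set by a regime argument:
with ~28 particles per species per micrograph, the expected number of
unrelated particles inside the 3σ tether disc of any particle is
ρ·π(3σ)² ≈ 0.16 ≪ 1, so greedy pairing can isolate genuine partners —
the regime in which the pairing readout is meaningful, and within a
factor ~2 of the areal particle density of the motivating dataset
(3–5 refined particles per 0.47 × 0.34 µm micrograph, ρ ≈ 2.6·10⁻⁷ Å⁻²,
giving ρ·π(3σ)² ≈ 0.29). At substantially higher densities the
observed−null excess remains but its peak is structurally biased low:
partner-stealing truncates long tether distances and the null's
chance-close pairs suppress the excess's right flank. The generator
makes no claim about converting linker residue counts to Å; σ is a free
parameter. Body-size offsets are not modeled (separations are
center-to-center, as picked coordinates behave), there is no image-level
simulation (no CTF, no noise), and the τB particles are treated as
single points.

What passing the recovery tests shows — and does not. The scenes
reproduce the coordinate-level structure of the problem: two
populations on shared micrographs, a stochastic projected tether,
unlinked background, detection loss. They do not reproduce picking
correlations, micrograph-edge effects, local clustering/aggregation, or
orientation-dependent detection; a recovery on synthetic scenes
validates the algorithmic chain, not the absence of such confounders in
real data.

## Binding curve

Retained counts are fitted to plateau · c/(K_d + c) — the Hill isotherm
with coefficient fixed at 1 — by nonlinear least squares over a
titration that must span at least a decade with ≥ 4 points. The plateau
is a fitted parameter rather than max(counts): normalizing by a noisy
top point would distort all fractions. Fractions bound are reported
relative to the fitted plateau, clipped to [0, 1]. "No binding" is
detected as zero signal everywhere or a non-positive Spearman
correlation of counts with concentration, and returns a failure
diagnostic rather than an exception. Concentrations are nM in the data
model; the table reader requires an explicit unit tag (nM or µM) and
converts.

## Duplex molecular weight

Default convention: sum of anhydrous nucleoside-5′-monophosphate
residue masses (A 313.21, C 289.18, G 329.21, T 304.20 Da) over both
strands, no end-group correction; kDa values round to the nearest
integer. For the bundled 98-bp TRR-TCT3-2 duplex this gives 60,552.24 Da
→ 61 kDa. Alternative conventions are available behind flags and are
clearly non-default: 5′-OH ends (−61.96 Da per strand) and the coarse
650 Da/bp rule. Ambiguity codes are rejected loudly; the analysis never
needs them.

## Conservation scoring

Protein columns: residues map to seven physicochemical classes —
default {AVLIMC} {FWYH} {STNQ} {KR} {DE} {G} {P}, fully overridable —
and the score is 1 − H/ln 7 with H the natural-log Shannon entropy of
the class frequencies among non-gap residues. The ln 7 normalization
makes the score exactly 1 for invariant columns and exactly 0 for
class-uniform columns; it is one member of the reduced-alphabet entropy
family, and no byte-compatibility with any external scoring tool is
claimed. Gaps are excluded from the frequency vector; all-gap columns
get an undefined-score sentinel and are never framed; columns with
> 50% gaps are flagged low-confidence (alignments for this kind of
analysis are normally trimmed of heavily gapped columns). Conserved
positions are framed at score strictly greater than 0.9 by default.
DNA columns report information content 2 − H₂ bits, the stack-height
basis of sequence logos, without small-sample correction. The synthetic
MSA generator produces seeded alignments with per-column known
substitution probabilities (consensus symbol replaced by a uniform
random alternative), giving ground truth for monotonicity and framing
tests. Alignment construction itself is out of scope; the module
consumes alignments.

## Problem sizes and numerical choices

Validation runs use 100 micrographs × 20 pairs (≈ 2,700 pairings per
scene, 10 null replicates) for tether-scale recovery, 25 micrographs of
free particles × 100 seeds for null calibration, 50 seeded repeats for
Hill-fit recovery, and ≤ 6×6 matrices × 100 for the pairing oracle —
sizes at which every stochastic check is stable while the whole suite
runs in well under a minute. Optimizer settings: `curve_fit` with
positivity bounds for the Hill fit (initial plateau = max counts,
initial K_d = geometric mid-range); the excess-peak fit is unbounded
with |σ| taken, 20,000 max evaluations. Degenerate inputs are handled
explicitly: empty tables round-trip as valid empty STAR documents,
zero-extent distance matrices pair to nothing, empty distance lists
produce flagged empty histograms, σ = 0 tethers give exactly coincident
partners.

## Known limitations

The greedy pairing is order-greedy, not globally optimal, by design —
it mirrors the single-molecule identification logic, and the oracle
test pins that exact behavior. The excess-peak fit assumes the tether
signal is approximately Rayleigh; a strongly non-Gaussian linker
(e.g., worm-like-chain at short contour length) would shift the fitted
mode, and no mechanistic polymer model is fitted. The randomized null
ignores micrograph-edge exclusion and any spatial inhomogeneity of
picking. Conservation scores are unweighted (no tree or redundancy
weighting), so phylogenetically clustered alignments overweight dense
clades.
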