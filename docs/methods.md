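# Methods

## Decay model and time base

A TCSPC acquisition bins photon arrivals into 1,250 channels of 20 ps,
spanning one 25 ns repetition period of a 40 MHz pulsed laser. The donor
decay is modelled as a two-species mixture

    I(t) = I0 [ f_D exp(-t/tau_F) + (1 - f_D) exp(-t/tau_D) ],

where f_D is the **pre-exponential (amplitude) fraction** of donors
quenched by FRET. A consequence worth keeping in mind everywhere in this
package: because a species' photon yield is amplitude × lifetime, the
FRET species at f_D = 0.17 contributes only
0.17·0.83 / (0.17·0.83 + 0.83·2.65) ≈ 6% of the photons. Expected counts
per channel are exact integrals of I(t) over the channel, scaled so the
infinite-window photon total equals `total_intensity`, convolved with the
unit-sum IRF, plus a uniform per-channel background (default 0; dark
counts can be supplied). Counting noise is independent Poisson per
channel, the physics of photon counting.

Repetition-period wraparound (incomplete decay) is available via
`wrap=True` but off by default: with tau_D = 2.65 ns and a 25 ns period
the wrapped tail is exp(-25/2.65) ≈ 8·10⁻⁵ of I0, negligible, but the
flag makes the effect testable.

The IRF defaults to a Gaussian of 100 ps fwhm centered 0.5 ns into the
window — a typical shape for a hybrid-detector confocal system — and a
tabulated per-channel histogram can be supplied instead. A delta IRF
helper exists for oracle tests.

## Reconvolution fitting

The fitters convolve the candidate model with the IRF inside the
objective (iterative reconvolution); direct deconvolution of the data is
numerically unstable and not offered. Residuals are evaluated over
`analysis_channels` (default 1,200) channels starting at the IRF peak
channel.

Two objectives:

* **Poisson maximum likelihood (default).** TCSPC histograms are Poisson
  counts; at imaging photon budgets (hundreds of photons over a thousand
  channels) most channels hold 0–2 counts, where chi-square weighting is
  known to be biased. Measured on this implementation, Neyman-weighted
  least squares underestimates a 2.65 ns lifetime by ≈ 2% at 10⁵ photons
  and inflates f_D by up to +0.05 at 600 photons; the Poisson objective
  shows neither effect. Standard errors come from the observed Fisher
  information at the optimum.
* **Weighted least squares** with Neyman weights 1/max(c, 1), the
  classical Marquardt-style choice, retained for high-count work and for
  the exact noiseless oracle tests.

Bounds (f_D ∈ [0, 1], honouring pre-exponential fractions; lifetimes and
amplitudes positive) are enforced by the trust-region-reflective
box-bound solver rather than a sigmoid reparameterization: identical
constraint, and no gradient saturation at the f_D = 0 boundary that
donor-only data sits on. Initialization is deterministic — lifetime from
the barycenter of the decay, f_D = 0.3, amplitude from total counts —
so fits are exactly reproducible. Convergence is a relative objective
change below 10⁻⁸ (500 iteration cap); non-convergence is flagged on the
result, never silent. Decays under the photon threshold (default 150,
the acquisition floor per binned pixel) raise a `LowSignalError`.

**Identifiability.** With tau_D fixed, the pair (f_D, tau_F) is jointly
estimable only with ample photons. At ~600 photons per decay the profile
is nearly flat along a ridge where tau_F drifts toward tau_D while f_D
grows; population means of f_D become meaningless (we measure ≈ 0.42 at
truth 0.17). The supported workflow therefore fixes tau_F at the value
obtained from pooled/high-count fits (0.83 ns here) when fitting
pixel- or cell-scale decays, exactly as the fixed-lifetime map formula
does. A tau_F estimate landing within 10% of tau_D is reported with an
explicit identifiability warning. Even with both lifetimes fixed, the
Cramér–Rao bound at 600 photons gives sd(f̂_D) ≥ 0.09–0.13, so
single-decay f_D values are population material, not per-cell claims —
and near f_D = 0 the [0, 1] bound induces a positive truncation bias of
up to ≈ +0.03 in population means, visible in the donor-only surrogate.

## Pixel-wise maps

2×2 spatial binning is a sliding-window sum that preserves image
dimensions (edge pixels sum their available neighbors), matching common
FLIM-software behaviour; a stride-2 block-sum variant exists for exact
photon-conservation checks.

The mean lifetime ⟨τ⟩ of a pixel is the barycenter (first temporal
moment) of its histogram over the first 1,200 channels from the decay
origin, with channel midpoints measured from the start of the origin
channel. The origin is the IRF peak channel; when no IRF is available it
is estimated as the steepest-rise channel of the summed decay (the
rising edge follows the IRF's cumulative profile, whereas the count
maximum sits on a flat top ~0.2 ns later). Two small systematics are
inherent and documented rather than hidden: the 24 ns truncation lowers
a pure 2.65 ns decay to 2.647 ns (closed form
τ − T e^{−T/τ}/(1 − e^{−T/τ})), and starting the window at the IRF peak
excludes the early half of the IRF-spread photons, raising ⟨τ⟩ by
≈ +0.012 ns for the default 100 ps IRF. Both are common mode across
pixels and groups. Pixels under the photon threshold are masked with NaN
(never 0) and excluded from every downstream statistic.

Two f_D estimators convert ⟨τ⟩, both clipped to [0, 1] with out-of-range
pixels flagged:

* `linear`: f_D = (τ_D − ⟨τ⟩)/(τ_D − τ_F). Exact if ⟨τ⟩ were the
  amplitude-weighted mean lifetime; applied to the barycenter (which is
  intensity-weighted) it systematically **underestimates** interior f_D
  — e.g. ⟨τ⟩ = 2.52 ns maps to 0.071. This is the conventional
  image-workflow formula and the default.
* `intensity-weighted-inversion`:
  f_D = τ_D(τ_D − ⟨τ⟩)/((τ_D − τ_F)(τ_D + τ_F − ⟨τ⟩)), the exact inverse
  of the barycenter's infinite-window expectation
  (f τ_F² + (1−f) τ_D²)/(f τ_F + (1−f) τ_D); ⟨τ⟩ = 2.52 ns maps to
  0.197. On noiseless stacks it recovers truth maps to < 0.01.

The two are mutually inconsistent by construction; published per-pixel
map values and per-cell fitted fractions generally cannot be reconciled
without knowing which convention produced them, so this package exposes
both behind a config switch and never silently mixes them.

## Efficiency, distance, uncertainties

E = 1 − τ_F/τ_D and r = R₀((1−E)/E)^{1/6} with R₀ = 57 Å for
mTFP1/mVenus taken as a configuration constant (spectral-overlap
integration is out of scope). Uncertainties are first-order delta
method, from lifetime sds or directly from an observed across-cell
spread of E; sds are exactly linear in the input sds and zero for exact
inputs. Distances are reported to 0.1 Å.

## Per-cell statistics

Cell summaries average ⟨τ⟩ and f_D over valid pixels inside a whole-cell
ROI, unweighted by default (photon weighting available). Group
comparisons use the two-sample t-test, pooled-variance ("student") by
default with Welch available. Independence of f_D from expression level
is operationalized as Spearman correlation between the per-cell
donor/acceptor intensity ratio and mean f_D, with a seeded permutation
p-value (9,999 permutations; p ∈ [1/(n+1), 1]); degenerate inputs
(constant f_D) are reported as not assessable rather than raising.

## Binding

Steady-state SPR responses are fitted to R = Rmax·C/(K_d + C) by
nonlinear least squares with deterministic initialization (Rmax at the
maximal response, K_d at the concentration nearest half-max). Flags —
never silent failures — mark fewer than four distinct concentrations, a
K_d outside the sampled range by >10×, or optimization failure. A
condition is called not-detectable when the one-site fit does not
improve on a zero-response model by an extra-sum-of-squares F-test at
α = 0.01 (or the maximal response is under an optional threshold),
mirroring competed/deglycosylated conditions. Competition additives are
metadata labels; each condition is an independent series. Kinetic
(on/off-rate) and mass-transport modelling are out of scope.

## Synthetic scenes: what they do and do not emulate

Scenes place hard-disk "endosome" puncta on a diffuse background inside
an elliptical cell mask; per-pixel expected photons come from the scene,
lifetimes and background from the decay parameters, and each stack
carries its ground-truth maps. Defaults emulate the studied acquisitions:
a donor-only cell at ~400 photons per binned pixel with f_D ≡ 0, and a
co-expression cell at ~600 photons per binned pixel with puncta at
f_D = 0.35 over a 0.15 diffuse background. The generator reproduces the
statistical structure the analysis assumes — Poisson counting on an
IRF-convolved biexponential with punctate spatial intensity — but not
optical blur, detector afterpulsing, autofluorescence spectra, cell-to-
cell lifetime heterogeneity, or motion. Passing tests therefore validate
the estimators under the model's own assumptions; they do not certify
instrument-specific artifacts.

## Problem sizes in the standard runs

The bundled checks use 200 decay replicates per recovery setting at 600
photons, 20 donor calibration fits at 10⁵ photons, ten 48×48 cells per
group for the imaging comparison, 100 noisy replicates per binding
affinity, and 9,999 permutations for the independence test — sizes
chosen so each check pins its quantity well inside the asserted
tolerance while a full run stays in the seconds-to-minutes range on one
core.

## Known limitations

* Vendor photon-stream formats are not parsed; stacks travel as
  multi-page TIFF or HDF5 with explicit metadata, decays and binding
  series as delimited text.
* The barycenter origin convention (IRF peak) shifts ⟨τ⟩ uniformly; maps
  produced with a different origin convention differ by a constant and
  should not be mixed.
* Background is uniform in time; structured afterglow is not modelled.
* Standard errors from the WLS objective at very low counts inherit the
  weighting bias; use the Poisson objective there.
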