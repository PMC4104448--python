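# flimfret

Quantification of protein–protein interactions in living cells from
time-domain fluorescence lifetime imaging (FLIM-FRET), together with
equilibrium binding analysis of surface-plasmon-resonance (SPR) series.

The package is written for cell biologists and microscopists who acquire
time-correlated single photon counting (TCSPC) FLIM data of a FRET donor
(e.g. mTFP1 fused to a membrane protein) in the presence of an acceptor
(e.g. mVenus on a candidate partner) and want to turn per-pixel photon
histograms into interacting-fraction maps, per-cell statistics, and
donor–acceptor distances — and for anyone fitting steady-state SPR
responses to a one-site saturation isotherm.

## The model

A donor population in which a fraction *f*<sub>D</sub> interacts with an
acceptor decays as a two-species mixture,

&nbsp;&nbsp;&nbsp;&nbsp;*I*(*t*) = *I*₀ [ *f*<sub>D</sub> e<sup>−*t*/τ<sub>F</sub></sup> + (1 − *f*<sub>D</sub>) e<sup>−*t*/τ<sub>D</sub></sup> ],

with τ<sub>D</sub> the unperturbed donor lifetime (fixed from
donor-only cells, ≈ 2.65 ns for mTFP1) and τ<sub>F</sub> the shortened
FRET lifetime (≈ 0.83 ns). The model, convolved with the instrument
response function (IRF), is fitted to the measured histogram by iterative
reconvolution (Poisson maximum likelihood by default, Marquardt weighted
least squares optionally), with the pre-exponential fractions constrained
to [0, 1].

Pixel-wise, the mean lifetime ⟨τ⟩ is the barycenter of the decay over the
first 1,200 channels (20 ps each) after 2×2 spatial binning, and is
converted to an *f*<sub>D</sub> map via either the linear form
*f*<sub>D</sub> = (τ<sub>D</sub> − ⟨τ⟩)/(τ<sub>D</sub> − τ<sub>F</sub>)
or the exact inversion of the intensity-weighted mean lifetime (see
`docs/methods.md` for why the two differ).

The true FRET efficiency and donor–acceptor distance follow from

&nbsp;&nbsp;&nbsp;&nbsp;*E* = 1 − τ<sub>F</sub>/τ<sub>D</sub>,&nbsp;&nbsp;&nbsp;&nbsp;*E* = 1 / (1 + (*r*/*R*₀)⁶),

with *R*₀ = 57 Å for the mTFP1/mVenus pair. Binding series are fitted to
*R* = *R*<sub>max</sub>·*C*/(*K*<sub>d</sub> + *C*); flat (e.g.
sugar-competed) conditions are called not-detectable by an
extra-sum-of-squares test.

Because raw FLIM acquisitions are rarely shared, the package includes a
first-class synthetic-data module (`flimfret.sim`) that generates decays
and punctate image stacks with known ground truth — Poisson counting
noise, IRF convolution, 25 ns window at 40 MHz — used by the test suite
to validate every stage against closed-form oracles.

## Worked example

```
$ flimfret reproduce-worked-example
E=0.687 +/- 0.060
r_angstrom=50.0 +/- 2.3
```

With the fixed lifetimes τ<sub>F</sub> = 0.83 ns and τ<sub>D</sub> =
2.65 ns the interacting donor transfers 68.7% of its excitations to the
acceptor; through the Förster relation with *R*₀ = 57 Å this places donor
and acceptor fluorophores 50.0 Å apart, with a ±2.3 Å first-order
uncertainty propagated from a 0.06 across-cell spread in *E* — i.e. the
two tagged proteins sit well within molecular-contact distance.

The same numbers are available from the library:

```python
from flimfret import fret_efficiency, fret_distance

e = fret_efficiency(tau_F=0.83, tau_D=2.65)   # 0.6868
r = fret_distance(e, R0=57.0)                 # 50.0 Å
```

A complete in-silico experiment — simulate a cell, bin, map, summarize:

```
$ flimfret simulate --preset coexpression --seed 7 --out scratch/cell.h5
$ flimfret map scratch/cell.h5 --out-dir scratch/maps
mean_tau_ns=2.5364
mean_f_D=0.0696
```

The simulated cell has interacting puncta (amplitude fraction 0.35) on a
0.15 diffuse background; the mean lifetime drops from the donor-only
≈ 2.65 ns to 2.54 ns. The default linear map converts that diminution to
a mean *f*<sub>D</sub> of 0.07 — substantially below the amplitude-truth,
because the barycenter ⟨τ⟩ is intensity- rather than amplitude-weighted;
switching the estimator to `intensity-weighted-inversion` in the run
config recovers the truth map (see `docs/methods.md`).

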