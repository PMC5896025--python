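# Methods

## The two-site equilibrium model

A DNA duplex carries one Sox half-site and one octamer half-site. With free
monomer concentrations `s` (Sox2) and `o` (Oct4), the per-duplex
statistical weights of the four DNA species are

    free : Sox2-DNA : Oct4-DNA : ternary
      1  :   s/Ks   :   o/Ko   : ω·s·o/(Ks·Ko)

where `Ks`, `Ko` are the intrinsic dissociation constants (nM) and ω ≥ 0 is
a dimensionless cooperativity multiplying the ternary weight. ω = 1 means
the two proteins bind independently; ω > 1 stabilizes the heterodimer on
DNA. The model deliberately contains **no DNA-independent dimerization**:
Sox2–Oct4 contact requires the DNA scaffold, so protein–protein association
in solution is excluded by construction. Kinetics (on/off rates) and more
than two sites are out of scope.

All concentrations are nM throughout; no unit conversions happen inside the
model. Protein preparations are treated as 100% binding-competent; an
`active_fraction` scalar (default 1.0) can down-scale both protein totals.

### Solver

Conservation of DNA, Sox2 and Oct4 closes the system. Eliminating the DNA
species through the site partition function reduces it to the two free
monomer concentrations. For a trial free-Oct4, the Sox2 conservation
equation is an explicit quadratic in free Sox2 (solved in closed form), so
a single bracketed Brent root find on free Oct4 over [0, oct_total]
remains. The residual is monotone in free Oct4, so the bracket guarantees
existence and uniqueness; every solution is checked against conservation to
a relative 1e-8 (with a sub-femtomolar absolute floor for degenerate
totals) and a violation raises a solver error naming the composition.

### Bound-fraction readouts

Which shifted species a gel or correlation experiment counts as "bound" is
an experimental choice, so three readouts are implemented:

- `titrant_bound` (default): titrant-containing monomer + ternary, over
  total DNA — matching quantification that sums every band containing the
  titrated protein;
- `ternary_only`: the heterodimer band alone;
- `any_bound`: 1 − free DNA / total DNA.

For a single-protein titration the three coincide at ω-independent values.

## Apparent-Kd inference

Because the probe DNA (5 nM) is comparable to the dissociation constants
(≈10–80 nM), free and total titrant differ and a hyperbolic (or Hill) fit
would bias the estimate. The fitted form is therefore the
**ligand-depletion quadratic**

    f(P; Kd, fmax) = fmax·((P + D + Kd) − √((P + D + Kd)² − 4·P·D))/(2·D)

with `D` the DNA total. `fmax` is fixed at 1 by default; freeing it
accommodates gel data that plateau below full saturation. Fits are weighted
by 1/se when per-point errors are provided, unweighted otherwise, and Kd is
optimized in log10 space to enforce positivity. A depletion-corrected
half-saturation estimator (`akd_from_half_saturation`) is provided as a
model-light cross-check.

The Kd fitted to a cooperative two-site titration is *apparent*: at a
saturating cofactor (100× its Kd) it converges to `kd_titrant/ω` (verified
to <1% in the acceptance checks), and at ω = 1 it is exactly independent of
the cofactor level. `infer_omega` exploits the monotone decrease of the
apparent Kd in ω to invert an observed shift by a bracketed root find over
ω ∈ [1e-3, 1e4] in log space, using the same forward simulate-and-fit
functional on the same default titrant grid — which makes noiseless round
trips exact to the root-finder tolerance.

### Uncertainty

Standard errors come from a **residual bootstrap** (default 1000 seeded
replicates: refit on fitted-curve + resampled residuals; se = sd of the
replicate Kds). Inside large simulation loops a Gauss-Newton covariance
estimate (`n_boot=0`) is used instead — the loops need only point
estimates. The apparent cooperativity factor `aKd(alone)/aKd(with)` carries
a first-order ratio-propagated error,
`se = value·√((se_a/a)² + (se_w/w)²)`; this propagation reproduces every
published parenthetical ± value after rounding. Reporting rounds half-up to
one decimal (matching how affinity tables print), with full precision kept
internally.

## FCS analysis

The ACF model is the canonical 3D Gaussian free-diffusion form with a
multiplicative triplet term:

    G(τ) = (1/N)·[1 + T·e^(−τ/τ_t)/(1−T)]·Σᵢ fᵢ·(1+τ/τ_Dᵢ)⁻¹·(1+τ/(K²·τ_Dᵢ))^(−1/2)

Defaults: structure factor K = 5 (w0 = 0.2 µm, z0 = 1.0 µm, V_eff ≈ 0.22 fL)
and a log-spaced lag grid 1 µs–1 s at 50 points/decade. Concentration
follows from the amplitude via `C = N/(N_A·V_eff)`.

Fitting is weighted nonlinear least squares (lmfit); for binding titrations
the free/bound diffusion times are fixed from calibration and only N, the
amplitude fractions and optionally the triplet parameters float. A
two-component fit with free diffusion times closer than 1.5× emits an
identifiability warning. The slow-component amplitude fraction is the bound
fraction under an equal-brightness assumption; a brightness ratio parameter
(default 1.0) re-weights amplitudes by q² when the bound complex is
brighter or dimmer. Raw photon traces, afterpulsing, cross-correlation and
spectral FRET analysis are out of scope.

## Motif scanning

Composite hits are found per (order, spacer) with lookahead regular
expressions compiled from IUPAC classes, on the forward text and on the
reverse complement with coordinates mapped back; all overlapping hits are
reported and deduplication is left to consumers. Coordinates are 0-based
half-open for BED compatibility. An `N` in the sequence matches nothing
(conservative), and spacer positions are unconstrained.

The default Sox pattern is `CWTTGTW` rather than the strict consensus
`CTTTGWW`: the characterized elements vary at exactly positions 2 and 7
(Nanog CATTGTA, Utf1 CATTGTT, Sox2 CATTGTG, Fgf4 CTTTGTT), and the relaxed
pattern covers all of them; the strict consensus remains available as a
preset. Conservation profiles report the per-position modal-base fraction
over an ungapped alignment, with alphabetical tie-breaks for the consensus
display. PWM scoring and de novo motif discovery are non-goals.

## The Sox2-threshold gene-response model

Occupancy of a gene's element follows the single-site isotherm with Kd set
to the gene's **Sox2-alone aKd** (Nanog 31.7, Fgf4 70.2, Fgfr2 81.2 nM); at
the genomic-locus limit (DNA ≪ nM) this is `S/(S + aKd)`. A gene under
activation is "on" when occupancy reaches a threshold; Fgfr2, repressed
through its intronic Sox motif, is "on" when occupancy stays below it.

Two design choices here were genuinely open:

- **Which aKd drives the dose response.** The with-cofactor aKds describe
  Oct4-assisted recruitment measured at one fixed Oct4 level; but the
  lineage logic turns on how much *Sox2* each element needs, and that
  half-point is the Sox2-alone aKd (it is also the quantity whose ordering
  31.7 < 70.2 ≤ 81.2 separates the three genes). The scenario therefore
  defaults to Sox2-alone values, with the with-cofactor substitution
  available as an opt-in (`oct4_assisted=True`, applied when Oct4 strictly
  exceeds the assayed cofactor level).
- **The threshold.** With the default stage concentrations, consistent
  calls for all three genes require a threshold in (0.345, 0.470]; the
  default is 0.4 — below half-occupancy, so a gene whose aKd modestly
  exceeds the prevailing Sox2 level still switches.

Stage Sox2 levels are stand-ins, not measured nuclear concentrations (no
in-vivo molar calibration exists): early inner cells 72 nM and late inner
cells 37 nM reuse the two assay concentrations the affinity measurements
contrast; TE is set low (10 nM) and the maternal-only (zygotic-null) state
to 30 nM, a level that sustains Nanog occupancy but not Fgf4/Fgfr2. Under
these defaults the model yields the expected dichotomy — early inner cells
Fgf4 on / Fgfr2 off (presumptive epiblast), late inner cells Fgf4 off /
Fgfr2 on (presumptive primitive endoderm) — and, in the zygotic-null state,
Nanog on with Fgf4 off and Fgfr2 derepressed. Upstream hippo signaling,
FGF/Erk transduction and spatial embryo geometry are out of scope.

## Synthetic data

All inputs are generated, seeded and manifest-tracked:

- **Titrations**: two-site model predictions on a log-spaced grid (default
  1–500 nM, 10 points) plus Gaussian noise on the bound fraction
  (sd 0.05, clipped to [0, 1.05]) — noise on the derived fraction, not on
  band intensities, which is the simplest model consistent with observed
  titration scatter.
- **ACF series**: one curve per titrant level; the free/bound component
  fractions come from the equilibrium model, the particle number from the
  fixed DNA concentration, and the noise is Gaussian with sd proportional
  to the local amplitude plus a 1% floor (so the tail is not artificially
  noiseless). Default noise scale 0.02.
- **Promoters**: uniform-random backgrounds with motif instances sampled
  from the degenerate patterns at recorded positions/spacers/strands.
  Backgrounds that happen to contain spurious pattern matches are
  resampled, so the manifest is the complete ground truth — appropriate
  for scoring the scanner, but it means the generated set understates the
  chance-hit rate of real genomic background.
- **Cell populations**: lognormal per-cell Sox2 (σ = 0.3, mean-preserving)
  around stage means following the developmental trend (4-cell high,
  declining to the 16-cell stage, rising in ICM, lowest in TE); Oct4
  near-constant (σ = 0.1) around 40 nM.

What passing tests on these data do *not* show: robustness to non-Gaussian
gel-quantification error, detector artifacts in real correlators,
background base composition bias, or any in-vivo concentration calibration.

## Problem sizes and numerics

The test suite and the acceptance script run 200-seed titration recovery at
10 points per curve, 20 two-component ACF fits plus a 10-point FCS
titration, 1000 random 500 bp sequences for the scanner/oracle comparison
and 100 planted promoters — sizes chosen to make the statistics stable at
interactive run times. Equilibrium solves converge to a relative residual
≤1e-10 (Brent tolerance 1e-14); isotherm and ACF fits use tolerance 1e-14
least-squares stops; ω inversion uses a 1e-7 log-space bracket tolerance.
Degenerate inputs fail loudly: all-zero curves, empty grids, zero DNA,
unknown stage labels and malformed FASTA all raise typed errors.
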