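# Methods

## The kinetic model

The loaded Mant-ATP chase assay reports how fast resting (pCa > 8) myosin
heads in a permeabilized single muscle fiber exchange nucleotide. Fluorescent
Mant-ATP pre-loaded onto the heads is chased with dark ATP while frames are
acquired every 5 s for 5 min; each fiber's fluorescence is averaged over
three sampled regions, the mean background region intensity is subtracted
frame-wise, and the result is divided by the corrected intensity of the
final pre-washout frame, so the decay starts at exactly 1. The normalized
decay is modelled as a double exponential

    F(t) = 1 − P1·(1 − e^(−t/T1)) − P2·(1 − e^(−t/T2)),

where (P1, T1) are the amplitude fraction and lifetime of the fast,
disordered-relaxed (DRX) population and (P2, T2) those of the slow,
super-relaxed (SRX) population. F(0) = 1 holds identically for any
parameters. The remainder 1 − P1 − P2 is a non-exchanging plateau and is
left free (the fit is "unconstrained" in this sense); fits with P1 + P2 >
100% are flagged (`AMPLITUDE_SUM_GT_100`) but kept.

Per-fiber ATP consumption follows from the fitted parameters under the
standard assumption that the myosin-head concentration in a fiber is
C = 220 µM, each population turning over one ATP per lifetime:

    ATP (µM·min⁻¹) = (P1/100)·C·(60/T1) + (P2/100)·C·(60/T2).

C is exposed as a parameter because it is an assumption, not a measurement.

## Fitting

Nonlinear least squares (`scipy.optimize.least_squares`, trust-region
reflective, analytic Jacobian) with a multi-start grid over lifetimes
T1 ∈ {2, 10, 30} s × T2 ∈ {100, 200, 400} s; at each lifetime pair the
amplitudes are initialized by a linear solve (the model is linear in P1, P2
at fixed lifetimes). The best residual sum of squares wins. Defaults use
loose box constraints (amplitudes in [−0.1, 1.2], lifetimes in
[0.1, 5000] s) to keep the optimizer off pathological optima on noisy
traces; `unconstrained=True` removes them. Convergence tolerances are 1e-10
on parameters and objective, at most 10 000 evaluations per start.

Components are relabelled after fitting so the faster lifetime is always
reported as DRX; the labelling never depends on the starting point. Standard
errors come from the Gauss–Newton covariance (J'J)⁻¹·RSS/(n−4). QC flags:
`NONCONVERGED` (no start converged; parameters NaN), `LIFETIMES_CLOSE`
(lifetimes within 5× and overlapping 95% CIs — weak identifiability, as for
an effectively single-exponential decay), `COMPONENT_NEGLIGIBLE` (an
amplitude below 0.5%). An exactly flat trace is an exact solution with both
amplitudes zero but a singular Jacobian; it is returned directly with
amplitudes 0 and flagged rather than run through the optimizer.

### Precision at the acquisition grid

With i.i.d. Gaussian noise of SD 0.01 on the normalized trace over the
0–300 s / 5 s grid, the Cramér–Rao bound at a typical fiber (P1 = 25%,
T1 = 15 s, P2 = 50%, T2 = 200 s) gives relative standard errors of about
5.9% (P1), 9.7% (T1), 3.1% (P2) and 12.2% (T2), i.e. median absolute
relative errors of roughly 4.0%, 6.6%, 2.1% and 8.2% for any unbiased
estimator. Simulated recovery with this fitter lands close to those bounds
(≈4.1%, 7.6%, 2.2%, 8.3% over 200 replicates): the fitter is
near-efficient, and per-fiber lifetime precision at this noise level is a
property of the measurement, not of the software. Group comparisons operate
on animal means of 8–12 fibers, which reduces these errors by a further
factor of ~3.

## Group statistics

The animal is the experimental unit. Fibers are averaged (unweighted)
within animal × condition × fiber type × temperature, and all tests run on
those animal means: classical one-way ANOVA across conditions per stratum,
fixed-effects two-way ANOVA (type-II sums of squares, chosen as the
standard treatment of mildly unbalanced layouts) with interaction for
factorial questions, with Šídák-adjusted pairwise follow-ups
(p' = 1 − (1 − p)^m). No multiplicity correction is applied across the many
stratum × metric one-way ANOVAs, and reports state this. Classical (not
Welch) ANOVA is the default; condition contrasts are reported as signed
percent change versus a named baseline condition (a value 35% below
baseline prints as −35%). Temperature sensitivity is the ratio of an
animal's 20 °C mean to its 8 °C mean, per fiber type; animals lacking one
temperature are omitted with a logged warning.

## X-ray reflection quantification

Profiles are 1-D intensity versus detector radius. Detector radius converts
to lattice spacing by the exact Bragg relation θ = ½·atan(r/L),
d = λ/(2 sin θ) with λ = 0.10 nm and L = 2.14 m by default (the small-angle
form d ≈ λL/r deviates by 1.5·(λ/2d)² relative, under 0.01% for the
reflections of interest). Each reflection is fit as a Gaussian plus local
linear baseline inside a search window, by default ±5% around the expected
spacing (14.3 nm for the M3 myosin crown repeat, 7.2 nm for the M6
backbone reflection; equatorial 1,0/1,1 windows are lattice-dependent and
must be supplied). "Intensity" means integrated peak area — the standard
convention — not height; the I₁,₁/I₁,₀ ratio is therefore invariant to
overall profile scaling. Windows with nothing above 3× the high-frequency
noise level (robust MAD of successive differences) raise `NOPEAK`. Global
background subtraction offers an iterated polynomial under-fit (repeatedly
fitting a low-order polynomial to data clipped from above, converging to a
smooth curve under the peaks) and a linear baseline through window edges;
the method is configurable because published reductions vary. Negative
artifacts are preserved, never clipped.

## Proteomics statistics

The TMT-style workflow starts from a quantified features × samples matrix:
log2 transform (if raw), exclusion of features where any group has fewer
than two observed values, and MinProb-style left-censored imputation —
missing cells drawn per sample from N(sample mean − 1.8·SD, (0.3·SD)²),
with the mean and SD computed from that sample's observed values. The draw
is seeded and reproducible. Differential expression uses per-feature
unpaired t-tests (Welch by default; the pooled-variance flavor is an
option, and the choice is a documented divergence risk versus
GUI pipelines), Benjamini–Hochberg FDR, and the two-part significance rule
FDR < 0.05 and fold change ≥ 2 (|log2FC| ≥ 1). Zero-variance features get a
variance-floored p (1 for identical groups) and a `ZERO_VARIANCE` flag.
PTM sites are standardized across all samples (z-scores, sample SD); z > 0
in a condition reads as hyper-modification. Scoring across all samples
(rather than within condition blocks) is a convention choice; within-block
scoring can be had by subsetting columns. Sample PCA centers features
(optional unit scaling) and reports percent variance explained.

## The synthetic-data generator

No per-fiber fluorescence or diffraction data accompany the hibernation
studies this pipeline targets, so the generator emulates the study design:
conditions (summer-active, interbout arousal, torpor) × 5 animals × 8–12
fibers, fiber types I/II (default 50/50, configurable — published
proportions are species-dependent), one or two assay temperatures, frames
every 5 s for 300 s. Fiber truth is drawn hierarchically: condition ×
fiber-type multipliers on lifetimes and shifts on the DRX amplitude,
log-normal between-animal (CV 0.08) and within-animal (CV 0.12)
multiplicative variation on lifetimes, normal jitter on amplitudes (SD 0.02
animal, 0.03 fiber), resampling any draw that violates the parameter
invariants. Noise is additive Gaussian on the normalized fluorescence
(SD 0.01 by default, consistent with visually smooth published decays);
raw traces are rescaled by a drawn baseline intensity (400–600 a.u.) and
offset by a drawn background (40–60 a.u.), with optional linear background
drift (off by default), so background subtraction and t = 0 normalization
are non-trivial. The variance components and intensity ranges are the
generator's own realism choices; the paper-level inputs (grid, design
sizes, noise default) are fixed by the emulated protocol.

Image stacks render a trace into frames where fiber-ROI pixels carry the
raw value and everything else the background level (Gaussian or Poisson
pixel noise optional), so ROI-mean extraction round-trips the tabular
trace. Diffraction profiles place area-normalized Gaussians at the exact
Bragg radius of each requested d-spacing on a smooth monotone-decreasing
background b0 + b1·e^(−r/r0). Abundance matrices are normal on the log2
scale (feature baselines N(16, 2), within-feature SD 0.5), with a chosen
fraction of features shifted by ±log2FC in non-reference groups and
logistic left-censored missingness concentrated in the low-intensity tail.

What the generator does not emulate: photobleaching, fiber movement or
focus drift, detector nonlinearity, 2-D diffraction geometry (profiles are
born 1-D), peptide-level quantification noise, or batch effects. Passing
tests therefore demonstrate correctness of the analysis chain under the
assumed data-generating model, not robustness to every artifact of real
recordings.

## Determinism and numerics

Every stochastic step takes a seed (`numpy.random.default_rng`); identical
config + seed reproduces byte-identical CSV/JSON outputs, verified by
SHA-256 manifests written per stage (timestamps live in a separate key and
are excluded from comparisons). Tie-breaks: component labelling is by
lifetime order, never by start order; multi-start winners are chosen by
strictly smaller RSS with the grid enumerated in a fixed order. Degenerate
inputs (flat decays, zero-variance features or sites, all-constant ANOVA
layouts) are handled explicitly rather than left to floating-point noise.

## Problem sizes used in the shipped checks

The acceptance script and study-scale tests use: 200 replicate fibers for
noisy recovery; 1000 random parameter sets for the energetics equivalence;
100 seeded two-condition studies (5 animals × 10 type II fibers) for
end-to-end effect recovery; 10 000 null simulations for ANOVA type-I
calibration; 1000 random p-vectors for BH/Šídák equivalence; 50 synthetic
matrices (1000 features, 10% true differential at |log2FC| = 2) for
false-discovery control; and two seeded reruns of the full
simulate → fit → energetics → report chain for hash-identity. These sizes
give Monte-Carlo errors comfortably below the margins being checked while
keeping the whole suite runnable on a laptop in minutes.
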