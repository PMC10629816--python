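# Methods

## Synthetic embryo generator

The generator emulates the statistical structure of segmented, tracked
MS2-MCP movies of nuclear cycle 14 (NC14) *Drosophila* embryos: one
fluorescence trajectory per nucleus on a uniform 21 s frame grid over a
~50 min interphase, with nuclei placed along the normalized dorsoventral
(DV) axis x ∈ [−1, 1] (0 = ventral midline).

**Promoter model.** Each promoter is an independent two-state continuous
time Markov chain (OFF→ON at k_on, ON→OFF at k_off), simulated exactly by
exponential waiting times and point-sampled at frame times.  The promoter
starts OFF, since imaging begins as the embryo enters NC14.

**Signal model.** A nascent transcript contributes fluorescence while it
transits the gene, so the noiseless signal is the box-kernel convolution of
the promoter path: I(t) = loading_rate × (ON time in [t − dwell, t]).
During sustained activity the signal rises linearly at `loading_rate` and
plateaus at `loading_rate × dwell_time`.  Additive Gaussian noise (clipped
at zero, consistent with background-subtracted intensities) completes the
model.

**Defaults** (chosen once as realistic for this system and held fixed):

| parameter | default | rationale |
|---|---|---|
| k_on | 0.5 min⁻¹ | ON fraction 2/3 — most wildtype domain nuclei are active in a given frame; burst separations of minutes |
| k_off | 0.25 min⁻¹ | mean burst durations of a few minutes |
| loading rate | 200 AU/min × Gaussian(x; σ=0.35) | amplitude peaks at the ventral midline, mirroring the nuclear Dorsal gradient |
| dwell time | 2.5 min | order of reporter-gene transit at ~1.5–2 kb/min |
| noise SD | 20 AU | ~10% of typical plateau amplitudes |
| frame interval | 21 s | imaging time resolution |
| mutant effects | k_off × 2, loading × 0.5 | qualitative direction of the binding-site-mutant phenotype; magnitudes are configuration, not claims |

**What the generator does not emulate**: image formation, photobleaching,
segmentation/tracking errors, nucleus division or movement, extrinsic
nucleus-to-nucleus parameter variability, and any AU→mRNA calibration
(intensities stay in arbitrary units throughout, as no absolute molecule
count is available).  Passing recovery tests on these synthetic data
therefore demonstrates correctness of the *inference chain*, not robustness
to those real-data artefacts.

## Trace features

A nucleus is active when its signal exceeds a threshold; the default
threshold is baseline mean + 3 baseline SD estimated from the first three
frames (overridable by an absolute AU value).  Activation time is the first
crossing; the transcription window counts frames above threshold; mRNA
output is the trapezoidal integral of the full trajectory (exact for
piecewise-linear signals); mean amplitude averages the above-threshold
frames.  The Pol II loading rate is the least-squares slope of the first 30
points above threshold after LOESS smoothing and 10× linear interpolation
(the interpolation scheme is unspecified upstream; linear is the minimal
choice, and "first 30 points" is read as interpolated points).  Spatial
profiles use 16 equal-width DV bins; single-member bins report SEM 0,
empty bins propagate as missing; boundary steepness is the maximum
|finite-difference derivative| of bin means versus bin centers (central
differences inside, one-sided at the edges).  Group comparisons use the
pooled-variance Student's t-test, with Welch's correction behind a flag.

## Equilibrium occupancy model

Sites and Patser scores: Dl1 (22.8), Dl2 (19.8), Dl3 (17.8), Twi2 (7.8).
Concentration profiles are normalized Gaussians: Dorsal with σ = 0.35
(so the wildtype expression domain occupies roughly the central fifth to
third of the DV axis) and a synthetic stand-in for Twist with σ = 0.45,
both peaking at the midline (the Twist profile stands in for an external
quantification that is not redistributable).

**Calibration.** Only relative affinities are known (Patser scores), so the
model works with midline occupancy ratios r_i = C_i(0)/K_i, mapped linearly
from the scores (an exponential map is available) and anchored to a
published no-cooperativity statistical weight.  Two anchors are exposed:

- the Dl1·Dl2 pairwise weight 0.0870 (the `calibrate_site_ratios` default);
- the fully-bound-state weight 3.45 × 10⁻⁴ (the model default).

The published weights are mutually inconsistent under any multiplicative
microstate model (0.0870 × 0.0397 ≠ 3.45 × 10⁻⁴), so only one can be
matched; the calibration reports the residual of the others.  The model
defaults to the fully-bound anchor because it is the only choice under
which the 65% mutant reduction is expressible at all: with ω ≥ 1,
cooperativity can only *raise* occupancies, so each mutant's
no-cooperativity occupancy is a hard floor, and the pairwise anchor puts
those floors (0.43–0.52) above 0.35 × max(wildtype).

**Mutants.** A mutated site is no longer a recognizable motif, so every
microstate containing it is deleted (equivalently C/K → 0).

**Fit.** The printed analysis used a constrained nonlinear solver whose
objective is the RMS error between mutant and wildtype conditions and whose
constraint is the 65% mutant reduction.  We mirror that structure: minimize
the stacked RMSE between each fitted mutant profile and 0.35 × wildtype
over the DV grid (101 points), subject to equality constraints pinning each
fitted *single-site* mutant's peak reduction at the target, with ω ∈
[1, 10⁶] (log₁₀ parameterization, SLSQP, tolerance 10⁻¹⁰, all-ones start).
The fitted mutant set is {Dl1, Dl2, Dl1/2}: these are the genotypes whose
expression curves the model analysis reproduces, and a fitted Twi2-mutant
constraint would be infeasible (masking the weakest site leaves the three
strong Dl sites, whose no-cooperativity floor caps the achievable reduction
near 58%).  The double mutant enters the objective but not the constraints;
the solution then over-reduces it relative to the singles — the same
behaviour the source analysis reports for its model.  A pure
objective-only mode (`constrain_singles=False`) reproduces the alternative
reading; it converges to ~58% mean single-mutant reduction with the
wildtype boost routed through ω1/ω6/ω11.

Under this stand-in calibration the published sparsity pattern
(ω1, ω6, ω11 > 1, all others at the bound) and the exact 65% reduction
cannot hold simultaneously; the constrained default achieves the reduction
with the boost carried by ω11 alone (plus a small ω5 lift for the Dl1
mutant).  The pattern presumably reflects the original, unpublished
dissociation constants.

**Scans.** Sensitivity scans scale one fitted ω (clamping at the lower
bound); summaries report peak p_bound, half-max domain width and the
wildtype−mutant peak gap.  Affinity scans scale dissociation constants;
with `refit=True` the cooperativities are re-fitted so the scaled enhancer
*maintains the baseline expression profiles* (seeded multistarts handle the
near-degenerate landscape) — weakened sites then demand larger compensating
cooperativities and strengthened sites smaller ones.  The Dl-level scan
scales the Dorsal profile; its rescue search bisects for the uniform
K-division factor restoring the baseline peak (≈ 1.7–2 when Dl is halved,
dominated by the fourth-power scaling of the quadruple state).

## Burst-kinetics HMM

Frames before activation are excluded; the active segment is LOESS-smoothed
(default span: a five-frame window, the classical loess default — wide
fractional spans of ~15% of a 140-frame trace smooth over ~7 min and
erase minute-scale bursts); the slope sign between consecutive frames is
binarized (rising = 1, falling = 0, exact ties carry); a two-state HMM with
Bernoulli emissions (initial transitions 0.5/0.5, initial emissions
P(1|ON) = 0.8, P(1|OFF) = 0.2, both re-estimated) is fitted per trace by
Baum–Welch (tolerance 10⁻⁸, ≤ 500 iterations, scaled forward–backward,
with a pooled multi-sequence mode for short traces); Viterbi decoding (log
space, ties to OFF) yields the state path.  Maximal ON runs are bursts,
maximal interior OFF runs separations; edge runs are censored because
their true lengths are unobserved; k_off = 1/mean(duration) and
k_on = 1/mean(separation) in min⁻¹.

**Known limitations (measured on synthetic data).**  The slope of a
box-kernel (dwell) signal compares the promoter state *now* with its state
one dwell time *earlier*.  Two consequences follow.  First, rising- and
falling-evidence are symmetric by construction, so the decoded paths
estimate the burst *frequency* well but compress the k_on/k_off asymmetry:
with generating rates 0.5/0.25 min⁻¹ the pooled decoded rates land near
each other rather than in a 2:1 ratio, and absolute recovery misses the
generating values by tens of percent.  Second, bursts longer than the
dwell time produce signal plateaus whose slope carries no state
information; plateau noise then decodes as spurious short bursts, so
recovered k_off responds monotonically to the true k_off only while mean
burst durations stay at or below the dwell time.  Within that regime the
monotone response and the decoded-path stationary consistency
(ON fraction ≈ k_on/(k_on + k_off) of the recovered rates) both hold.
Run-length estimation on the *true* sampled paths is accurate to within
the discretization bias dt/(1 − p_stay) of the frame-sampled chain (~10%
at the default rates, ~40% at rates approaching one switch per frame);
relative comparisons across genotypes (the analysis the chain is used for)
are much more robust than absolute rates.

## Numerical choices

- Microstate enumeration is exact over all 2⁴ subsets; probabilities are
  normalized weights (verified against an independent brute-force coding to
  1e-12 relative).
- With all ω = 1 the partition function factorizes,
  Z = Π(1 + C_i/K_i) — used as a closed-form limit check.
- Optimizers: SLSQP (equality-constrained) / L-BFGS-B (box-only) in
  log₁₀ ω; the log parameterization keeps the 10⁰–10⁶ range well scaled.
- Viterbi ties resolve to the OFF state; binarization ties carry the
  previous value with the first frame defaulting to OFF.
- Bisection rescue uses Brent's method (xtol 10⁻⁶) after bracketing.
- The frame grid is floor(duration/dt) + 1 frames covering [0, duration];
  the 21 s interval does not divide round movie durations exactly.
- Seeds: each nucleus draws from a child of a single `SeedSequence`, so
  embryos are reproducible bit-for-bit and independent of nucleus count
  ordering.
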