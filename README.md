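# snaburst

Quantitative analysis of transcriptional dynamics driven by the *snail*
(*sna*) distal enhancer in the early *Drosophila* embryo, built around
MS2-MCP live-imaging trajectories.  The package is for researchers studying
enhancer logic — how multiple transcription-factor binding sites of
different affinities cooperate to set the level, timing and spatial pattern
of a target gene — who want a fully synthetic, end-to-end testable version
of the standard analysis chain.

It provides four composable stages:

1. **Synthetic embryos** (`snaburst.simulate`): single-nucleus fluorescence
   trajectories from a two-state (telegraph) promoter.  The promoter
   switches OFF→ON at rate *k*<sub>on</sub> and ON→OFF at rate
   *k*<sub>off</sub> (exact Gillespie simulation, point-sampled at the
   21 s frame interval); each minute spent ON within the preceding dwell
   time contributes `loading_rate` AU of signal; Gaussian measurement noise
   is added.  Kinetics vary with dorsoventral (DV) position and genotype,
   and every trace carries its ground truth for recovery tests.
2. **Trace features** (`snaburst.features`): activation time, transcription
   window, mean amplitude, mRNA output (trapezoidal integral), Pol II
   loading rate (initial slope of the LOESS-smoothed rise), 16-bin DV
   profiles and their boundary steepness, activity time courses, and
   Student's t comparisons.
3. **Thermodynamic occupancy model** (`snaburst.thermo`): the four
   strongest activator sites of the minimal enhancer (Dl1, Dl2, Dl3, Twi2)
   define 16 microstates in equilibrium.  A subset *S* of bound sites has
   Boltzmann weight
   ω(S) · Π<sub>i∈S</sub> C<sub>i</sub>/K<sub>i</sub>, the partition
   function is Z = Σ<sub>S</sub> w(S), and
   p<sub>bound</sub> = (Z − 1)/Z is the probability that at least one
   activator is bound — the model's proxy for transcription initiation.
   The 11 cooperativity factors ω ≥ 1 are fitted (SLSQP in log ω, bounds
   [1, 10⁶], tolerance 10⁻¹⁰) so that enhancers with mutated sites —
   modelled by deleting every microstate using the site — show the observed
   65% reduction in expression.  Sensitivity, affinity and Dl-concentration
   scans probe the fitted model.
4. **Burst kinetics** (`snaburst.hmm`): LOESS smoothing → slope-sign
   binarization (rising = ON evidence) → two-state Bernoulli-emission HMM
   fitted by Baum–Welch → Viterbi decoding → run-length statistics.  Burst
   durations and separations estimate k_off = 1/mean(duration) and
   k_on = 1/mean(separation).

The model-facing classes follow scikit-learn conventions
(`EnhancerOccupancyModel.fit()`, `BurstStateHMM`,
`TraceFeatureExtractor`), with plain functions underneath, and a `snaburst`
CLI (`simulate`, `features`, `thermo-fit`, `thermo-scan`, `hmm`, `report`)
wraps the pipeline.

## Worked example

```python
import numpy as np
from snaburst import EnhancerOccupancyModel

model = EnhancerOccupancyModel().fit()
print("converged:", model.converged_)
for i in (1, 5, 6, 11):
    print(f"omega_{i} = {model.omega_[i-1]:.4g}")
for genotype, reduction in model.peak_reductions().items():
    print(f"{genotype}: {100*reduction:.1f}% peak reduction")
```

prints

```
converged: True
omega_1 = 1
omega_5 = 2.216
omega_6 = 1
omega_11 = 2.976e+04
Dl1: 65.0% peak reduction
Dl2: 65.0% peak reduction
Dl1/2: 79.6% peak reduction
Twi2: 57.2% peak reduction
```

The fit pins each fitted single-site mutant (Dl1, Dl2) at exactly the 65%
peak reduction seen experimentally, routes the required wildtype boost
through the fully-bound state's cooperativity (ω₁₁ ≈ 3×10⁴), and
over-reduces the Dl1/Dl2 double mutant — the same qualitative behaviour the
underlying model analysis reports.  Removing a highlighted state's
cooperativity collapses its statistical weight by far more than 90%
(e.g. 100×(1 − 1/28) ≈ 96.4% for the Dl1·Dl2 pair).

An end-to-end synthetic run:

```sh
snaburst report --set n_nuclei=60 --set duration=30 --set "genotypes=WT,Dl2"
```

writes traces, per-nucleus features, DV profiles, the fitted occupancy
model and per-nucleus burst kinetics under `snaburst_run/`, with a
provenance block (config hash, seed, version) in `report.json`.

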