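# Methods

`rovingdcm` implements a two-level dynamic-causal-modelling (DCM) analysis of
roving-oddball auditory ERPs, together with a synthetic-data generator that
stands in for the human EEG recordings of the emulated crossover study
(18 subjects, placebo and ketamine sessions, two dose tiers).  This note
documents the model, the generator, every numerical choice that matters, and
what the passing tests do and do not establish.

## Neuronal model

Each cortical source is a canonical microcircuit (CMC) of four neural-mass
populations: spiny stellate cells (ss, granular), superficial pyramidal
cells (sp), inhibitory interneurons (ii) and deep pyramidal cells (dp).
Each population follows second-order synaptic kernel dynamics

    dv/dt = i
    di/dt = kappa * u_pre - 2 kappa * i - kappa^2 * v

with `v` the mean depolarisation (a.u.), `kappa = kappa0 * exp(tau)` the
population rate constant, and `u_pre` the weighted sum of presynaptic
firing.  Firing is a logistic sigmoid of depolarisation with slope 2/3 and
its resting output subtracted, so the all-zero state with zero input is an
exact fixed point.  Prior-mean time constants are 4, 8, 16 and 28 ms for
ss, sp, ii and dp.

The literature on this model class fixes its structure but not a single
numerical wiring, so the intrinsic connection table is a documented package
choice (weights in units of the global synaptic scale, 200):

| target ← source | weight | gain parameter |
|---|---|---|
| ss ← ss | −8 | — |
| ss ← sp | −4 | — |
| ss ← ii | −4 | exp(g3)  *(the ii→ss inhibition)* |
| sp ← ss | +4 | exp(g1)  *(excitatory granular drive)* |
| sp ← sp | −4 | exp(m + n·basis), activity-dependent |
| sp ← ii | −2 | exp(g2) |
| ii ← ss | +4 | — |
| ii ← sp | +4 | exp(g2) |
| ii ← ii | −4 | — |
| ii ← dp | +2 | — |
| dp ← sp | +3 | — |
| dp ← ii | −2 | — |
| dp ← dp | −2 | — |

The labelling convention fixes `g3` as the ii→ss inhibitory gain (the locus
of the drug effect), `g1` as the excitatory intra-columnar ss→sp drive, and
`g2` as the reciprocal sp↔ii pair.  The sp recurrent self-connection carries
an additional cubic activity-dependent term `-4·exp(m_eff)·s^3` (the M
parameter, with condition modulations N), which vanishes at rest and
self-limits large superficial responses.

Extrinsic forward connections project sp firing onto ss of the target
(base weight 32); backward connections project dp firing onto sp (−0.25)
and ii (+0.5).  The exogenous stimulus — a Gaussian bump with 60 ms onset
(absorbing subcortical conduction) and 16 ms dispersion — drives ss of
bilateral A1 with weight 12.  These constants were calibrated by forward
simulation against qualitative targets: plausible ERP latencies that
increase up the hierarchy, settled responses by 300 ms, monotone
attenuation of ss responses under increasing g3, and the directional
signatures of the region-specific inhibition sweep (below).  Conduction
delays are omitted.

The network is the six-source auditory hierarchy — bilateral A1
(±42/46, −22/−14, 7/8), STG (±61/59, −32/−25, 8) and IFG (±46, 20, 8), MNI
mm — with forward edges A1→STG→IFG per hemisphere and their reverses as
backward edges.

## Repetition effects: temporal basis functions

Condition-specific coupling changes across the four conditions (D1, S2, S6,
S36; repetition numbers r = 1, 2, 6, 36) are a linear mixture of two basis
functions, each normalised to peak 1:

* monophasic decay `exp(-(r-1)/8)`, maximal at the deviant;
* phasic change `(r-1)·exp(-(r-2)/2)`, maximal at the first standard S2.

Decay constants are configurable; construction rejects a phasic constant so
slow that its peak would leave S2.  Effective log-couplings are
`base + Σ_k w_k · basis_k(condition)`, with B weights on forward/backward
extrinsic edges and N weights on the sp self-modulation, exponentiated onto
the fixed wiring.  All neuronal parameters are log-scale deviations with
zero-mean Gaussian priors (variance 1/16 for couplings and modulations,
1/64 for rate constants).

## Observation model

Sensors see the pyramidal mixture `sp + 0.2·dp`, projected through a
synthetic lead field and scaled by `exp(gain)`.  The lead field places one
equivalent current dipole per source at its MNI coordinate and evaluates
the quasi-static homogeneous-medium potential at idealised 10/20 electrode
positions (20 channels, MNE's standard montage), average-referenced and
globally scaled to unit RMS.  Orientations follow a per-class convention:
A1/STG dipoles are tangential with their average-referenced Fz sensitivity
nulled exactly, IFG dipoles near-radial pointing outward, with a small
seeded jitter emulating inter-individual variability.  This makes the
frontocentral midline channel a frontal readout and gives the
deviant-minus-standard difference wave its canonical negative polarity at
Fz.  A BEM head model and anatomical source localisation are out of scope;
the lead field's job is a fixed, source-separating linear map.

Integration uses fixed-step RK4 (0.5 ms for simulation, 1 ms inside the
fitting loop; the public epoch integrator enforces step ≤ 1 ms), output at
the 500 Hz recording grid on the −100..300 ms epoch with zero pre-stimulus
prediction.  Step-halving changes response peaks by < 0.1%.  A compiled
(numba) kernel and a pure-numpy fallback produce identical trajectories to
~1e-15; each path is deterministic bit-for-bit given identical inputs.

## Synthetic study generator

The generator emulates the study's shape: 18 subjects (even split across
infusion orders; 6 of 18 on the high dose tier), two sessions each, four
condition averages per session on a 20-channel × 201-sample grid, roving
tone sequences (700–1200 Hz in 50 Hz steps, 2–36 repetitions, 400 ms
inter-onset interval), condition-specific baseline rules (D1: −100..0 ms;
S2: 250..300 ms; S6/S36: the mean of both window means), and trial counts
D1 228, S2 209, S6 150, S36 76 scaling sensor noise as 1/√trials.

Grand-truth repetition effects are graded up the hierarchy: N-modulation
(mono, phasic) of (−0.1, 0.05) in A1, (−0.2, 0.1) in STG and (−0.9, 0.3)
in IFG, with small B modulations (forward 0.2/−0.1, backward 0.1/−0.1).
Two considerations drove this composition.  Scientifically, hierarchically
higher areas carry longer-time-scale context, so repetition plasticity
concentrates toward the top.  Practically, the opposed drug effect
(+δ on STG g3, −δ on IFG g3) acts on the difference wave through two
pathways of opposite sign; with plasticity concentrated frontally both
pathways align and the simulated drug reduces the frontocentral mismatch
response, as observed in the emulated study.  With uniform or
forward-B-dominant plasticity the net effect inverts — a genuine property
of this microcircuit, recorded here so nobody rediscovers it the hard way.

The drug ground truth shifts g3 by +0.25·dose-code in bilateral STG and
−0.25·dose-code in bilateral IFG (dose codes 1 and 2; placebo 0).  An
alternative target (`a_fwd`) shifts forward extrinsic couplings instead and
is used as the extrinsic control in tests.  Between-subject dispersion is
Gaussian (SD 0.125) on the coupling/modulation log-deviations; rate
constants are not dispersed (they are poorly identified from 20-channel
averages and carry no ground-truth effect).  Per-trial sensor noise SD
defaults to 0.05 a.u., i.e. averaged-ERP noise of ~0.003–0.006 a.u.
against D1 peaks of ~1 a.u. — cleaner than routine human averages.  This
is deliberate: the generator's purpose is to test the analysis chain, so
ground-truth structure (including the deliberately weak ~1% sensor-level
drug effect, whose model-level cause is large) must dominate measurement
noise.  Passing tests therefore show the chain recovers what the data
contain; they do not show robustness to clinical noise levels or to
artefacts, drift, and trial-level variability, none of which are modelled.

## Inversion

Each session's four condition ERPs are fitted jointly in the space of the
leading 8 spatial singular modes of the stacked data.  The predictor
integrates the microcircuit per condition, applies the same baseline rules
as the data, projects through the modes, and is fully batched so the
finite-difference sensitivities (step 1e-3 on the log-deviations) cost one
batched integration per iteration.

Variational Laplace maximises the free energy of a Gaussian observation
model with a single log-precision hyperparameter (hyperprior N(4, 1); with
~6000 data points the hyperprior is effectively uninformative) by
Gauss–Newton ascent with Levenberg-style step rejection — the accepted
trajectory is non-decreasing by construction — and Newton updates of the
log-precision.  Curvature is ridge-regularised (1e-6); convergence is a
free-energy gain below 1e-2 nats or the iteration cap.  On linear-Gaussian
problems with fixed noise precision the converged posterior matches the
conjugate closed form and the free energy equals the exact log evidence
(tested to 1e-6).

Desk-scale defaults: sessions free the g, M, A, B, N and gain groups
(85-parameter vector; the 24 rate-constant deviations stay pinned at their
prior mean with near-zero variance so all densities remain proper);
grand-mean fits run up to 16 iterations refreshing the Jacobian on the
first 4, session fits up to 6 iterations refreshing on the first 1
(quasi-Newton thereafter).  These sizes keep a full 36-session study at
roughly 15–20 s on one CPU while leaving group-level recovery intact; every
setting is config-overridable.

The empirical-prior pipeline fits the grand-mean ERPs from the base priors,
then gives every session a prior centred on the grand-mean posterior means
with variances reset to base values.

## Model comparison and group inference

**Bayesian model reduction (BMR).**  For Gaussian prior/posterior and a
reduced prior, the reduced posterior and evidence change are closed form
(precisions: `Pr = P + Pr0 - P0`, etc.); fixing a parameter group shrinks
its prior variance to 1e-8 and, at the first level, pins its mean at 0 so
"no condition effect" means exactly that even under empirical priors with
nonzero means.  BMR matches direct refitting on linear-Gaussian instances
to 1e-6 nats (tested).

**First-level space.**  {forward B free/fixed} × {backward B} × {intrinsic
N} × {monophasic, phasic, both} = 24 models, scored per session and pooled
by summing evidence changes.

**Bayesian parameter averaging** pools session posteriors by precision
weighting.

**PEB.**  Session parameters are explained by a group GLM with regressors
(i) group mean, (ii) ketamine dose code 0/1/2, (iii) per-subject indicator
columns (the random subject effects), over the free first-level fields
excluding the observation gain.  Because the hierarchical model is Gaussian,
the session-evidence change induced by moving a session's prior mean is an
exact quadratic in the second-level effects, so for a fixed between-session
covariance the effect posterior and second-level free energy are closed
form.  The between-session covariance is `exp(-gamma)` times the
first-level prior covariance with `gamma` optimised by bracketed scalar
search on the free energy (hyperprior N(0,1)); the subject-block prior
scale is optimised the same way in a coordinate pass.  Second-level priors
are zero-mean with variance 1/16 of the first-level prior variance.
Session posteriors enter through their marginals over the included fields.

**Second-level space.**  The declared default roster (shipped as JSON,
replaceable by configuration) has 14 models: exclusively-extrinsic subsets
of {A, B} (3) and exclusively-intrinsic subsets of {tau, g, M, N}
(4 singletons, 6 pairs, the full set).  Scoring fixes the ketamine-effect
entries of excluded groups via BMR on the ketamine block of the effect
posterior (the prior is block-diagonal across regressors, so the block
marginal is sufficient); ties break toward the earlier declaration, which
places smaller models first.  Models naming only groups absent from the
first-level fields (e.g. tau at desk-scale settings) degrade gracefully to
the empty model.

**Effect probabilities.**  Per-entry BMR against a point null (variance
1e-8, a Savage–Dickey ratio on the 1-D marginal), mapped through
`p = 1/(1+exp(dF))`; a posterior equal to its prior scores 0.5 exactly.

## Sensor statistics

Deviance (D1 vs S36) and repetition (S36 vs S2) effects: paired t-tests per
timepoint at Fz over 0–300 ms, Bonferroni-corrected by the number of
timepoints.  Whether the original analysis pooled channels is not
recoverable; Fz-only is implemented.  The MMN summary takes the most
negative deflection of the D1−S36 wave at Fz within 100–200 ms ("around
150 ms"), per subject and session, and compares placebo vs ketamine peak
magnitudes with a paired t-test (df = n−1).  The body text's "S26" is read
as a typo for S36, following the figure caption.

## The g3 sweep

From a grand-mean parameter vector, g3 is modulated concurrently and in
opposite directions — bilateral STG 0→+2, bilateral IFG 0→−2, default
9-step grid — simulating the deviant condition (the sweep characterises
single-event responses) and recording sp time courses and (sp, ss)
trajectories per source.  Divergent steps are reported individually and the
rest retained.  At the synthetic grand truth the IFG sp peak attenuates
monotonically (to ~0.82 of baseline) with a terminal latency not earlier
than baseline (+16 ms), the early STG ss response falls relative to sp, and
A1 changes by < 3% ("minimal effect" is operationalised as < 5%).

## Known limitations

* Transient ss-peak monotonicity in g3 holds at A1 and STG; at the top of
  the hierarchy the delayed ii↔ss loop produces a resonant rebound, so the
  IFG transient peak is non-monotone even though its steady-state response
  decreases monotonically in g3 (both facts are tested as stated).
* The sensor-level drug effect on the difference wave is ~1% and rides on
  larger between-subject variability — individually non-significant, as in
  the emulated study; only pooled averages resolve the direction.
* Conduction delays, trial-level data, artefacts and realistic noise floors
  are not modelled; parameter values are a.u., not physical units.
* Session fits at desk-scale settings free 61 of 85 parameters; absolute
  posterior values of weakly identified couplings (g1/g2, backward A) trade
  off against each other, and only between-session contrasts are
  interpreted at the group level.
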