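# Methods

This note documents the generative model, the statistical constructions, the
defaults and their rationale, and what the synthetic benchmark does and does
not demonstrate.

## Generative model of the assay

The simulator emulates a two-chip kinome peptide array read in real time.
Its structural constants default to the reference assay: 196 PTK substrates
read over 94 reaction cycles and 144 STK substrates over 124 cycles (340
peptides total), five camera exposures (10–200 ms), a 16-bit detector
(saturation 65535 AU) with mean background 100 AU; a cohort of nine patients
(five male, four female) contributing paired tumor and adjacent tissue in
technical triplicate; and an inhibitor panel of imatinib (1000 nM),
rebastinib (100 nM) and olverembatinib (100 nM) against a DMSO vehicle, all
nominally targeting ABL1.

For substrate *s* in sample unit *u* under treatment *t*:

* **Velocity.** `V(s,u,t) = Σ_K w(K,s)·base_K·mult(K, tissue_u, sex_u)·
  mean_{p∈u}[pat(p,K)·f(p,t,K)]`. Weights `w ∈ (0,1]` come from the
  annotation; `f` is single-site occupancy `1/(1+[D]/IC50)` or a per-patient
  override.
* **Kinetics.** `A(c) = V·(1 − e^{−r_s c})`, the minimal monotone saturating
  curve; rates `r_s ~ U(0.02, 0.08)` per cycle so end-levels genuinely
  differ from initial velocities over a ~100-cycle run.
* **Detection.** `I = clip(bg + e·A·spot·rep + ε, 0, sat)` with lognormal
  spot (CV 10%) and replicate (CV 5%) effects of unit mean and additive
  Gaussian read noise (sd 2 AU). With all noise at zero the emitted
  intensities equal the closed form exactly, which is what makes the oracle
  tests exact rather than approximate.

**Drug action** is pure competitive occupancy. The assay's reduced-ATP
protocol (used so inhibitors are not outcompeted) is folded into the
*effective* IC50 rather than modeled explicitly: occupancy is the simplest
mechanism that yields graded, dose-monotone on- and off-target inhibition,
and nothing downstream depends on the finer pharmacology. The default IC50
table is synthetic but pharmacologically shaped: imatinib is the weakest ABL
binder (600/700 nM for ABL1/ABL2, so ~60% occupancy at 1 µM), rebastinib and
olverembatinib are potent (4–15 nM) and carry off-target entries (DDR1; SRC
and FRK) that generate reportable off-target calls.

**Biology enters multiplicatively.** Tumor effects for the named kinases put
the ABL axis up in both sexes (ABL1 ×2.5) and script the sex dichotomy on
the AKT axis (up in male tumors, down in female tumors); unnamed kinases get
mild lognormal tumor effects (log-sd 0.15). Per-patient lognormal effects
(log-sd 0.2) create inter-patient heterogeneity; pooled mode averages the
noiseless per-patient velocities (equal allocation) before noise. A
non-responder is scripted by replacing the occupancy factor with 1.4 for one
(patient, drug, kinase) triple — target activity *rises* under the
inhibitor, which is exactly what the trial stage must flag.

**The annotation fixture** (520 kinases: 190 tyrosine-side, 330
serine/threonine-side across TKL/STE/CK1/AGC/CAMK/CMGC/Other) is
structurally realistic, not a copy of any vendor database (those are
proprietary). Substrate in-degree follows a truncated geometric law on 1..15
(P(d) ∝ 0.78^d, mean ≈ 3.9); the named report kinases are guaranteed
realistic substrate sets (ABL1 ≥ 12). Substrate *sharing* matters: a
kinase's observed PerMed is diluted by co-mapped uninhibited kinases, so a
drug at its target's IC50 scores −50% only when the substrates are
exclusive; on the shared fixture the same dose reads −20 to −45%, which is
the realistic regime.

## Quantification

The per-spot statistic is the background-corrected least-squares slope
through the origin of intensity vs. exposure, refit after excluding
saturated reads (≥ 2 unsaturated points required; otherwise the cell is
flagged, not fatal). The curve summary is the **end-level** — the mean slope
over the final `window = 10` cycles — matching final-cycle imaging of this
instrument class; an initial-rate mode (first `window` cycles) sits behind
`QuantifyParams.statistic`. Replicates are collapsed by arithmetic mean
*after* quantification, mirroring technical-triplicate group assessment. QC
flags (precedence saturated > low_signal > high_cv) use a detection floor of
0.01 AU/ms and a replicate-CV threshold of 0.5. Log2 views floor cells at
ε = 1e−3 AU/ms so fold changes stay finite; the floor is recorded in the
matrix metadata. Background is taken from the assay design (simulation) —
no blank-spot layout is assumed.

No quantification statistic is published for the commercial pipeline; the
choice here is documented, configurable, and validated against the
simulator's closed form (exact on noiseless data), not against the
proprietary software.

## Substrate statistics

Contrasts are paired on the log2 scale: tumor − adjacent within patient, or
drug − vehicle within sample unit, optionally restricted by sex. The
waterfall flag threshold is |mean LFC| ≥ 0.2 and the boundary is counted as
passing (the inclusive reading of "passing a threshold"). No per-substrate
hypothesis test is run by default — significance lives at the kinase level,
where substrate evidence aggregates. Heat-map export optionally z-scores
rows and orders them by average-linkage clustering on correlation distance;
constant rows are emitted as zeros with a warning flag.

## Upstream kinase inference

The kinase statistic is the **mean** LFC of its mapped, measured substrates
(median available by argument; mean keeps the sampling null analytic and
matches the substrate-aggregation used elsewhere). Kinases need
`min_substrates = 3` to be scored. Sampling is always within chip type —
PTK and STK runs are physically separate chips with separate panels.

* **Sampling Z**: null = means of `n_iter = 2000` random size-m subsets of
  the measured panel, drawn without replacement; `z = (stat − μ₀)/σ₀`.
  Panel-wide scoring shares null draws between kinases of equal m (the null
  depends only on chip and m). `exhaustive_z` enumerates all C(N,m) subsets
  (bounded at 200,000) and is the exact oracle the sampler is tested
  against.
* **Two-component ranking**: specificity Z (sampling null, "is the signal
  specific to this kinase's substrates?") and significance Z (sign-flip null
  over the paired LFCs, appropriate for paired contrasts; label permutation
  would suit unpaired designs). `final_score = sign(stat)·(|z_spec| +
  |z_sig|)/2`; ranking by |final_score|, ties to larger m then lexicographic
  id. This follows the published *description* of hierarchical
  upstream-kinase ratings in spirit; the commercial implementation is
  proprietary and numerical agreement with it is explicitly not claimed.
* Degenerate nulls (zero variance): an isolated Z computation raises a
  diagnostic error; inside the ranking, a statistic equal to the null mean
  scores zero for that component (so an all-zero contrast yields all-zero
  scores rather than an exception).

The kinome-tree export is a plain TSV (kinase, family group, activity =
statistic, significance = |score|) consumable by the usual kinome-tree
renderers; no phylogeny is inferred — family labels come from the
annotation.

## PerMed and the trial report

PerMed is computed on the **linear background-subtracted** scale:
`score(K) = mean_s 100·(treat_s − ctrl_s)/ctrl_s` over K's measured
substrates. Background subtraction is what makes scores below −100%
possible (a strongly inhibited spot can fall below the subtracted
background), which published patient-level values require; a log or
unsubtracted ratio could never go there. Controls within ε = 1e−3 AU/ms of
zero are excluded and listed with reasons — a transparent denominator guard
rather than clipping.

Trial logic per sample unit and drug: the nominal target's PerMed is the
on-target readout; off-targets are every other kinase with |PerMed| ≥ 20%
(no published threshold exists; 20% is the package default and is printed
in every report header), sorted by magnitude with sign retained so
compensatory increases are visible; a strictly positive on-target score
under an inhibitor marks a non-responder. Drugs are ranked by most negative
on-target score, then fewer off-target calls, then smaller off-target
burden; non-responder drugs rank last regardless, not-assayed drugs after
those.

## Numerical and design choices

* All randomness flows through `numpy.random.default_rng(seed)`; chips are
  processed in sorted order so the stream is well-defined. Identical
  configs and seeds give byte-identical artifacts (floats serialized at 9
  significant digits); the run log carries wall-clock timings and is the
  only non-deterministic output.
* Subset draws use the argsort-of-uniforms construction (vectorized
  sampling without replacement); sampled null moments use the sample sd
  (ddof 1), exhaustive moments the population sd over the full enumeration.
* Scores are invariant to substrate row order: panels are sorted by
  substrate id before any draw.
* Grid completeness of raw tables is verified by cardinality (unique keys +
  row count = product of dimension sizes), with the first missing key named
  on failure.

## Benchmark scope and limitations

The evaluation experiments (`kinomechip.benchmarks`, surfaced by
`scripts/acceptance.py`) use deliberately sized problems: 20 small instances
at 50,000 draws for sampler-vs-enumeration agreement; 2000 kinase draws on
196-substrate panels for null calibration; 50 runs each for spiked-kinase
recovery (shift +1.0 on 10 substrates over sd-0.1 noise, 196-substrate
panel) and noisy PerMed recovery (default noise, 10 exclusive substrates,
dose at IC50). These sizes give stable rates while keeping a full
re-evaluation around a minute on one CPU.

What passing these benchmarks shows: the sampling null is correctly
calibrated, the ranking recovers a truly driving kinase, and the
quantification-to-PerMed chain is exact in the noiseless limit and tight
(±10 points) under realistic noise. What it does not show: agreement with
proprietary vendor scores, robustness to assay artifacts the generator does
not emulate (spatial/wash effects, image segmentation error, ATP depletion,
batch effects across runs), or the validity of the synthetic IC50 and
effect-size tables as estimates for any real compound or cohort —
patient-level numbers from real studies are not reproducible from synthetic
data and are not claimed.
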