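# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic generators do and do not emulate,
and the design decisions taken where the problem was genuinely open.

## Motif scanning

Coordinates are 1-based inclusive residue numbers throughout; a record may
start at any residue number (`offset`), so sub-sequences keep native
numbering (V780 stays V780). The CRAC pattern is directional (N→C) with
three anchor classes — apolar {L,V}, aromatic {Y} canonical / {Y,F,W}
extended, basic {K,R} — and two gaps of 1–5 residues counted *strictly
between* anchors. This gap convention reproduces the canonical worked
examples exactly (V780→F786 is a gap of 5; Y788→K790 a gap of 1).

Every satisfying (apolar, aromatic, basic) triple is reported as a distinct
motif, overlapping or not, because variants sharing residues are biologically
distinct binding hypotheses. Transmembrane searches expand each segment by a
configurable flank (default 5 residues, the lipid–water interface stretch)
and require *all three anchors* inside the flanked window — the strictest
containment reading that still yields the published inventories. Windows
from different segments are never merged; a motif in two overlapping windows
is reported under each. `X` (unknown residue) matches no anchor class but
may occupy gap positions.

Two TM2 boundary presets are provided (`mTRPA1-fig`: 766–793;
`mTRPA1-model`: 765–793) because published annotations of the same channel
differ by one residue; neither is privileged.

The scanner is validated against an exhaustive brute-force triple enumerator
on random sequences — the two implementations share no code.

## Conservation

Scoring is a transparent property-class scheme, not a re-implementation of
any particular alignment viewer's score. Residues belong to (possibly
several of) seven classes: hydrophobic, aromatic, positive, negative, polar,
small, special (P/G). A column's conservation score is the number of classes
shared by *all* its residues divided by the class count, promoted to 1.0 for
strict identity. The viewer-style flags are exact by construction: `*`
(identity) requires all residues identical and no gaps; `+` (property)
requires a shared class and no gaps. Gaps are maximally conservative: they
break both flags, score 0, are excluded from consensus denominators, and
never conserve an anchor.

Consensus ties break alphabetically and carry an explicit ambiguity flag, so
outputs are deterministic without hiding the tie.

Anchor conservation maps each motif anchor through the alignment (the
reference row must be ungapped at anchors) and reports the fraction of rows
whose residue stays in the anchor's class — an in-class substitution (F→W at
an aromatic anchor) conserves; anything else, including a gap, does not.

## Gradient partitioning

Profiles are per-fraction intensities with fraction 1 at the top (lightest)
of the gradient. All statistics are scale-invariant (they use the normalized
profile). Peak ties resolve to the lowest fraction index with a tie flag.
The headline "fraction shift" is the integer peak shift — matching how such
shifts are usually eyeballed on blots — with the centroid shift reported
alongside as the continuous version; the replicate summary averages either
(configurable, peak by default) and reports mean ± s.e.m. (s.e.m. undefined
for a single pair). Densitometry itself is out of scope: profiles enter as
tables.

## TIRF colocalization

Detection: difference-of-Gaussians band-pass (σ vs 1.6σ, default σ = 1.5 px
— a standard point-spread approximation), local maxima above a robust floor
(median + k·1.4826·MAD of the response, k default 6), sub-pixel refinement
by background-subtracted window centroid. Fully deterministic.

Tracking: greedy nearest-neighbour linking, accepting candidate pairs in
ascending distance order while distance ≤ `r_link` (default 3 px); no gap
closing, because the co-movement rule presumes unbroken observation.

Scoring: a red track is colocalized when some green track stays within
`r_pair` (default 3 px; the underlying studies state no distance, so it is a
parameter) for at least `min_consecutive` = 3 consecutive shared frames.
The denominator is red tracks of length ≥ `min_consecutive` — shorter tracks
cannot satisfy the rule either way and would only dilute the score with
undecidable cases. An optional integer frame offset compensates sequential
two-channel excitation (default 0). With no eligible red tracks the
percentage is reported as undefined, never as 0.

## Confocal membrane fraction

Ring segmentation: Otsu threshold on the membrane-dye channel, morphological
closing (disk radius 2), largest connected component; the whole-cell mask is
the filled ring, so ring ⊆ cell and the fraction is bounded in [0, 1] by
construction. One cell per image is assumed; a component-selection knob
handles multi-cell crops.

Background handling follows the strict-exclusion rule: pixels at or below
the background level contribute nothing (they are discarded, not
baseline-subtracted). The background level defaults to the median reporter
intensity outside the cell mask — the estimator is unspecified upstream, and
an outside-cell median is robust to both the cell's own signal and isolated
bright debris.

`membrane_cv` — the coefficient of variation of mean ring intensity over 36
angular sectors — is this package's own clustering index, added to give
"clustered membrane expression" a number; it is reported alongside the
fraction but is not part of any recovery guarantee.

## Hill dose-response

The model is `ΔCa²⁺(c) = Max · c^H / (c^H + EC50^H)`, evaluated as a
logistic in log-concentration so extreme doses neither overflow nor lose
the asymptotes. Fits pool all cells of a condition into one least-squares
problem (the source experiments pool >50 cells into a single fitted curve);
a per-concentration-mean mode exists for comparison. Parameters are fitted
on the log scale, making positivity structural; the Hill coefficient is
additionally bounded to [0.3, 10] — it is treated as a free parameter with
default 2 in the generator, since no reference value is asserted upstream.
Initialisation: Max at the largest per-concentration mean, EC50 at the first
concentration whose mean crosses half of that, H = 1. Non-convergence is
flagged on the result object, never silent.

Condition comparison resamples cells with replacement within each condition
(percentile bootstrap, default B = 200, seeded) and reports 95% intervals
for the EC50 fold change and Max ratio; a genotype is called
depletion-sensitive when the fold-change interval excludes 1. Resamples
with failed fits are dropped and the comparison is flagged when more than
20% fail. Percentile intervals for a ratio undercover somewhat below ~50
cells per concentration; at the pooled sizes used throughout (50 cells per
concentration, six concentrations) the false-positive rate of the
sensitivity call is at or under its nominal 5% in the package's own
specificity simulation.

## Synthetic generators

Each generator returns its ground truth with the data; recovery tests never
re-derive truth from the data. All draw from one `default_rng(seed)` stream
and are bit-reproducible.

* **Ortholog panels** (default 24 species): no indels — the panel is its own
  alignment, since conservation analysis operates on an existing alignment
  and the gap policy lives there instead. Anchor sites keep an in-class
  residue with probability `anchor_fidelity` (default 0.9) and otherwise
  move *outside* the class, so class membership carries the signal;
  non-anchor sites substitute uniformly at `substitution_rate` (default 0.1).
* **TIRF movies**: isotropic Gaussian spots (σ = 1.5 px) on reflected
  Brownian trajectories; co-moving pairs share one trajectory plus
  independent jitter (0.3 px). Defaults — 128×128 px field, 20 frames at
  0.5 s, 5 co-moving pairs + 5 red-only + 3 green-only, amplitude 100 over
  background 10 with read noise 2 (SNR 50) — represent a sparse TIRF crop in
  which ~13 vesicles are individually resolvable; a density warning fires
  when the expected nearest-neighbour spacing drops below twice the pairing
  radius. Noise is additive Gaussian on an ideal image (no Poisson/EMCCD
  model), keeping recovery expectations analytic.
* **Confocal cells**: membrane annulus (radius 45 px, thickness 4 px),
  nuclear disk, and a reporter photon budget split membrane/interior at
  exactly `f_membrane` before noise; membrane signal is uniform along the
  ring or von Mises-concentrated (`clustering_concentration` as κ) to
  emulate patchy expression.
* **Gradient profiles**: a two-Gaussian mixture over fraction indices (raft
  component centred at 3, non-raft at 5.5, width 0.7 fractions), discretized
  and renormalized per component, plus truncated Gaussian noise. The
  noise-free centroid of the discretized mixture is available in closed form
  and serves as the analytic expectation in shift tests.
* **Dose-response tables**: Hill responses plus Gaussian noise per cell;
  defaults are the wild-type control condition (EC50 11.8 µM, Max 0.79 µM,
  50 cells per concentration over 1–300 µM, noise 0.1 µM).

What the generators do **not** emulate — photon (Poisson) statistics, depth-
dependent TIRF excitation, drift, photobleaching, indel evolution, blot
densitometry nonlinearity, per-cell Max heterogeneity — bounds what passing
tests show: the pipeline recovers planted truth under idealized noise, which
validates the algorithms and their calibration, not instrument-specific
robustness.

## Problem sizes

Default test and pipeline runs use 24-species panels, 20-frame 128×128
movies with 13 structures, 128×128 single-cell images, 6-fraction profiles,
and 300-cell dose-response tables with up to 200 bootstrap resamples —
sizes at which every stage's behaviour is already asymptotic for its
statistic while keeping a full run inside a couple of minutes on one core.

## Known limitations

* The motif scanner targets CRAC-family patterns only; inverted (CARC) and
  sterol-sensing-domain motifs are out of scope.
* Conservation scoring is a property-class scheme, intentionally simpler
  than substitution-model or entropy-based scores; only the `*`/`+` flag
  semantics are exact reproductions.
* Tracking is greedy nearest-neighbour without gap closing or motion
  prediction; it is adequate at the sparse densities the co-movement rule
  assumes and degrades in crowded fields (hence the density warning).
* Real-image quantities that depend on unavailable raw data (a measured
  colocalization score, a measured membrane-amplitude reduction) are
  emulated by the generators, not reproduced.
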