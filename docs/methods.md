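# Methods

`poreflux` implements two linked analysis pipelines for characterizing a
narrow β-barrel nanopore — the trimeric-autotransporter transmembrane
barrel with its lumen-occluding coiled-coil removed — together with the
synthetic data generators used to validate them end to end. This note
documents the models, the parameters that matter, the numerical choices,
and what the synthetic generators do and do not emulate.

## 1. Ion-permeation arm

### 1.1 Counting model

The ionic current through the pore is obtained by counting complete
directional translocations in an ion trajectory:

    I = (N_K + N_Cl) · e / Δt,        G = I / V,

where `N_K` is the number of K⁺ ions that traverse the pore in the +Z
direction, `N_Cl` the number of Cl⁻ ions that traverse in −Z, `e`
= 1.602 × 10⁻¹⁹ C, `Δt` the analyzed duration and `V` the applied voltage.
Counter-productive crossings (K⁺ in −Z, Cl⁻ in +Z) are tallied and
reported but never enter `N_K`/`N_Cl` — the counting equation is applied
literally. A signed net current including them is available separately
and is the quantity tested against zero at V = 0. Replicate runs are
aggregated as mean ± sample SD (n − 1).

"Traverse" needs a definition robust to boundary dithering. We use
two-plane hysteresis: the counter arms when an ion leaves the reservoir on
one side of the membrane slab and fires only when it reaches the opposite
reservoir; excursions into the slab that return to the same side count
nothing. On periodic trajectories the z coordinate is first unwrapped
(minimal-image; a jump of exactly half the box is read as physical motion,
not a wrap) and the slab is repeated periodically, so reservoir recycling
across the box boundary can never masquerade as a translocation. A
single saved frame that jumps across both planes still counts once and is
flagged as sparse sampling. The implementation is validated exactly
against an independent frame-by-frame automaton on randomized paths.

Counting planes default to the membrane slab faces; an optional radial
cutoff can restrict counting to paths through the pore lumen (irrelevant
for the surrogate geometry, where the membrane is impermeable).

### 1.2 Brownian-dynamics surrogate

No raw MD trajectories are distributed with the study this package
models, so the generator is a first-class component: an overdamped
Brownian-dynamics model of point ions in a periodic box with an
impermeable membrane slab pierced by one cylindrical pore.

Euler–Maruyama stepping: per time step δt each ion moves by
(D/kT)·F·δt + N(0, 2D·δt) per axis. Species carry ±e and their
infinite-dilution diffusion coefficients. Defaults (chosen once):

| parameter | default | rationale |
|---|---|---|
| box | 6 × 6 × 12 nm | reservoirs ≈ 4 nm deep, lateral room for access flow |
| membrane slab | z ∈ [4, 8] nm | 4 nm hydrophobic span |
| pore radius | 0.25 nm | narrow-pore regime; Nernst–Einstein conductance 0.74 nS (sub-nS, matching the measured scale) |
| temperature | 298.15 K | recording/simulation temperature |
| KCl | 1.0 M | recording/simulation electrolyte |
| voltage | +150 mV | applied potential, trans (+Z) side positive |
| D(K⁺), D(Cl⁻) | 1.96, 2.03 nm²/ns | infinite-dilution values |
| δt | 1 ps | RMS step 0.064 nm ≪ pore radius; conductance changes < 10% under δt/4 |
| save interval | 10 ps | resolves sub-ns dwells without oversized outputs |
| duration | 50–150 ns | per analysis, see §4 |

Ion numbers follow from the nominal concentration times the
solvent-accessible volume (box minus membrane matrix), in equal K⁺/Cl⁻
numbers, so the reservoirs sit at the stated bulk concentration. Ion–ion
interactions are neglected (mean-field neutrality only).

**Field geometry.** A uniform field confined to the slab with the whole
drop across it starves the pore mouths at +150 mV (qV/kT ≈ 5.8): carriers
are extracted faster than bare diffusion resupplies them and the
conductance saturates well below the ohmic value — we measured the
deficit growing with voltage exactly as a capture-limited model predicts.
A real electrolyte avoids this through its access (spreading) field, so
the simulator partitions the applied drop the same way: the pore carries
V·R_p/(R_p + 2R_a) as a uniform axial field, and each reservoir carries
the spreading potential of its mouth — a monopole tail φ ∝ V_a·r₀/r
outside r₀ = 2a/π, with V_a = V·R_a/(R_p + 2R_a), using the geometric
resistance ratio R_a/R_p = πa/4L. The access drift then resupplies the
mouths at exactly the ohmic rate. With this geometry the no-trap
conductance reproduces the Nernst–Einstein closed form

    G_NE = (e²/kT)(c_K D_K + c_Cl D_Cl) · πa²/L

to within ~13% (the residual being the access share πa/2L ≈ 10% plus
stepping effects), which is the basis of the 25% validity check.

**Walls.** The pore wall uses billiard reflection (the lateral step is
reflected across the tangent at its wall-crossing point); membrane-face
hits from the reservoirs reject the move. Both rules were verified to
preserve the equilibrium density profile in the narrow-pore regime;
naive radial folding or global move rejection measurably bias either the
in-pore density or the near-wall axial mobility.

**Constriction trap.** The wild-type arginine constriction binds anions
*and* impedes them. A bare attractive well cannot do the second — in
steady state a well lengthens residence but leaves the flux unchanged
(only barriers add 1-D Nernst–Planck resistance) — so the trap is a
Gaussian well of depth U₀ (default 4 kT, half-width 0.3 nm, mid-slab)
plus a Gaussian barrier of height 1.25·U₀ centered two half-widths on
the anion-exit side, both acting on Cl⁻ only. One scale parameter U₀
therefore controls both signatures; U₀ = 0 is the double-glycine mutant
surrogate. At the defaults the trapping pore conducts ≈ 0.67× the
trap-free pore, matching the scale of the reported wild-type/mutant
contrast (0.28 vs 0.40 nS), with Cl⁻ dwell times in the constriction
window growing monotonically in U₀.

### 1.3 Dwell analysis

A dwell event is a maximal run of saved frames with z inside a chosen
axial window (default: trap center ± half-width). Durations follow the
half-open frame convention (k frames at save interval h ⇒ duration k·h);
runs separated by at most `gap_frames` outside frames can be merged, and
runs shorter than `min_duration` are dropped. For "trapping events" in
the surrogate a 1 ns threshold is a reasonable default; *mean dwell
comparisons across trap depths use min_duration = 0*, because at depth 0
the window is transited in tens of ps and essentially no dwell survives a
1 ns filter — a conditional mean over an almost-empty set would be
undefined. Dwell summaries report count, mean, median, max and total
occupancy per species.

### 1.4 RMSD

Structural-stability series use the Kabsch algorithm (SVD
superposition with the proper-rotation sign fix) per frame against a
reference frame; superposition can be disabled for raw RMSD. When
reading structured MD files the selection is by ion/atom name map;
backbone selections are the conventional choice for protein stability.

## 2. Electrophysiology arm

### 2.1 Acquisition model (trace generator)

Synthetic recordings emulate the planar-bilayer acquisition chain:
+150 mV holding potential, 20 kHz sampling, 4-pole Bessel-type low-pass
at 4 kHz. The filter is applied zero-phase (forward–backward with the
Bessel kernel): this reproduces the amplitude response without
introducing a group delay into the rendered ground truth — boundary
recovery is then a property of the analysis, not of an arbitrary delay
convention. Gaussian white noise (default SD 2 pA before filtering,
≈ 1.1 pA after) is added ahead of the filter.

Events are drawn from a labelled mixture (defaults: 55% step-like, 25%
multi-level, 20% erratic) and placed sequentially with exponential
closed gaps (mean 1/event_rate plus a 0.2 s floor), so they can never
overlap; a fixed recording length that cannot hold the drawn events is
an error.

* **Step-like**: one level, conductance from the law below, duration
  log-normal (ln T ~ N(0.624, 0.9²) in seconds).
* **Multi-level**: 2–3 levels, each dwelling 0.1 s + log-normal
  (N(−1.2, 0.8²)), consecutive levels redrawn until ≥ 0.05 nS apart so
  they are genuine distinct states.
* **Erratic**: 5–15 flickers of 5–60 ms separated by 2–10 ms closures,
  amplitudes jittered ×U(0.8, 1.3) around a base conductance (redrawn
  to ≥ 0.12 nS so every flicker clears a 5σ detection threshold).
* **Control (fusion) mode**: single rectangular transients with
  log-normal durations (N(−1.036, 1²) ⇒ ≈ 85% under 1 s), emulating
  transient liposome fusion.

The class duration laws were set once so that, across the mixture,
≈ 54% of pore-mode events exceed the 1 s criterion — the proportion
reported for the real pore (63/116) — and control events are dominated
by sub-second transients (> 80% under 1 s).

**Step-conductance law.** Conductances are summarized in the source
study as median (IQR) = 0.17 (0.12–0.32) nS. A two-parameter log-normal
cannot reproduce these three numbers (its quartiles are geometrically
symmetric about the median: √(0.12·0.32) = 0.196 ≠ 0.17), so the law is
a *shifted* log-normal G = γ + exp(N(μ, σ²)) with γ solving
(med−γ)² = (q1−γ)(q3−γ): γ = 0.095 nS, μ = ln 0.075, σ = ln 9 / (2·z₀.₇₅)
≈ 1.629. All three target quantiles are then matched exactly. Draws
above 2.5 nS are redrawn (≈ 2% of mass): a single channel tens of nS
strong is not physical, and one such event would dominate a whole trace.

### 2.2 Idealization pipeline

1. **Baseline/noise**: mode of a Gaussian-smoothed amplitude histogram
   over a quantile-clipped range (0.1st–90th percentile, 512 bins);
   among comparable modes (≥ 10% of the tallest) the lowest-current one
   is the closed state, flagged as bimodal when several exist. Scale is
   1.4826 × MAD of the samples within ±6 pA of the mode.
2. **Detection**: maximal runs of |I − baseline| > k·σ (k = 5; absolute
   floor 0.5 pA when σ = 0), gaps shorter than a 15 ms debounce merged
   (so flicker closures stay inside one event), runs under 10 ms
   dropped. Each edge is then refined to the half-amplitude crossing of
   its *local* plateau (median of the first/last 10 ms) — the standard
   single-channel convention; a global plateau would misplace edges of
   multi-level events.
3. **Sub-levels**: binary segmentation minimizing within-segment sum of
   squares with a BIC-style acceptance penalty (10·σ²·ln n), minimum
   segment 20 samples (1 ms), adjacent segments re-merged when their
   means differ by < 3σ. A segment is *stable* iff its robust SD
   (1.4826 × MAD, insensitive to edge transients) is within 1.5σ and it
   dwells ≥ 50 ms; it is *open* iff its mean deviates > 2.5σ from
   baseline. With σ = 0 an absolute floor of 0.25 pA stands in for the
   noise scale.
4. **Classification**: distinct stable conductance states are stable
   open segments clustered to 4σ. Step-like ⇔ exactly one distinct
   state and ≤ 10% of the event unstable; multi-level ⇔ ≥ 2 distinct
   states and not unstable-dominated (≤ 50%); erratic otherwise.
   Requiring *distinct* states is what separates genuine sub-conductance
   structure from flicker bursts that happen to contain two longish
   openings at the same level.
5. **Summaries**: step-like conductance = mean of the single stable
   segment (excluding edge transients) minus baseline, over V; cohort
   summarized as median (IQR) through the same quantile code path used
   everywhere (linear-interpolation convention), with a 0.05 nS-bin
   histogram. Duration comparisons report per-group fractions exceeding
   a 1 s cutoff and a two-sided Brunner–Munzel test; groups under 10
   events are flagged low-power but still tested.

All thresholds above are declared defaults exposed as keyword arguments,
not inferences about the original study's (unpublished) analysis
settings.

## 3. Statistical kernel

The Brunner–Munzel test is implemented from its defining formulas:
midranks over the pooled sample and within groups, the relative effect
p̂ = P(X<Y) + ½P(X=Y) from mean pooled ranks, rank-based variance
estimates, a studentized statistic referred to a t distribution with
Satterthwaite degrees of freedom. Ties are exact via midranks. With zero
rank variance in both groups (complete separation, or two identical
constant samples) the statistic is reported at its documented limit
(±∞, or 0 with p = 1) and flagged degenerate. The implementation agrees
with an independent reference to < 10⁻⁶ on fixed samples and holds a
5.0 ± 0.5% empirical size at α = 0.05 under the null (n = m = 30).

`median_iqr` uses linear interpolation between order statistics (the
common default), `mean_sd_sem` the n−1 sample SD with SEM = SD/√n; a
single observation reports SD 0 with an explicit "undefined by
convention" flag.

## 4. Problem sizes used in validation

The acceptance script and the end-to-end tests run, per invocation:
10 × 100 ns trap-free replicates for the Nernst–Einstein check and
10 × 20 ns runs at 0 mV; 10 paired 150 ns replicates per condition for
the wild-type/mutant contrast and 10 × 50 ns per depth for the dwell
monotonicity scan; two 60-event recordings (≈ 4 minutes of 20 kHz trace
each) plus one 20-event noise-free recording for the idealization round
trip; a 1,000-event conductance cohort; 100 duration-comparison repeats
(n = 116 vs 100); and 10,000 null replicates for test calibration.
These sizes put every Monte-Carlo standard error well inside the
tolerance it is checked against.

## 5. What the generators do and do not emulate

The Brownian surrogate reproduces drift–diffusion permeation, access
limitation, anion-selective trapping and replicate-to-replicate
variability, and its conductance sits in the measured sub-nS regime. It
omits everything atomistic: explicit water and electro-osmotic flow,
ion–ion correlations (no saturation or single-file blocking), protein
flexibility and position-dependent diffusivity. Quantitative agreement
with the all-atom currents is therefore not expected and not claimed —
the printed wild-type/mutant currents enter only through the exact
Ohm's-law conversions, while the surrogate is held to closed-form and
qualitative-contrast checks.

The trace generator reproduces the event phenomenology and acquisition
chain but not capacitive transients, line interference, slow baseline
drift, or gating kinetics with memory (no Markov state structure).
Passing the round-trip criteria therefore demonstrates that the
idealization recovers events of the documented classes at realistic
SNR — not that it is robust to every artifact of real recordings.

## 6. Reproducibility

Every stochastic component consumes a single integer seed through
`numpy.random.Generator(PCG64)`; identical configurations (seed
included) give bitwise-identical trajectories and traces. The compiled
stepping kernel and the pure-numpy fallback implement the same update
rule; which one runs is a performance detail recorded nowhere in the
outputs. CLI runs write a manifest (tool, version, config hash, seeds,
paths) next to their outputs.
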