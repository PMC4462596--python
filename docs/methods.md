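# Methods

## Model

The model couples the mammalian core circadian loop to NAD metabolism in 11
ODEs.  State variables: CRY/PER mRNA `M`, free BMAL1/CLOCK `TF`, CRY/PER
monomer `CP` and dimer `CP2`, NAMPT mRNA `N` and protein `NP`, fractional
promoter histone acetylation `AC_CP`/`AC_NP`, promoter accessibility
`OP_CP`/`OP_NP`, and `NAD`.  Two algebraic quantities follow from
conservation: the inactive complex `IC = TFtot − TF` (BMAL1/CLOCK is a
conserved pool) and total PER `CPtot = CP + 2·CP2 + 2·IC`.  Concentrations
are in arbitrary units, rates in 1/h.

Assumptions inherited from the lineage the model belongs to:

- CRY and PER paralogs are merged into a single repressor species; only
  PER stoichiometry is tracked inside complexes.
- SIRT1 protein is constant; only its activity varies, through NAD
  availability.  All five SIRT1 reactions (on `IC`, `CP`, `CP2`, `AC_CP`,
  `AC_NP`) share one two-substrate Michaelis-Menten law
  `V·S·NAD/(ka·kb + kb·S + S·NAD)` with the same `ka`, `kb` constants.
  Each reaction debits NAD one-for-one, so the five terms reappear with
  matching magnitude in dNAD/dt (asserted structurally in the tests).
  The denominator is used exactly as specified for this model; it omits
  the `ka·NAD` cross-term of textbook ordered bi-bi kinetics.
- Transcription is gated by promoter accessibility, which relaxes toward
  `AC^nac` with promoter-specific time constants; acetylation is driven by
  TF (CLOCK acetyltransferase) and antagonized by the PER dimer through
  the promoter-occupancy factor `[TF/(TF+K_TF)]·[K_CP2/(K_CP2+CP2)]`.
- PARP1 is a first-order NAD sink (`kPARP·NAD`); CHK2 phosphorylation
  (`kchk2` on free PER species, `kchk2c` on complexed PER) marks PER for
  degradation.  Both are zero except during simulated DNA damage.
- Dexamethasone enters as an additive CRY/PER transcription rate `Dex`;
  a 12 h on / 12 h off square wave at `Dex = 0.125` serves as the
  entrainment (zeitgeber) surrogate.

### Sign resolutions

Two signs in the source equations are structurally ambiguous, and the
package resolves both through `ModelVariant` flags (defaults validated by
the 23.8 h free-running period):

- **SIRT1 action on the inactive complex** (`tf_sirt1_release`, default
  True): SIRT1 deacetylation of BMAL1 destabilizes the CRY-BMAL1
  interaction, so the term *releases* free TF (`+` in dTF/dt).  The
  opposite sign makes SIRT1 a ~0.09 AU/h drain on TF against ~0.004 AU/h
  of sources, drives TF negative and destroys the oscillation.
- **NAMPT promoter acetylation** (`nampt_acetylation_gain`, default True):
  the CLOCK-driven acetylation term is a gain, `+knpac·(1−AC_NP)`,
  mirroring the CRY/PER promoter equation.  With a loss sign the
  acetylation variable leaves [0, 1] immediately.

### 0/0 conventions and guards

`promoter_acetylation_rate` defines indeterminate 0/0 quotients as 0 (the
inert limit used by the core-model parameter set, where all four binding
constants are zero).  `AC^nac` with `AC = 0, nac = 0` evaluates to 1, which
the core-model reconstitution requires.  State components more negative
than −1e−6 raise; smaller undershoots (stiff-solver noise) are clamped
before power/quotient terms.

## Numerics

LSODA with rtol 1e−8, atol 1e−10, output step 0.05 h (defaults).  Halving
both tolerances changes the estimated period by < 0.01 h, and halving the
output step moves CP peak times by < 0.05 h (both tested).  The right-hand
side is numba-compiled; a 20-day simulation takes tens of milliseconds.
Forcing discontinuities are never stepped over: the integration is split at
every schedule breakpoint, the segment endpoint is evaluated explicitly,
and the solver restarts from it.  Pulse intervals are half-open
`[start, start + duration)` and *replace* the baseline parameter value.

Standard analysis windows: 20 simulated days with the first 5 discarded as
transient.  After the transient, consecutive CP cycle lengths agree to
better than 0.05 h (limit-cycle convergence, tested).

## Rhythm analysis

**Period** — downward mean-crossings of the series (value above the mean
followed by a value below; the crossing is assigned to the later sample),
averaged crossing-to-crossing; at least seven full oscillations are
required, otherwise the error code −1 is returned.  Periods are always
computed on the CP series.  Sub-grid interpolation is deliberately not
used: with a 0.05 h grid and ~14 averaged cycles the estimator resolves
~0.004 h.

**Amplitude** — peak-to-peak (max − min) of the post-transient series; the
relative NAD amplitude is reported as (max − min)/max by default, with
min- and mean-referenced alternatives available.

**Phase shift** — CP peak times (3-point parabolic refinement on the grid)
of an unperturbed and a perturbed run are compared at evaluation day 19 and
wrapped into (−12, +12] h; positive = advance.  Because the free-running
period P = 23.832 h differs from the 24 h wrap modulus, the peak-pairing
convention offsets every shift by a multiple of 24 − P = 0.168 h.  The
default ("bracket") pairing — unperturbed reference is the last peak
*before* day 19, perturbed is the first peak *at/after* day 19 — is the
convention that reproduces the published damage-battery statistics to
~0.01 h for the CHK2-only configuration; `first_after` and `nearest`
pairings are available as flags.

**PRC protocol** — a free-running reference defines circadian hour 0 at its
first CP peak after the 5-day transient; 24 treatment start hours, one
hour apart, each receive co-timed 2 h pulses (the stated duration of the
damage protocol; used for all pulse types).  `kchk2c` is not pulsed with
`kchk2`.  Summary statistics: max advance, max delay (signed), their ratio
(+inf when nothing delays), and the positive area fraction A⁺/(A⁺+A⁻) of
the piecewise-linear PRC treated as a closed curve over the circadian
cycle (the wrap-around segment makes the statistic exactly invariant under
rotation of the anchor, which is also tested).  A PRC is classified Type 0
when the largest circularly-adjacent jump exceeds 6 h, else Type 1.

### Known sensitivity of the summary statistics

The area fractions and the period are robust (insensitive to comb
alignment and pairing at the 0.01 level).  The advance-to-delay *ratio* is
not: it divides by the sampled maximum delay, which for strongly advancing
configurations is a few minutes of peak timing after a 19-day simulation.
Fractional alignment of the hourly treatment comb — which no protocol
statement fixes — moves sampled lobe extremes by up to ~0.1 h, and the
ratio amplifies this without bound as the delay lobe shrinks.  The package
therefore anchors the comb exactly at a reference CP peak (offset 0) and
reports the ratio as computed; for the combined low-damage configuration
(kchk2 = 0.1, kPARP = 10) and for the reconstituted core model the ratio
should be read with this caveat (the core-model ratio computed here, 3.55,
matches the value originally published for that model, 3.54).

## Experiments

- **Robustness sweep**: every parameter individually scaled by 0.8 and 1.2,
  free-running period and peak-to-peak mRNA amplitude per row; failures are
  recorded per row, never abort the sweep.  The four stress inputs are zero
  at baseline and scaling leaves them zero, so their rows equal baseline.
- **Inhibition scan**: `VNADc`, `VSIRT1c` or `VSIRT1d` scaled into (0, 1];
  per-factor percent change of the steady-state CRY/PER mRNA level over
  the final 5 days.  Two level statistics are exposed: the cycle maximum
  (default, the figure-style measure) and the time average; for a 75%
  NAD-biosynthesis reduction they give −15.6% and −12.1% respectively, and
  the quoted ~12% level drop corresponds to the time-averaged measure.
- **Damage battery**: 24-start-hour PRCs for each (kchk2, kPARP)
  configuration with simultaneous 2 h pulses, tabulated in the published
  four-statistic schema; the core-model reconstitution runs the same
  protocol on the `hong2009` parameter set.

## Validation strategy and limits

The test suite checks the right-hand side term-by-term against an
independent transcription of the printed equations, the full integrator
against an independent minimal implementation of the four-variable core
model (< 1e−6 relative error over five days), the reaction-network view
(45 labeled processes; stoichiometry-weighted rate sum equals the rhs to
1e−10), the period estimator on closed-form sinusoids, and the PRC summary
arithmetic against brute-force recomputation.  There are no stochastic
elements anywhere; identical inputs give bit-identical trajectories.

The model makes no claim to absolute concentrations (all species are in
arbitrary units), contains no nicotinamide intermediate, no NMNAT1 step,
no PARP1 auto-modification feedback, and no cell-to-cell coupling; PRC
statistics quantify this single deterministic oscillator, not a
population.  Parameter values are taken as given; no fitting is performed.
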