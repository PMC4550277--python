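# Methods

This note documents the models implemented in `eggshed`, the parameter
defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical choices made where the design was
genuinely open.

## Barcode species assignment

Reads are compared to references by global alignment with free terminal
gaps (semi-global): truncated Sanger reads of a homologous amplicon
should not be penalized for missing ends. Identity is matches divided by
aligned columns after trimming terminal-gap columns; internal gaps count
as mismatches. Alignment uses match +1, mismatch −1, gap open −3,
extend −1; identity fractions are insensitive to moderate changes in
these scores because reads are near-homologous to their references.

The assignment ladder:

1. Rank the read's identity against every same-locus reference; reduce
   to a best hit per species.
2. If the best identity ≥ 0.95 and no other species is "close" to the
   best-hit reference, assign (`unique_threshold`).
3. "Close" species are operationalized as any second species whose
   reference-to-reference identity with the best hit is ≥ 0.99
   (configurable). When close species exist, the diagnostic-site rule is
   evaluated **before** raw identity: close congeners are, by
   construction, separated by fixed differing nucleotide positions, so a
   read covering ≥ 2 diagnostic positions and agreeing with exactly one
   species at *all* covered positions is assigned (`diagnostic_sites`).
   One contradicting site vetoes the diagnostic path — a conservative
   reading of "two or more covered sites are adequate".
4. Otherwise, best identity ≥ 0.99 assigns the best hit
   (`high_identity`) — this fires when diagnostics are unavailable or
   not covered.
5. Best ≥ 0.95 without resolution → `ambiguous`; below 0.95 →
   `unassigned`. Ties at the top are never broken arbitrarily.

A minimum aligned length (default 150 bp) guards against spuriously
perfect identities on very short overlaps; the value is a config choice,
not a claim about any particular survey protocol.

In-silico PCR anneals primers by Hamming distance (no indels) with ≤ 2
mismatches and none in the 3 terminal 3′ bases; surveys do not report a
mismatch tolerance for their primers, so this is a standard permissive
default. Product length is the span between outer primer ends and is
invariant to flanking sequence.

## Lagrangian surface transport

Tracer positions advance by explicit Euler with Δt = 1 h, matching the
hourly cadence of gridded surface-current maps (the discrete sums the
scheme implements are exactly the hourly cumulative displacement):

    x(t+Δt) = x(t) + (u + ε_u) Δt

with ε_u, ε_v independent zero-mean **Gaussian** draws per component,
step and tracer, rms ε. Only the mean and rms of the noise are
physically specified; Gaussian is the maximum-entropy choice. The
default ε = 5 cm/s represents unresolved velocities; 8.6 cm/s (a typical
HF-radar rms error against drifters) is a documented alternative via the
`epsilon` parameter. Optional substepping subdivides Δt for convergence
experiments.

Backward-in-time (BIT) integration applies the identical update with
the time axis reversed (position decremented by the interpolated
velocity at the backward time step), tracing arrivals at a fixed
collection point to their probable sources. Noise is drawn identically
in both directions; backward "diffusion" as source uncertainty is a
modeling choice, not a physical time reversal. With zero noise the
FIT/BIT pair inverts exactly in a homogeneous static field; in time- or
space-varying fields the per-step round-trip error is O(Δt²) (Euler),
which the tests verify by step-halving. Exact inversion through a
spatially varying field would require an implicit scheme and is not
attempted.

Velocity sampling is bilinear over valid grid cells (invalid-corner
weights are zeroed and renormalized) and linear in time between hourly
maps. Inside the nearshore band (default width 1000 m, the unobserved
strip inshore of typical HF-radar coverage) tracers move with the
along-coast projection of the velocity probed one band-width offshore of
the nearest coastline point. Tracers stepping onto land are snapped to
the nearest coastline point and remain active — consistent with
along-coast advection rather than absorption; an absorbing variant is
available (`beaching="absorb"`). Tracers leaving the grid are frozen as
`exited`. The three statuses partition every release.

Releases are 50 tracers/hour (default) at the source for every hour of
the event window: 3 days for spawning hindcasts (the assumed egg
hatching time at ~18 °C), 20 days for larval forecasts. Kernels
accumulate *hourly position snapshots* per grid cell — not continuous
path length — matching the data cadence and the count-ratio definition
P = 100·F/max F. Cells never visited have P = 0; max P = 100 whenever
any cell is visited. The spatial accumulation grid defaults to the
current-field grid; both are configurable because no canonical kernel
resolution exists.

Positions live in a local equirectangular projection (meters from the
grid origin); lon/lat inputs would be converted at read time using the
grid mid-latitude, since the update integrates Cartesian velocities.
Coastlines are ordered polylines with land to the left of the walking
direction.

## Community and phenology statistics

- **Tow volume**: pulls · π(d/2)² · depth. Four pulls of a 1 m net over
  5 m water ≈ 15.7 ≈ 16 m³.
- **Collection temperature**: mean of the 10 nearest readings before and
  10 after the tow; fewer than 10 on either side yields a missing value
  with a warning.
- **Temperature split**: collections split at the grand mean
  temperature; egg totals compared by a two-sided pooled-variance
  Student t-test (df = n₁+n₂−2 — the pooled form is what a reported
  df of group sizes minus two implies). Cold-water spawners can be
  excluded and tested separately, since their negative association
  would dilute the community-level signal.
- **Seasonal ANOVA**: one-way fixed-effects over season × collection-year
  groups, Tukey HSD post hoc (studentized range). Seasons are
  meteorological (Dec–Feb winter, etc.) and the collection year starts
  in September; surveys rarely state their season boundaries, so these
  are package conventions. A zero-variance layout is reported as
  degenerate (F undefined) rather than an error.
- **Bray-Curtis / PERMANOVA / NMDS**: monthly mean abundances are
  log(x+1)-transformed before Bray-Curtis. PERMANOVA partitions squared
  dissimilarities (SS_total = Σd²/n; within-group analogously), with
  pseudo-F = (SS_b/(a−1))/(SS_w/(n−a)) and p = (#{F* ≥ F}+1)/(n_perm+1)
  under unrestricted label permutation (one-way design). An exhaustive
  mode enumerates all distinct label arrangements for exact small-n
  p-values. Pairwise tests rerun the same machinery per group pair,
  unadjusted by default (optional Bonferroni); proprietary "Monte
  Carlo" pairwise p-values fit an asymptotic permutation distribution
  instead — the pure-permutation p reported here differs slightly by
  construction. NMDS minimizes Kruskal stress-1 by SMACOF with isotonic
  regression of the disparities (scikit-learn backend), best of 20
  random starts, tolerance 1e-6.
- **Yates chi-square**: X² = Σ (max(|O−E|−0.5, 0))²/E on 2×2 tables.
  The correction is clamped at |O−E| so near-null tables cannot
  overshoot past zero; the unclamped variant is available for
  comparison. On the marker-bias table (6, 895 / 0, 12348) this gives
  68.2 with 1 df.
- **Wilcoxon signed-rank**: zeros dropped, ties mid-ranked, T = smaller
  signed-rank sum; exact p for n ≤ 25 without ties, otherwise normal
  approximation with continuity correction.
- **Presence tables**: per species × month, the fraction of that month's
  collections containing the species, binned at ≥0.90 / ≥0.75 / ≥0.50 /
  ≥0.25 / >0 / 0.

## Synthetic data: what it emulates, what it does not

All generators are pure functions of their parameter objects (seed
included) and emit planted truth alongside the data.

**Reference DB.** A random root sequence diverges along a star phylogeny
— the simplest structure giving direct control of pairwise divergence —
at 0.08 substitutions/site between non-sister species (comfortably
above every assignment threshold). Each sister pair differs at exactly
5 planted diagnostic positions in 660 bp (identity ≈ 99.2%), the hardest
real discrimination case the rules must solve. Substitutions are uniform
over the three alternative bases: the assignment rules depend only on
identity fractions, so transition/transversion bias would add realism
without changing what is being tested. Real barcode databases have
phylogenetic correlation structure, length variation, ambiguity codes
and intraspecific polymorphism that the generator omits — passing tests
demonstrate the *rules*, not robustness to curation artifacts.

**Reads.** Each read copies its species' reference, loses up to
`truncation_range` bases from the ends (uniform total, uniform split),
and mutates with i.i.d. substitutions (default rate 0.005/site ≈ 3.3
errors per full read). Truth records the retained interval and how many
planted diagnostic sites survive; fewer than two is flagged as
insufficient coverage. Chimeras, indels and base-quality structure are
not modeled.

**Current fields.** Analytic regimes — uniform flow, solid-body gyre
(u = −ω(y−y_c), v = ω(x−x_c), edge speed u0), and sinusoidally modulated
uniform flow — with optional zero-mean Gaussian cell/hour noise of given
rms. The coastline is the vertical line x = 0 with land to the west.
Defaults (10–20 km grids, 500–1000 m spacing, ~10 cm/s speeds) match
coastal HF-radar scales. No geostrophy, tides, shear dispersion or data
gaps: transport tests verify the integrator and kernel bookkeeping
against closed forms, not ocean realism.

**Collection series.** Deterministic tow schedule at 2.5/week over 744
days — 266 collections, the size of a two-year, twice-plus-weekly pier
survey. Species counts are Poisson with a wrapped-Gaussian seasonal
intensity (peak day-of-year, width, amplitude per species) times a
log-linear temperature factor exp(s·β·(T−T̄)) with sign s per species
(−1 for the anchovy-like cold-water spawner) and β = 0.15/°C, a
moderate effect that the planted-power tests must detect at n = 266
without being trivially large. Temperature is a seasonal sinusoid
(mean 17.8 °C, amplitude 3.5 °C, peak mid-August — Southern California
shelf values) plus a small diel cycle and noise, sampled half-hourly.
The default community (two dominant long-season spawners, several
spring–summer peakers, one winter cold-water spawner) mirrors the
qualitative structure of a real nearshore ichthyoplankton series.
Zero-inflation beyond Poisson, multi-day autocorrelation, and
effort variation are not modeled.

## Problem sizes and reproducibility

The test suite and the acceptance script run releases of 10–1000
tracers over 12–72 hourly steps on 15–40 cell grids, 100–500 replicate
simulations for calibration and power checks, and 199–999 permutations
per PERMANOVA — sizes chosen so each property is measured with adequate
Monte-Carlo precision while the whole suite stays quick on one CPU. One
global seed fans out to per-stage seeds by fixed offsets
(`pipeline.SEED_OFFSETS`), so every stage is independently reproducible
and reruns with the same config are identical.

## Known limitations

- Exposure kernels count hourly snapshots; sub-hourly residence inside a
  cell is not resolved.
- The along-coast projection uses a single probe point one band-width
  offshore; strongly curved coastlines would warrant averaging along
  the normal.
- PERMANOVA p-values are pure-permutation; for very small groups the
  attainable floor is limited by the number of distinct relabelings
  (random permutation can redraw the observed labeling).
- The NMDS convergence flag reflects the SMACOF iteration cap of the
  best start, not a global optimality guarantee.
- Assignment treats IUPAC ambiguity codes and N as mismatches; a
  degenerate-base-aware matcher would be slightly more permissive.
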