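# eggshed

Tools for molecular monitoring of fish spawning in coastal waters:
DNA-barcode identification of individually sampled fish eggs, phenology
and community statistics for the resulting collection time series, and a
stochastic Lagrangian surface-transport model whose backward-in-time
exposure kernels localize where the collected eggs were probably
spawned.

The intended user is an ecologist or oceanographer running (or
simulating) a pier-based ichthyoplankton survey: repeated vertical
plankton-net tows, per-egg amplicon sequencing of the COI barcode (with
a 16S rRNA fallback), and hourly gridded surface-current maps of the
adjacent coastal ocean.

## What it computes

**Species assignment.** Each egg read is compared to a barcode reference
database by semi-global pairwise identity. A read is assigned when it
matches a reference at ≥95% identity with no closely related alternative
(reference-to-reference identity ≥99%), by species-diagnostic nucleotide
positions when close congeners exist (≥2 diagnostic sites covered, all
agreeing with one species), or at ≥99% identity as a fallback. An
in-silico PCR pre-screen reproduces the amplicon-length shortcut for
species with dedicated primers (e.g. 430 bp and 205 bp products against
the generic 710 bp COI amplicon).

**Transport kernels.** Water tracers are integrated through hourly
current maps `u(t, x, y)` with an explicit Euler scheme and a stochastic
velocity component,

```
x(t+Δt) = x(t) + (u + ε_u) Δt,    y(t+Δt) = y(t) + (v + ε_v) Δt,
```

where `ε_u, ε_v` are zero-mean draws with rms ε = 5 cm/s. Releasing 50
tracers per hour at the collection point and integrating 3 days
backward-in-time (the assumed egg hatching window) gives per-cell visit
counts `F(x, y)`; the coastal exposure kernel

```
P(x, y) = 100 · F(x, y) / max F
```

is the relative probability (percent) that the collected eggs were
spawned in each cell. The same machinery run forward-in-time over a
multi-week window maps larval dispersal and retention.

**Community statistics.** Tow-volume effort normalization
(`pulls · π (d/2)² · depth`), sliding-window abundance, pooled-variance
t-tests of egg totals split at the mean seawater temperature,
season-by-year ANOVA with Tukey HSD, Bray-Curtis dissimilarities of
log(x+1) monthly mean abundances with one-way PERMANOVA (pseudo-F,
permutation p) and NMDS ordination (Kruskal stress-1), Yates-corrected
2×2 chi-square for marker-bias checks, the Wilcoxon signed-rank test,
and monthly presence-fraction tables.

No sequencing archive or current-map archive ships with the package; the
`synthetic_data` module generates all five inputs with planted ground
truth (diagnostic sites, read labels, seasonal peaks, source locations)
so every stage is testable end to end.

## Worked example

```
python analysis/01_simulate_inputs.py
python analysis/02_assign_species.py
python analysis/03_seasonality_stats.py
python analysis/04_transport_kernels.py
python analysis/05_marker_bias.py
```

On the default synthetic survey (40 reference species with two
~99.2%-identical congener pairs, 300 noisy truncated reads, 266
collections over two years) this prints, among other lines:

```
reads: 300; assigned: 300 (100.0%); accuracy among assigned: 100.0%
method
unique_threshold    264
diagnostic_sites     35
high_identity         1
```

— every read is recovered, with 35 truncated sister-pair reads rescued
by the diagnostic-site rule rather than raw identity;

```
all-but-cold-spawner t-test: t_264 = -19.271, p = 2.88e-52
seasonal ANOVA: F_9,256 = 98.38, p = 7.2e-78
PERMANOVA across months: pseudo-F = 107.41, p = 0.001
NMDS stress-1: 0.050
```

— the planted warm-season spawning signal is detected by the
temperature split and the seasonal ANOVA, months separate in Bray-Curtis
space at the permutation floor p = 0.001, and the 2-D NMDS embedding is
adequate (stress ≈ 0.05); and

```
hindcast (BIT, 3 d): 125412 tracer position-hours, max P = 100% at cell (1250 m, 7250 m)
forecast retention inside the 5x7 km nearshore box: 36.8%
```

— the backward-in-time kernel peaks at the release cell in the weak-gyre
regime (local retention), and roughly a third of forecast larval
position-hours stay inside the nearshore box.

The `eggshed` console script exposes the same stages
(`eggshed simulate|assign|stats|hindcast|forecast|run`).

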