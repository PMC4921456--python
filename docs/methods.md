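# Methods

`igtnet` re-implements, as a tested pipeline over synthetic data, a
rest-vs-task voxel-wise functional connectivity analysis: per-block binary
correlation graphs under a fixed-density rule, Latora–Marchiori efficiency
metrics at whole-brain and regional (DMN/FPN) level, a Jaccard-index
permutation test of hub topography, repeated-measures group statistics, and
an Iowa Gambling Task (IGT) payoff simulator supplying behavioral scores.
This note documents the models, defaults, and design choices.

## Synthetic data generator

The generator emulates the statistical structure the downstream analysis is
sensitive to, at desk scale; it does not emulate MR physics.

**Atlas.** `make_toy_atlas` builds a labeled grid with gray-matter
communities (by voxel count or as spheres in mm space), a CSF slab (bottom
z-plane) and a white-matter slab (top z-plane). The unit-example default is
a 20×20×20 grid of 4 mm voxels. The study-scale atlas
(`default_study_atlas`) instead uses a (24, 26, 18) grid of 6 mm voxels
whose affine places the volume around the origin of a "virtual MNI" mm
space, so the canonical DMN/FPN seed coordinates (|x| up to 55 mm, y from
−61 to 57 mm) fall inside the volume and the packaged ROI table can be used
verbatim; a 20³ grid at 4 mm (span 80 mm) cannot contain those coordinates.
It carries one 10 mm-sphere community per seed (4 DMN, 7 FPN) plus three
generic communities — 265 gray voxels, i.e. a few hundred network nodes, in
the intended 10²–10³ range. A real atlas volume can be substituted by
loading any labeled NIfTI with its own label table.

**Time series.** Gray voxel *i* in community *k* follows a shared-factor
model

    x_i(t) = sqrt(rho_b) u(t) + sqrt(rho_w(k) − rho_b) c_k(t)
             + sqrt(1 − rho_w(k)) e_i(t),

giving an exactly block-compound-symmetric correlation matrix: `rho_w(k)`
within community *k*, `rho_b` between all communities. Positive
semi-definiteness requires `0 ≤ rho_b ≤ min_k rho_w(k) < 1`, validated up
front. All factors are unit-variance AR(1) processes (default coefficient
0.3, a plausible low-frequency BOLD-like autocorrelation at TR = 2 s). On
top of this sit a shared global signal (own SD, default 0.5, so
global-signal regression has a real target), white measurement noise
(SD 0.2), and motion: each flagged volume gets a sustained step in the
emitted 6-parameter motion trace plus a displacement artifact in the data at
that volume, so scrubbing has ground truth. WM/CSF voxels carry a
within-tissue shared factor (correlation 0.5) so tissue-mean confounds are
informative. Defaults: 120 volumes at TR = 2 s per block.

**Conditions.** Rest-like blocks use strong within- / weak
between-community coupling (`rho_w` 0.60, DMN 0.68, FPN 0.55; `rho_b`
0.10). Task-like blocks raise between-community coupling to 0.30, raise FPN
coupling to 0.62 and lower DMN coupling to 0.50, with generic communities at
0.45. Lowering the non-FPN within-community coupling in the task state is
deliberate: under the fixed-density threshold, edges are the top-E
correlations, and with ~110 retained volumes the sampling SD of a
correlation is ≈ 0.1 — if task within-coupling stayed at 0.60 the
between-community tail (0.30) would essentially never reach the cutoff and
the task graphs would be as modular as rest graphs. With these defaults
task graphs recruit a minority of cross-community edges, reproducing the
intended direction of reconfiguration: higher local efficiency and lower
global efficiency at rest than during the task. Rest-like graphs at default
parameters are typically fully modular (several connected components),
which is more extreme than real resting-state graphs; the metrics
(disconnected pairs contribute zero) are designed to remain meaningful.

**Design.** Each subject contributes 12 blocks in the fixed order rest →
IGT → orienting, repeated over 4 sessions; 9 subjects give 108 blocks.
Orienting blocks are generated (task-like parameters) and carried through
network construction, but flagged `analyze=False` and excluded from all
statistics. Per-block seeds derive from one study seed via
`numpy.random.SeedSequence`, so every product is reproducible bit-for-bit.

**What passing tests do not show.** The generator has no hemodynamic
response, no scanner noise spectrum, no realistic motion trajectories, no
spatial autocorrelation beyond community structure, and communities are
internally exchangeable. Passing the directional tests shows the pipeline
detects the modeled reconfiguration, not that real BOLD data would show it.

## IGT simulator

Four decks with fixed reward per card and penalties at fixed positions in a
10-card cycle. Decks 1/3 pay $150, decks 2/4 pay $200; decks 1/2 penalize
once per cycle, decks 3/4 five times; expected net per 10 cards is +$250
(decks 1/3) and −$250 (decks 2/4) — the classic magnitudes. Exact penalty
positions/magnitudes are data on the `DeckSchedule` object and swappable.
Deck state resets per block. Agents: uniform-random, or epsilon-greedy on
each deck's running mean net payoff (default ε = 0.1; ties toward the
lowest deck id). Missed responses (no press within the 2 s window) are
modeled, when enabled, as trials counting toward no deck. Performance is
the net-advantageous score (#decks 1+3 − #decks 2+4).

## Preprocessing

Order: discard first 10 volumes → scrub → gray-matter mask → band-pass →
nuisance regression. Scrubbing removes volumes with framewise displacement
FD(t) = Σ|Δtrans| + 50 mm·Σ|Δrot| above 0.5 mm (Power convention, 50 mm
head radius; first volume FD = 0; no neighbor augmentation — all
configurable). The gray-matter mask is (GM+WM+CSF > 0) ∩ atlas-gray minus
voxels with WM probability ≥ 0.99. The band-pass is a 2nd-order Butterworth
(0.009–0.08 Hz) applied forward-backward (zero phase). Nuisance regressors
(WM mean, CSF mean, 6 motion parameters, global gray-matter mean) are
band-passed identically to the data before per-voxel OLS projection, so
regression cannot reintroduce removed frequencies; the
regression-before-filter order is available by flag since the original
ordering convention is a genuinely open choice. Residuals are exactly
orthogonal to every confound column; rank-deficient designs are rejected
naming the collinear columns.

## Network construction

Pearson correlations between all gray-voxel pairs; the cutoff r* solves the
density rule N = K^S (default S = 2.5): with target mean degree
K = N^(1/S) and E = round(N·K/2) edges (half-up rounding), r* is the E-th
largest positive off-diagonal correlation, and every pair with correlation
≥ r* becomes an edge. Fixing S fixes density across blocks and subjects.
Numerical choices: negative correlations are never edges (the threshold is
a lower bound over the positive tail); ties at r* are all included
(deterministic, order-independent; realized mean degree is recorded and can
exceed the target by the tie count, bounded by 2/N in practice); exact
integer solutions of K = N^(1/S) are returned exactly (float pow is off by
an ulp on cases like 1024^(1/2.5)). A threshold sweep accepts either a list
of S exponents or explicit target degrees (published robustness checks are
sometimes quoted on other thresholding scales); a network that fragments
during the sweep triggers a warning and records its component count, never
a failure.

## Graph metrics

Efficiency uses the Latora–Marchiori mean-of-inverse-distances form:
E_glob = mean over ordered pairs of 1/d(i,j), with 1/∞ = 0. This is the
cited definition, bounded in [0, 1], and finite on disconnected graphs —
unlike the inverse-of-mean-path-length reading, which is undefined there;
the distinction matters because rest-like graphs fragment by construction.
E_loc of a node is E_glob of the subgraph induced by its neighbors (node
excluded); nodes with fewer than two neighbors get 0. A nodal efficiency
map (per-node mean inverse distance) averages exactly to E_glob and
supports volume export. Distances come from unweighted BFS/Dijkstra on the
sparse adjacency; tests verify equality (to 1e−12) with an independent
Floyd–Warshall oracle and with networkx.

## Hub topography comparison

Hubs are the top 20% of each network's degree distribution (ceil(0.2·N)
nodes, extended across ties at the cutoff degree). All-pairs Jaccard
indices (two empty sets count as identical) over the 72 analyzed networks
form a similarity matrix; the statistic is mean within-condition JI divided
by mean between-condition JI (diagonal excluded, each unordered pair once).
The null permutes condition labels — by default independently within each
subject, respecting the repeated-measures structure; free-label permutation
is available. p uses the add-one estimator (1 + #{null ≥ observed})/(1 +
n_perm) with ≥-exceedance (conservative, never zero): with the default 512
permutations the attainable floor is 1/513 ≈ 0.00195, and the result object
records that floor alongside p. When a small design admits fewer distinct
within-subject label patterns than requested permutations, the null is
enumerated exhaustively (with a warning). An all-disjoint between-condition
configuration (between-mean zero) is rejected as degenerate rather than
reported as an infinite ratio.

## Group statistics

**RM-ANOVA.** Balanced fully-within-subject designs only (missing cells are
rejected by name). Each effect is tested against its own subject-by-effect
stratum; partial η² = SS_effect/(SS_effect + SS_error), the convention
consistent with reporting values like η² = 0.53 alongside F(1,8).
Degrees of freedom are uncorrected by default; Greenhouse–Geisser
correction (contrast-based ε per effect) is available by flag. Sums of
squares below a data-scaled numerical floor are treated as exact zeros so
constant data yields F = 0 rather than a 0/0 artifact. The same routine
serves the 2 (condition) × 4 (session), the 2 (network) × 4 (session), and
the one-way behavioral analyses.

**Mixed model.** IGT score ~ intercept + K + E_loc + E_glob with a subject
random intercept and AR(1) within-subject error correlation over sessions
(V_i = σ_b²J + σ_e²R(ρ), R_jk = ρ^|t_j−t_k|), estimated by REML: fixed
effects are profiled out by GLS and the three variance parameters optimized
by Nelder–Mead from three starting points on log-/atanh-transformed scales.
No installed Python mixed-model routine supports this covariance
combination, so the objective is implemented directly; the test suite
verifies coefficients, standard errors and ρ against R `nlme::lme` with
`corAR1` on the same data (agreement to ~1e−4) and checks parameter
recovery and CI coverage by simulation at the study's design size
(9 subjects × 4 sessions). Wald t-tests use df = n − p; non-convergence
raises with optimizer diagnostics.

No multiple-comparison correction is applied across the metric families,
mirroring the reporting style of the analyses this package reproduces; the
ANOVA tables expose raw p-values for any correction a user prefers.

## Orchestration and reproducibility

A YAML config (schema-validated dataclasses) drives six stages — simulate,
preprocess, networks, metrics, hubs, stats — each reading the previous
stage's serialized outputs (NIfTI volumes, NumPy archives, edge lists with
JSON sidecars, CSV tables) from the run directory, so stages rerun in
isolation. A manifest records package version, config hash, seed and
content checksums of every product; identical config + seed reproduce an
identical manifest. The `igtnet` CLI exposes per-stage subcommands and
`run-all`. Problem sizes used by the shipped analysis and the acceptance
script: 9 subjects × 12 blocks on the 265-gray-voxel study atlas, 120
volumes per block — the full run completes in well under a minute on one
core while exercising every stage at the study's real design shape.

## Known limitations

- The generator's rest-like graphs are fully modular (disconnected), an
  idealization of the rest condition.
- Efficiency contrasts between conditions are driven by the chosen coupling
  defaults; they demonstrate sensitivity, not effect sizes of real data.
- The hub permutation test assumes within-subject exchangeability of
  condition labels under the null; session order effects would violate it.
- The mixed model fixes the AR(1) metric to session index distance;
  unequally spaced sessions are treated as equally spaced.
- The IGT agent is a bandit heuristic, not a cognitive model; it produces
  plausible score distributions, not fits to human learning curves.
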