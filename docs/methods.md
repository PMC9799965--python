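# Methods

## Study design and data model

The analysis targets a 2×2 mixed factorial: *time of day* (TOD; a morning
and an evening resting-state session per subject, within-subject) crossed
with *chronotype* (morning-type MT vs evening-type ET, between-subject).
The pipeline starts from preprocessed ROI time series — one T×N numeric
table per subject-session, columns matching a parcellation lookup of N
cortical regions, each pre-assigned to a hemisphere and to one of seven
large-scale functional systems (visual, somatomotor, dorsal attention,
salience/ventral attention, limbic, control/frontoparietal, default).
The default dimensions mirror the emulated study: 31 subjects per
chronotype, 200 regions (ids 1–100 LH, 101–200 RH), T = 325 volumes at
TR = 1.8 s.  Everything upstream (motion correction, normalization,
nuisance regression, band-pass filtering) is out of scope.

## Connectome construction

Connectivity is Pearson correlation across time, Fisher-transformed
(z = atanh r) for variance stabilization.  Before atanh, |r| is clipped
at 1 − 1e-7; the clip only matters for degenerate collinear inputs and
equals ½ln(2/ε − 1) ≈ 8.406 at the clip point.  The diagonal is forced to
zero and the matrix symmetrized.

Binary graphs are obtained by proportional thresholding: at density d the
k = round(d·N(N−1)/2) upper-triangle entries with largest |z| become
edges (magnitude ranking, so strong negative correlations are kept).
Rounding is half-away-from-zero — the rounding rule is not dictated by
the procedure itself, so we fix one and apply it to every subject, which
is what makes densities comparable.  Ties in |z| are broken by ascending
(i, j) pair order; this makes thresholding deterministic and the edge
sets exactly nested across densities.  The analysis grid is d = 0.05 to
0.50 in steps of 0.05.

## Graph measures

All topology is computed on the binary graphs.  Conventions for the
degenerate cases that arise at d = 0.05:

* shortest-path quantities average over *reachable* pairs; a node with no
  reachable partner is excluded from the characteristic path length;
* nodal efficiency treats unreachable pairs as 1/∞ = 0;
* participation of a degree-0 node is defined as 0 (the 0/0 case);
* assortativity of a degree-regular graph (zero endpoint-degree variance)
  is flagged undefined (NaN) and excluded from group statistics.

Synchronizability is the eigenratio S = λ₂/λ_max of the combinatorial
Laplacian D − A.  The raw adjacency spectrum would not yield a
[0, 1]-bounded synchronizability (and can be negative), so the Laplacian
convention — the one standard in the connectomics toolkits this pipeline
mirrors — is used; a disconnected graph has λ₂ = 0, hence S = 0.

Small-worldness σ = (C/C_rand)/(L/L_rand) uses a null ensemble of
degree-preserving Maslov–Sneppen rewirings (igraph's C implementation,
10 swaps per edge, 100 graphs by default; both configurable and seeded).
The ensemble size trades Monte-Carlo error in C_rand, L_rand against run
time; 100 keeps the σ standard error well below session differences at
the default dimensions.

Betweenness is normalized by (n−1)(n−2) ordered pairs so the star center
attains exactly 1.  AUC over the density grid is the trapezoidal
integral, giving threshold-free per-subject scalars.

## Multilayer modularity and allegiance

Layers are *subjects* (their weighted z-matrices, negatives zeroed —
the Newman–Girvan null is undefined for signed weights; the number of
zeroed edges is reported in a warning), not time windows.  Interlayer
coupling is therefore categorical: each region is coupled with strength ω
to its copies in *all* other layers, and community labels live in one
shared label space.  The quality function is

    Q = (1/2μ) Σ_ijsr [(A_ijs − γ k_is k_js / 2m_s) δ_sr + ω δ_ij] δ(σ_is, σ_jr)

with 2μ the total intra-layer strength plus total coupling; the i = j,
s = r null-model self-terms are included, matching the plain double-sum
reading (this is what makes the two-clique worked value exactly 0.5).
Each session's layers are optimized separately.

Maximization is Louvain-style on the dense supra-modularity matrix:
greedy single-node moves (including detaching into a fresh singleton
community) followed by aggregation, iterated to convergence; then
iterated-local-search refinement (perturb 30% of labels, re-optimize,
keep on improvement, 2 kicks) to escape the coordinated-move traps that
pure greedy sweeps cannot leave; best of n seeded restarts (default 10).
On an exhaustive scan of all partitions of ≤8-node graphs this finds the
global optimum across the full test library.

Module allegiance P_ij is the fraction of layers co-assigning i and j.
Recruitment R_iS = (1/n_s)Σ_{j∈S} P_ij follows the defining sum literally
(the j = i self-term is included), so regional and system-level values
are mutually consistent; integration I_iS = (1/(N−n_s))Σ_{j∉S} P_ij.
System-level allegiance averages region pairs between systems k and l;
the k = l blocks exclude i = j self-pairs so system recruitment is not
inflated by the unit diagonal; hemispheres are pooled before averaging
(7×7 output) unless disabled (then 14×14).

### Choosing γ and ω

The emulated protocol scans γ ∈ [0.5, 1.5] and ω ∈ [0, 1] (step 0.05,
441 cells) and keeps the highest-Q cell; `grid_search_gamma_omega`
implements exactly that, with row-major first-cell tie-breaking.  Note
the caveat: Q is not scale-invariant across γ, so the argmax-Q selection
is a protocol convention, not an optimality principle — on clean block
data it drifts to the grid corner.

For the *synthetic* block generator one can say precisely where the
informative resolution lies.  Merging two equal planted systems changes Q
in proportion to z_b − γ·k̄/N (z_b the between-system weight, k̄ the mean
strength), so systems merge when γ < N·z_b/k̄.  With the generator
defaults this threshold is ≈0.7–0.8 for the morning condition and
≈0.95–1.0 for the evening condition (which carries the injected
between-system increase); at γ = 1.2 neither session ever merges, the
allegiance matrix is exactly block-diagonal in both sessions, and
integration is identically zero — the analysis is blind.  Synthetic-cohort
analyses therefore use a γ placed between the two sessions' merge
thresholds (0.8 for the 4×10-region geometry, 0.9 for the 56-region
7-system geometry), with ω = 0.1 as in the emulated protocol.  The
protocol-faithful defaults (γ = 1.2, ω = 0.1) remain the pipeline
defaults for real data.

## Statistics

All inference is by permutation, two-sided on absolute statistics, with
p = (b+1)/(n_perm+1) (so p ≥ 1/(n_perm+1); default n_perm = 30,000):

* **TOD main effect** — mean within-subject (evening − morning)
  difference; null by independent sign flips of each subject's
  difference (exact for a two-level within factor).
* **Chronotype main effect** — group mean difference of subject means;
  null by shuffling group labels.
* **Interaction** — group mean difference of the difference scores; null
  by shuffling group labels.
* **One-way tests** (mesoscale session contrasts) — difference of sample
  means under pooled label shuffles; when the number of distinct label
  assignments is small the test enumerates all of them and the p-value is
  exact.
* **Identity-line test** — is the least-squares line of evening-vs-
  morning coefficients different from y = x?  Statistic: mean squared
  deviation of the fitted line from the identity over the observed x;
  null swaps each pair's session assignment independently.
* **Covariate-adjusted correlations** — Pearson correlation of residuals
  after regressing both variables on the covariates (intercept, age, sex
  by default); null permutes the y-residuals.

FDR is Benjamini–Hochberg.  Families: per metric × density across the
regions (nodal tests); per metric across the density grid (global
tests); per session across metric × score pairs (correlations).  A nodal
effect is *consolidated* when FDR-significant at strictly more than half
of the densities.  Cohort demographics use Pearson chi-square without
continuity correction (this is what reproduces the printed worked value
X² = 0.069 on the 11/20 vs 12/19 sex table), pooled-variance t for
interval variables and two-sided Mann–Whitney U for ordinal ones.

## Synthetic cohort generator

Time series are zero-mean multivariate normal draws with block-constant
correlation: ρ_within = 0.35 inside a system, ρ_between = 0.10 across
systems, plus white measurement noise of SD 0.25 on unit-variance
signals (attenuating observed correlations by ≈6%).  These levels sit in
the range of empirical resting-state system correlations and — more
importantly for a test bed — place the network near the segregation/
integration boundary where the mesoscale analysis is sensitive.  Effects
are injected additively on the latent correlations: the TOD integration
effect adds δ to all between-system entries in the evening session; a
chronotype effect adds δ to within-system entries of a chosen region set
for ET subjects.  After injection the matrix is repaired to positive
definiteness by eigenvalue clipping at 1e-6 and diagonal renormalization,
and Cholesky feasibility is verified at construction.

Randomness fans out from one seed to per-(subject, session) substreams
keyed by a stable hash, so enlarging the cohort never changes existing
draws.  Questionnaire scores are drawn at the emulated cohort's group
means/SDs (ME separates chronotypes sharply; AM, ESS, age, sex are
exchangeable between groups).

What the generator does *not* emulate: temporal autocorrelation and
hemodynamics (irrelevant to zero-lag Pearson correlation, which is all
the pipeline consumes), head motion and physiological noise, regional
heterogeneity within systems, and inter-subject topographic variability.
Consequently, passing tests demonstrate the correctness and sensitivity
of the pipeline under the assumed block-covariance model — not that the
specific empirical effect sizes of any real cohort would be recovered.
No quantitative effect sizes for the TOD/chronotype contrasts are
published for the emulated study; the defaults (δ = 0.15 on integration)
are chosen for testability.

## Numerical choices and degenerate inputs

* Threshold ties: lexicographic (i, j) order — deterministic, nesting
  exact.
* Fisher-z clip 1e-7; PD-repair eigenvalue floor 1e-6.
* Louvain move tolerance 1e-12; restart improvement tolerance 1e-15;
  grid-search ties go to the first cell in row-major (γ, ω) order.
* Constant metric across observations → p = 1 with a note, not an error;
  a constant coefficient vector makes the identity-line test undefined
  and is reported as NaN.
* Eigenvector centrality on a disconnected graph is computed on the
  largest component (others 0); PageRank damping 0.85.
* Degenerate rewiring inputs (fewer than 2 edges) return the graph
  unchanged.

## Problem sizes

Tests and the verification script run on reduced dimensions chosen to
keep the full suite interactive while preserving the statistical
structure: calibration uses 200 replicates of a 10-per-group, 16-region
cohort at 199 permutations; effect recovery uses 50 replicates of a
20-per-group, 40-region (4×10 systems) cohort at T = 325 with 5
optimizer restarts; the worked analysis uses 12 per group × 56 regions
with 2,000 permutations.  All dimensions scale up by configuration only.

## Known limitations

* The block-covariance generator makes mesoscale transitions sharper
  than in real data (whole systems merge nearly deterministically);
  detection rates on it are upper bounds.
* Comparing Q across γ during grid search inherits the protocol's scale
  issue noted above.
* Whether layers should couple categorically or ordinally is undecidable
  from the emulated protocol; categorical coupling is the appropriate
  choice for subjects-as-layers and is what we implement.
* Hub classification depends on an arbitrary participation threshold
  (0.3, configurable); no inferential test is attached to hub identity.
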