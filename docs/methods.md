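# Methods

## Network construction

Each subject's T × N ROI time-series matrix is reduced to an N × N Pearson
correlation matrix (T ≥ 3 required; a constant ROI column is an error naming
the region). The diagonal is stored as 1 but never treated as a candidate
edge.

Thresholding is by **sparsity**: at level S the strongest
K = round(S · N(N−1)/2) node pairs become edges of an undirected, unweighted
graph, so all subjects have identical node and edge counts at every level
and group differences reflect relative organization rather than overall
correlation strength. Conventions:

* **Edge ranking** uses |r| by default: strongly negative correlations count
  as connections. This is a genuine modelling choice — the alternative
  (`edge_ranking: positive`, ranking by signed r) is a config switch. With
  the default 0.05–0.18 grid on 90 nodes only the top 5–18 % of pairs enter,
  so in practice the two modes coincide unless anticorrelations are strong.
* **Rounding** of K is half-away-from-zero (e.g. S = 0.10 on 90 nodes gives
  K = 401 from 400.5), not banker's rounding; ties in |r| break by
  lexicographic node-pair order. Both choices make thresholding
  bit-reproducible, and they make the edge sets *nested* along the grid.
* **Regime search** (`determine_regime`) returns the maximal contiguous run
  of levels on which every subject satisfies (1) mean degree > 2·log(N) and
  (2) σ > 1.1. The log is natural by default (2·ln 90 ≈ 9.00); the base is
  configurable because the literature is inconsistent, and with base e the
  mean-degree rule only admits S ≥ 0.11 on 90 nodes (S·89 ≤ 9 below that).
  The shipped default grid stays 0.05–0.18 with 0.01 steps regardless;
  ties between equally long runs resolve to the lowest-S run.

## Topological metrics

All metrics use standard unweighted-graph definitions on the binary
networks (nodal clustering = realized fraction of neighbour pairs, 0 when
degree < 2; network Cp = mean over nodes; Lp = mean shortest-path length
over reachable ordered pairs; efficiencies = mean inverse distances with
1/∞ = 0; local efficiency of a node = global efficiency of its
neighbour-induced subgraph; betweenness = unnormalized Brandes counts over
unordered pairs, with a normalization flag for cross-N comparisons; degree
centrality = plain degree).

**Disconnected pairs.** Lp and NLp exclude unreachable pairs from their
means rather than imputing a penalty distance; exclusion counts are
reported per subject in the component report, and an isolated node's NLp is
a missing value that downstream group statistics drop. The
efficiency-based metrics handle disconnection natively (1/∞ = 0), which is
why both families are computed.

Distances come from level-synchronous BFS. Two equivalent implementations
exist — numba-compiled kernels (used when numba imports) and a pure-numpy
boolean-matmul fallback — verified identical on random graphs; the test
suite additionally checks every metric against independent brute-force
oracles (triangle enumeration, Floyd–Warshall, exhaustive shortest-path
enumeration) on the complete atlas of graphs up to 7 nodes, sampled 8-node
graphs, and 200 random 12-node graphs.

## Null models and small-worldness

Reference ensembles are degree-preserving randomizations: starting from the
observed edge list, `swaps_per_edge × |E|` double-edge swaps are attempted,
rejecting any swap that would create a self-loop or duplicate edge
(Maslov–Sneppen). Defaults are **100 nulls** and **10 swaps per edge** —
field-standard values, recorded in output metadata and adjustable; swap
counts trade mixing quality against runtime. Swap-rigid graphs (complete
graphs, stars) are returned unchanged with a warning. Connectedness is not
enforced in the nulls.

γ = Cp/⟨Cp_rand⟩ and λ = Lp/⟨Lp_rand⟩ use ensemble **means**; null Lp uses
the same reachable-pairs convention as the observed networks. σ = γ/λ
exactly. A network too sparse for normalization (mean null Cp = 0) is an
error rather than a silent zero.

Sampling noise matters when validating these quantities: a single graph's
Cp fluctuates with its triangle count (relative SD ≈ 15 % for
Erdős–Rényi N = 90, p = 0.1), so calibration tests compare *seed-averaged*
γ and σ against 1, and the self-normalization check (nulls fed back through
their own ensemble) averages 20 draws and uses a 3-standard-error band for
that mean.

## AUC integration

Each metric's curve over the sparsity grid is collapsed to its area by the
composite trapezoidal rule (a left-rectangle variant exists as
`quadrature: rectangle` for sensitivity analysis; the choice is recorded in
output metadata). Panels adjacent to a missing grid point are skipped and
counted; a curve with fewer than two usable points yields a missing AUC.
The quadrature is linear and invariant under grid refinement of
piecewise-linear curves to 1e−12, and these properties are tested.

## Modular connectivity

The shipped parcellation (`data/aal90_modules.tsv`) assigns the 90 AAL
regions to six anatomical modules — frontal (12), prefrontal (24),
parietal (14), temporal (18), occipital (14), subcortical (8). The module
memberships are a documented reconstruction from AAL region nomenclature,
not a published lookup table; the file is editable, every result is defined
relative to the loaded mapping, and the mapping's content hash is recorded.

"Connection strength" is implemented as **edge density** — intra-module:
edges within the module / |m|(|m|−1)/2; inter-module: crossing edges /
|m₁||m₂| — so modules of different sizes are comparable; raw counts are
also emitted for audit, and the intra+inter edge counts sum exactly to |E|.
With six modules this yields 21 measures per subject per threshold, each
integrated to an AUC like any other metric.

## Group statistics

* **Categorical demographics**: Pearson χ² without continuity correction
  (zero margins rejected).
* **Routing**: Shapiro–Wilk per group at α = 0.05; a variable is treated as
  normal only if *every* group passes. Normal → one-way ANOVA with
  pooled-variance pairwise t-tests (a Welch switch exists); non-normal →
  Kruskal–Wallis with Mann–Whitney U pairwise.
* **AUC metrics**: ANCOVA — the linear model
  `metric ~ group + age + sex + avg_ht + ht_8k` with sex as a 0/1 indicator
  and no interactions; the omnibus F comes from model reduction (full vs.
  group-dropped fit). When the normality gate fails, the same model runs on
  rank-transformed responses; the choice of rank ANCOVA as the
  "nonparametric test with covariates" is this package's own
  operationalization, as no canonical procedure exists. Covariate columns
  with zero variance in a cohort are dropped with a logged warning;
  genuinely collinear covariates are an error naming the redundant column.
* **Post hoc**: LSD — pairwise t-contrasts on adjusted group means using
  the full model's residual variance, uncorrected (that is the definition);
  reported in the order PT–ROT, PT–HC, ROT–HC.
* **Multiplicity**: nodal pairwise p-values are Bonferroni-multiplied by
  the node family size (90); module tables carry LSD pairwise values plus a
  Bonferroni column over the 21 measures for the omnibus. Family sizes are
  recorded in each table.
* **Correlations**: Spearman rho with average ranks, Benjamini–Hochberg
  adjustment across all tested pairs; constant variables are flagged and
  excluded from the FDR family. BH preserves p-value ordering and never
  shrinks a p-value; it is *not* idempotent on arbitrary adjusted vectors
  (only on flat ones), and the tests reflect that.

The ANCOVA/LSD battery's type-I error is verified by simulation: under a
null with covariate effects but no group effect (n = 25/group), both the
omnibus and the pooled pairwise rejection rates fall within [0.03, 0.07]
at α = 0.05 over 2,000 replicates.

## Synthetic cohorts

The generator emulates the *structure* of a parcellated resting-state
study, not its physiology: zero-mean multivariate Gaussian time series
whose population correlation is `r_within · effect_map[group]` inside a
module and `r_between` across modules (unit diagonal; positive
semidefiniteness checked at construction and violations rejected with the
smallest eigenvalue). Gaussianity is a deliberate simplification — the
pipeline consumes only Pearson correlations, which this model controls
exactly. An optional moving-average smoother emulates band-limited noise
but is off by default; correlation targets are defined pre-smoothing.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| `n_per_group` | 25 | typical clinical-cohort arm size |
| `n_rois`, `t_len` | 90, 240 | 90-region atlas; 250 volumes minus 10 discarded |
| modules | AAL six-module table | matches the analysis parcellation |
| `r_within`, `r_between` | 0.30, 0.10 | moderate modular FC; the empirical FC distribution of any real cohort is unknown, so these are calibration knobs, not estimates |
| `effect_map` | ROT: 0.5 | planted segregation deficit: halves ROT within-module correlation |
| covariates | tinnitus groups ≈ +6–13 dB HL | mirrors the direction of typical cohorts without copying specific values |
| durations | ROT < 6 months ≤ PT | the defining group boundary |

Each subject draws from an RNG substream keyed by `(seed, subject index)`,
so cohorts are bit-reproducible and enlarging a group never reshuffles
existing subjects.

What passing tests show — and don't: recovering the planted effect
demonstrates that the pipeline's thresholding, metrics, integration and
statistics are correctly wired and adequately powered for a
correlation-scale effect of this size at n = 25/group. It does not certify
sensitivity on real fMRI, where hemodynamics, motion residuals,
physiological noise and non-Gaussian tails are all absent from this
generator. Likewise, at the planted effect size ROT networks fragment at
the lowest sparsity levels (the component report shows it), which is
handled — not hidden — by the reachable-pairs conventions above.

## Problem sizes in the shipped checks

The test suite and acceptance script choose sizes that keep a full run at
desk scale: oracle sweeps use the exhaustive ≤7-node atlas plus 100
eight-node and 200 twelve-node random graphs; small-world calibration uses
20 seeds × 30 nulls; the type-I simulation uses 2,000 replicates; the
planted-effect power check runs the pipeline on 100 cohorts of 75 subjects
(aCp/aEloc need no null ensembles, so those stages are disabled there);
the acceptance script's full-pipeline run uses 20 nulls per network and
estimates power over 20 replicates. All are configuration, not convention:
the defaults inside the package remain 100 nulls and the full stage set.

## Known limitations

* Binary, undirected networks only; no weighted or directed metric
  variants, no Fisher z-transform, no rich-club/assortativity/hub analysis.
* No data-driven community detection; the module layer is a fixed
  anatomical partition.
* The null ensemble matches degree sequence but not connectedness.
* The exact six-module membership of the 90 AAL regions is a reconstruction
  (see above); swap in your own TSV if you have the authoritative mapping.
* Synthetic cohorts have no hemodynamic model, scanner artefacts, motion,
  or preprocessing residuals.
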