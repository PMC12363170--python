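# Methods

This note documents the models, algorithms, numerical choices and known
limitations behind `guildnet`. The package analyses microbial communities
around kidney failure and transplantation from an ecological-network
perspective: instead of asking which taxa change in abundance, it asks how
the web of co-occurrence relationships — its guilds (modules) and its
topology — changes, and how those network features track kidney function.

## The compositional problem and SparCC

Shotgun metagenomic profiling yields relative abundances: each sample's
taxon vector is closed to a constant sum. Closure induces spurious negative
correlation between taxa (if one fraction rises, others must fall), so
Pearson or Spearman correlation on fractions is not a valid estimate of
ecological association. SparCC works from the variance of pairwise
log-ratios,

    t_ij = Var_s[ log(x_is / x_js) ],

which is invariant to the closure. Writing w_i for the variance of taxon
i's latent ("basis") log-abundance and rho_ij for the basis correlation,

    t_ij = w_i + w_j − 2 rho_ij sqrt(w_i w_j).

Under the sparsity assumption that most basis correlations are near zero,
row sums of t satisfy the linear system

    sum_j t_ij ≈ (D − 2) w_i + sum_j w_j,

which is solved for w; correlations follow by inverting the first display
and clamping to [−1, 1].

**Exclusion iterations.** Strongly correlated pairs are exactly the ones
that violate the sparsity assumption, so after the initial solve the
strongest pair with |rho| above a threshold (default 0.1) is removed from
the row sums and the system re-solved. This package iterates that exclusion
*until no eligible pair exceeds the threshold* (with a hard cap of one
round per pair). A small fixed round budget is not sufficient when planted
or real module structure makes correlated pairs a non-trivial minority: in
simulations with four modules of 7–8 taxa among 30 (≈23% of pairs truly
correlated at rho = 0.8), a 10-round budget leaves basis variances biased
low, drags uncorrelated pairs to ≈ −0.24, and inflates the rho RMSE to
0.19; exclusion to convergence brings the RMSE to 0.026.

**Degeneracy handling.** The linear system can become singular along the
exclusion path (two equal blocks with every within-block pair excluded
leave only the total variance identified); the solver uses min-norm least
squares (`rcond=1e-8`), which resolves unidentified directions
symmetrically. A component excluded from D−3 pairs no longer constrains the
system and is dropped entirely, its equation pinned to its last estimate.
Basis variances that come out non-positive are floored at 1e−10 with a
warning, and any component whose variance collapses more than three orders
of magnitude below the median is treated as carrying no pairwise signal:
its correlations are reported as 0 rather than as clamp artefacts at ±1
(a tiny denominator otherwise forces |rho| = 1 regardless of the data).

**Count input.** For count tables the estimate is averaged over 20 (default)
Dirichlet-posterior resamples of the per-sample fractions (counts + 1), the
standard treatment of sampling noise at finite depth. Relative input takes
a single deterministic pass with a pseudocount of 1e−6 added before logs.

**Significance.** Two-sided pseudo-p-values come from a permutation
bootstrap (default 100 replicates): every taxon's values are permuted
independently across samples, destroying association while preserving
marginals, and the full estimate is recomputed. p = (1 + #{|rho_b| ≥
|rho_obs|})/(1 + B), so p is never 0. Benjamini–Hochberg adjustment runs
over the family of all unordered pairs. Note the FDR resolution this
implies: with B replicates the smallest attainable q on m pairs of which k
are true discoveries is roughly m/(k(B+1)); B must be sized to the network
(100 suffices for the 30-taxon simulations here, but small edge sets on
large pair families need more).

**Edge rule.** The default keeps pairs with |rho| > 0.7 and q < 0.05,
carrying the sign as an edge attribute; a strict signed mode (rho > 0.7
only) is exposed as an option because the wording of unsigned "R > 0.7"
thresholds is ambiguous in the field.

## Networks, guilds, and per-sample topology

The co-occurrence graph is simple and undirected over all taxa that passed
the prevalence screen (occurrence in strictly more than 70% of samples and
mean relative abundance strictly above 0.001%), keeping isolated nodes.
The screen is cohort-wide by default — the standard convention when one
network is built per body site — with a within-group mode (keep a feature
passing the cuts in at least one group) available for designs where taxa
appear only at certain timepoints. "Occurrence" means strictly positive
value, and both cuts are strict inequalities. Filtered tables are kept as
sub-compositions (columns sum to at most 1) rather than renormalised:
renormalising would change the mean-abundance screen on repeated
application, and the log-ratio statistics downstream are closure-invariant
anyway.

**Module detection** is greedy agglomerative modularity maximisation
(CNM-style): start from singletons, repeatedly merge the connected pair of
communities with the largest modularity gain, and return the best-Q
partition along the merge sequence. Ties in the gain are broken by the
lexicographically smallest pair of community representatives, making the
result invariant to node input order — a property the test suite asserts.
Q is Newman–Girvan modularity on the unweighted graph (edge signs and
weights ignored; signed-modularity variants are out of scope). Modules
holding strictly more than 10% of the nodes are labelled M1, M2, ... by
descending size.

**Per-sample topology.** Each sample induces the subgraph of taxa with
strictly positive abundance in it. Reported scalars: modularity (by
default, modules re-detected on the subnetwork; an alternative mode scores
the global partition restricted to the present nodes),
mean degree 2E/N, linkage density (mean degree)/N, and the mean over
present nodes of eigenvector centrality. Centrality is computed by power
iteration on A + I over the largest connected component (the +I shift
rules out bipartite oscillation without changing the leading eigenvector),
max-normalised so values lie in [0, 1]; nodes outside the largest component
get 0. Subnetworks with fewer than 2 nodes or no edges report zeros with a
`degenerate` flag so downstream tables stay rectangular. "Mean" (rather
than total or maximum) for degree and centrality is a definitional choice;
both are simple summaries a per-sample scalar requires.

**Module abundance and function.** A labelled module's abundance in a
sample is the sum of its members' relative abundances (unlabelled network
taxa pool into "other"). KO functional features are linked to modules by
Spearman correlation after a mean-abundance screen (> 0.001%), keeping
pairs with |rho| > 0.5 and p < 0.05.

## Diversity and trends

Shannon entropy uses natural logarithm over strictly positive fractions.
Bray–Curtis dissimilarity d(u,v) = 1 − 2 Σ min(u_i, v_i)/(Σu + Σv) is
computed with scipy; a pair of all-zero samples is defined to have distance
0 with a warning. PERMANOVA partitions the squared-distance sum into
between- and within-group components (Gower identity), with an
unrestricted-label-permutation p-value; the two-factor variant uses
sequential (type-I-like) hat-matrix projections of the Gower-centred
matrix, so factor R² values are order-dependent and the fitted order is
stated in the output. Within-group dispersion comparisons use only
within-group pairwise distances, compared across groups by Kruskal–Wallis.

The abundance screen tests the top-50 features by mean abundance with
Kruskal–Wallis per feature and retains p < 0.05 unadjusted by default
(mirroring common practice for this screen); a BH-adjusted mode is
available. Time trends over ordered cohort groups are fitted by least
squares as a quadratic in integer group rank (first group = 0). Quadratic
in rank is the minimal family expressing both the U-shaped ("first
decreasing then increasing") and inverse-U trajectories of interest; rank
rather than calendar-day encoding prevents the half-year timepoint from
dominating the fit's leverage. The sign of the quadratic coefficient
classifies the shape (tolerance 1e−12 relative for "flat"), and the vertex
location is reported with an in-range flag. An asymptotic-exponential
alternative, y = a + b·exp(c·r) fitted by nonlinear least squares, is
available behind a model flag for trajectories that saturate rather than
turn around; there the sign of b classifies the curvature.

## Clinical associations

**eGFR** uses the CKD-EPI creatinine equation, 2021 race-free refit by
default: eGFR = 142 · min(Scr/κ,1)^α · max(Scr/κ,1)^−1.200 · 0.9938^age
(· 1.012 if female), κ = 0.7/0.9 and α = −0.241/−0.302 for female/male;
the 2009 coefficients (race term omitted) are available. Creatinine must
carry an explicit unit — μmol/L is converted by ÷ 88.42, and unit-less
input is refused rather than guessed, because clinical tables in the wild
mislabel creatinine units. The implementation is continuous at the κ knot
and monotone decreasing in creatinine (both asserted numerically).

**Association screen.** Spearman correlations of per-sample network
features and module abundances against clinical indicators, with
pairwise-complete handling of missing values, tie-corrected ranks,
two-sided p-values and significance stars at 0.05/0.01/0.001. Pairs with
fewer than 5 complete observations or a constant margin report NaN.

**Random forest for eGFR.** The forest is a bagged ensemble of
feature-subsampling decision trees (equivalent to a random forest; the
bagging wrapper exposes each tree's bootstrap indices, which the
out-of-bag machinery needs). The per-split candidate-feature count is
grid-tuned by 10-fold cross-validation minimising RMSE, then the winner is
refit on all data. Importance is %IncMSE-style: the mean increase in a
tree's out-of-bag MSE when one feature's OOB values are shuffled (the
shuffle preserves the feature's marginal distribution by construction).
Per-feature and model-level significance come from response-permutation
nulls: the response is permuted, the forest refit, and importances and
OOB R² recomputed, B times (default 100); p-values use the add-one rule.
Defaults are 500 trees; simulations in the test suite use 40–100 trees and
24 permutation replicates, which is sufficient for rank recovery and
level-α calibration at n = 100.

## The synthetic cohort generator

The generator produces exactly the data model under which SparCC's
estimand is well defined: per sample, latent log-abundances are drawn from
a multivariate normal whose correlation matrix has equicorrelated planted
blocks (the guilds; default within-block r = 0.8, between-block 0),
exponentiated, closed to a composition, and observed as multinomial counts
at fixed depth (default 1e5, a typical per-sample species-table total).
Structural zeros are then applied as independent Bernoulli masking
(default rate 0.1, a conventional sparsity level — real tables' sparsity
is platform- and pipeline-dependent). Cohort simulation adds ordered
groups (HC, R00–R05 style) with per-attribute quadratic trends over group
rank plus Gaussian noise; clinical indicators are linear combinations of
named module abundances plus noise; KO tables couple a chosen fraction of
functions to module abundances through noisy monotone (log-linear) maps.
Every generator takes one explicit integer seed and is bit-for-bit
reproducible; planted structure (block memberships, coefficients, KO
links) is recorded in a `SyntheticTruth` object for recovery scoring.

**What the generator does not emulate**: real taxon names or phylogeny,
overdispersion beyond the log-normal/multinomial hierarchy,
batch/compositional artefacts of specific profilers, antibiotic-resistance
gene content, and — importantly — the dependence structure of real
structural zeros. Recovery results on this generator show the estimator
chain is correct under its own model; they do not certify performance on
real tables.

**Recovery conditions.** Planted-structure recovery (rho RMSE ≤ 0.12,
module ARI ≥ 0.9) is evaluated at n = 500 samples, 30 taxa in four blocks,
within-block r = 0.8, depth 1e5, and **no structural zeros**. Structural
zeros break the log-normal composition model — a masked count carries a
pseudocount into the log-ratio statistic — and at masking rate 0.1 the
planted correlation is no longer SparCC's estimand (measured rho RMSE
rises to ≈ 0.35). This is a model-mismatch property of zero inflation, not
an implementation artefact, and is the reason the recovery conditions
exclude it while the generator's default keeps it for realism.

## Numerical and testing conventions

- All stochastic tests fix seeds; ensemble assertions use medians or hit
  rates over 10–100 seeds rather than single draws.
- Oracles are independent of the code paths they check: per-pair
  variance loops for the t matrix, O(n²) double sums for modularity, dense
  `eigh` for eigenvector centrality, normal equations for trend fits,
  rank-then-Pearson for Spearman, scikit-bio for the PERMANOVA pseudo-F.
- Simulation sizes in the test-suite and the acceptance script (10–20
  seeds per ensemble, n ≤ 500, ≤ 100 bootstrap replicates) were chosen as
  the smallest ensembles at which the asserted medians and rates are
  stable.
- Under planted independence at n = 200, the maximum |rho| over 435 pairs
  concentrates around 3.2/√200 ≈ 0.22 — the expected extreme of null
  estimates with sd ≈ 1/√n — and no consistent estimator can push the
  order statistic below that at this n. Edge-level calibration (no pair
  passes the |rho| > 0.7 & q < 0.05 rule under the null) is the meaningful
  check and holds exactly.

## Known limitations

- SparCC's basis variances are weakly identified when correlated pairs are
  not a sparse minority (e.g. two equal blocks covering most taxa);
  estimates there are conservative (shrunk), and module recovery relies on
  the surviving within-block edges.
- The bootstrap recomputes the full estimate per replicate, so runtime
  scales as B × resamples; the FDR floor set by B is documented above.
- Per-sample modularity re-detects communities on each subnetwork; with
  very few present taxa, Q is noisy and the degenerate flag should be
  respected downstream.
- Sequential two-factor PERMANOVA gives order-dependent R²; there is no
  marginal (type-III) variant.
- The random-forest significance machinery refits the forest per
  permutation replicate and is the most expensive stage at its defaults.
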