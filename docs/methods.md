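# Methods

This note documents the models, conventions, defaults, and known limits of
`netcog`. Everything quantitative stated here is computed by the test suite
or by `scripts/acceptance.py`; nothing is asserted that the code does not
measure.

## Mutual-friendship networks

A wave's network contains every subject who submitted that wave's roster
survey. An edge {a, b} exists iff a rated b "friend" **and** b rated a
"friend". Two survey dialects are normalised at parse time: the binary
friend / not-friend dialect of the first two waves, and the later
four-category dialect (friend / acquaintance / recognize / do-not-know), in
which every non-friend category maps to "not-friend". Duplicate ordered
ratings and self-ratings are validation errors, not silent merges.

Degree-zero subjects stay in the graph (they are part of the roster
universe) but are flagged: the per-wave centrality table gives them a friend
count of 0 and a missing influence value, so summary statistics describe
only members of the mutual-friendship network.

## Influence (eigenvector centrality)

Influence is the leading eigenvector of the binary adjacency matrix,
computed by power iteration on `A + I` — the unit shift leaves eigenvectors
unchanged while making the dominant eigenvalue strictly largest in
magnitude, so the iteration also converges on bipartite components. The
start vector is uniform, the convergence tolerance 1e-13 (L2 change per
step), and the result is clipped to non-negative values and rescaled so the
maximum entry is exactly 1. The procedure is deterministic: the same graph
always yields the same values.

On disconnected graphs the leading eigenvector concentrates on the
spectrally dominant component; nodes elsewhere decay toward zero and end up
with small positive values (or exact zeros), which matches the convention of
reporting near-zero influence for peripheral members rather than dropping
them. No teleportation / damping term is added.

The implementation is validated against an independent dense
`numpy.linalg.eigh` oracle; across 50 random graphs of up to 200 nodes the
maximum absolute discrepancy is ~1e-12 (asserted < 1e-8).

## Stability measures

Jaccard edge stability is `|E_s ∩ E_t| / |E_s ∪ E_t|` over raw edge sets —
deliberately *not* restricted to subjects present at both waves, since the
denominator is meant to count every unique friendship observed at either
time. Spearman rank stability of a centrality metric, by contrast, is
computed over the intersection of subjects (a rank correlation needs paired
observations) with average ranks for ties, and requires at least three
common subjects.

## Consensus communities

Four detections are run per wave via python-igraph:

| algorithm | igraph routine | settings |
|---|---|---|
| map equation | `community_infomap` | 10 restarts, best objective |
| edge betweenness | `community_edge_betweenness` | divisive cut at max modularity |
| modularity optimisation | `community_multilevel` | default resolution |
| random walks | `community_walktrap` | walk length 4 |

The stochastic routines are seeded (igraph draws from Python's `random`,
which is re-seeded before every call), so detection is reproducible.
Modularity optimisation uses the multilevel (Louvain) routine by default;
greedy agglomeration is available via `ConsensusConfig.modularity_method`
but is not the default because it reliably strands individual nodes even on
strongly separated planted partitions.

"Consensus" is the meet of the four partitions: a cell is a maximal node set
whose members received identical labels under *all four* algorithms — the
only reading under which "all algorithms assigned at least *m* subjects to
the same community" is well-defined without cross-algorithm label alignment.
Cells with ≥ `min_size` members (default 5) become consensus communities;
everything else, including degree-zero nodes (which every algorithm leaves
as singletons), is *unassigned*. Meso ties are shared consensus membership;
a pair with any unassigned member — including two unassigned nodes — has no
meso tie, since membership in "no community" is not shared membership.

### Recovery convention

Planted-block recovery is scored as the adjusted Rand index between
consensus communities and planted blocks **over assigned nodes**. An
unassigned node is an abstention, not an error: inspection of non-recovered
draws shows the stranded node's realised edges genuinely favour (or tie
with) a foreign block, so no algorithm could recover its planted label from
the graph — exactly the ambiguity the consensus construction is designed to
abstain on. A draw still counts as a failure when the four algorithms
*agree* on an assignment that contradicts the planted labels (≈1–2% of
strongly separated draws, again reflecting genuinely ambiguous realised
edges). At p_in = 0.4, p_out = 0.02, four 25-node blocks, exact recovery
occurs on ~98/100 seeds.

## Knowledge-task design

Stimulus samples hold 30 alters per subject (therefore C(30,2) = 435 pairs
and 870 directed trials). Quotas by unweighted shortest-path distance from
the subject are (5, 10, 15) for distances 1, 2, 3 — distant members are
deliberately oversampled. Shortfalls backfill from the nearest richer
stratum: distance-2 leftovers first, then distance-3, then remaining
distance-1 nodes, with unreachable / beyond-3 nodes last; realised counts
per stratum are recorded on the sample.

Base-rate matching is two-pass with independent seed streams: a first pass
averages the true-friendship count of random quota-respecting samples across
all subjects (the *global target*); the sampler then draws `n_iter`
candidates per subject and keeps the one whose true-friendship count is
closest to the target, breaking ties by draw order so the sampler is a pure
function of (network, subject, quotas, n_iter, seed). Candidates in which
some member has no friend among the other members are rejected when any
satisfying candidate exists; otherwise the best unrestricted candidate is
returned with `friend_constraint_met=False` — the constraint is "whenever
possible" by construction. `n_iter` defaults to 1000 for production use;
the simulation studies use 25–100 (the candidate stream is cheap but the
studies draw hundreds of cohorts; matching quality changes little beyond a
few dozen candidates).

Responses on the four-point likelihood scale are binned to binary guesses
(likely / very likely → 1); the binary dialect passes through.

## Subject-level knowledge model

Per subject and wave: maximum-likelihood logistic regression of the binary
guess on veridical friendship and veridical shared-community indicators,
both looked up in the *immediately preceding* survey's network and
consensus communities. Both directed judgments of every unordered pair enter
as separate Bernoulli rows: the task genuinely collects two responses per
pair, and the per-subject GLM treats trials as exchangeable. (Whether to
deduplicate is a real design fork; the dual-row choice retains all data and
is the natural reading of a per-subject trial-level GLM. Aggregation-
sensitivity can be probed by passing deduplicated rows to the same fitting
function.)

Internally the trials are aggregated into the four (friendship, community)
cells and fit as a binomial GLM — the MLE and Wald standard errors are
identical to the Bernoulli-row fit and the fit is an order of magnitude
faster, which matters for the Monte-Carlo studies. Degenerate subjects
(constant predictor, separation, SEs above 50 on the logit scale, optimizer
failure) are flagged `converged=False` and excluded with reason
`nonconvergence` rather than raising.

Monte-Carlo check (200 replicates, agent weights (−2.0, 1.5, 1.0), 870
trials on a sampler-produced design): mean recovery error below 0.05 on
both coefficients (asserted ≤ 0.1) and 95% Wald coverage within ±3 points.
The estimator's median error also shrinks monotonically over 100 → 870 →
5000 trials.

### Exclusions

Applied per wave, over converged fits: a subject is excluded when β₁ or β₂
lies more than 3 group-SDs from the group mean (`beta_outlier`), or when
either SE lies more than 3 SDs from the mean SE (`se_outlier`). The rule is
per-coefficient (pooling across coefficients would mix scales), uses
population SDs, excludes nobody when an SD is zero, and is idempotent
because the reference pool (converged fits) is unchanged by flagging.

## Group-level models

Ordinary least squares with classical standard errors and t-based 95% CIs;
no multiple-testing correction. Knowledge coefficients enter unstandardised
(they are in logit units; the group models' coefficients are therefore in
outcome-units per logit). Model families: change models (outcome = late
minus early centrality; M2 adds early friend count and extroversion as
controls), contemporaneous models per wave, and interaction models for late
influence (parsimonious: fall-meso, spring-micro, and their product; full:
both waves' main effects plus all four early×late products). Preconditions:
≥ 10 subjects and a full-rank design (a rank-deficient design raises an
error naming the degenerate columns). Marginal predictions fix non-focal
columns at sample means and take the ribbon from the coefficient
covariance; for interaction models this means the product column is also
held at its mean, so the curve shows the focal main effect at average
levels of everything else.

Calibration: with nothing planted, each term of the controlled change model
rejects at 5% ± 2 points over 500 simulated cohorts of n = 100 (verified
exactly nominal at 2000 cohorts during development).

## Synthetic cohort

Defaults (all configurable in `SyntheticConfig`):

| parameter | default | rationale |
|---|---|---|
| subjects / waves | 190 / 6 | cohort and survey cadence of the study design |
| planted blocks | 6 | ~32-member communities, comfortably above `min_size` |
| p_in / p_out | 0.25 / 0.01 | mean degree ≈ 8.7, matching observed fall mean 8.6 |
| churn drop rates | 0.4, 0.3, 0.1, 0.05, 0.05 | heavy fall turnover, spring stability |
| β₀ | N(−2.0, 0.5) | low base guess rate absent structure knowledge |
| β₁ (micro) | N(1.5, 0.75) | strong but heterogeneous reliance on real friendships |
| β₂ (meso) | N(1.0, 1.0) | wide spread in community reliance, the trait under study |
| extroversion | N(3.5, 0.8) | Big-Five-like 1–5 scale, independent of weights |

Wave 1 is a planted-partition draw. Each transition drops edges at the
wave's churn rate *d* and adds non-edges at the block-dependent stationary
rate `d·p/(1−p)`, which keeps expected within/between densities constant,
so declining drop rates translate directly into rising Jaccard similarity
(observed in 100/100 default draws). Block memberships are fixed across
waves by default (they are the recovery target); a membership-switch rate
exists but is off.

Agent responses are Bernoulli draws from the agent's own logistic weights
applied to the realised friendship and planted-block indicators of each
trial. The full chain — generate → sample → simulate → fit → exclude —
recovers the generating weights with Spearman ρ ≈ 0.9 (micro) / 0.95 (meso)
across 100 agents.

`plant_influence_link` regenerates the final transition with edge formation
tilted by `exp(γ·(β₂_u·s_v + β₂_v·s_u))`, where *s* is the partner's degree
percentile — high-meso agents preferentially attach to well-connected
nodes. Weights are normalised to mean 1 over candidate non-edges, so the
expected edge count is unchanged and γ = 0 reproduces the unbiased
transition draw exactly (same RNG stream, identical edges). At γ = 5 the
rank correlation between true meso weight and influence gain is positive in
≥ 19/20 seeds; at γ = 0 it is centred on zero.

## Power study design

The planted-effect study measures what the headline group-level contrast
requires: cohorts of n = 100 subjects whose knowledge coefficients are
*estimated* from simulated task runs (so estimation noise and exclusions are
in the loop), an influence-change outcome generated as
`Δinfluence = 0.1·β₂_true + ε`, ε ~ N(0, 0.23²) — slope from the planted-
effect design point, noise SD at the observed scale of influence change —
and no micro effect. Over 200 cohorts the controlled change model detects
the meso term (positive, p < 0.05) with power ≈ 0.93 (asserted ≥ 0.8) while
the micro term rejects at ≈ 6% (asserted ≤ 10%; slightly above nominal
because measurement error in β̂₂ leaks a little signal onto the correlated
β̂₁). The outcome is planted directly rather than through the γ-attachment
generator because the study fixes a known effect size; the generator's
induced effect size depends on the whole network trajectory and is the
subject of its own tests, not a calibrated quantity.

## Problem sizes and determinism

The simulation studies run at fixed sizes chosen to give stable Monte-Carlo
estimates: 200 replicates (recovery), 200 cohorts (power), 500 cohorts
(type-I), 100 seeds (consensus recovery, stability dynamics), 50 graphs
(eigen oracle). All randomness flows from explicit seeds through
`numpy.random.SeedSequence.spawn`, so adjacent master seeds index disjoint
cohort sets and every study is exactly reproducible; igraph's RNG is
re-seeded per detection call.

## What the synthetic cohort does not emulate

Planted-block communities are cleaner than real social communities (the
generated networks typically have *no* unassigned subjects, versus 26–35%
in real data); degree heterogeneity within blocks is binomial, with no
hubs beyond what the block model produces; agents' response weights are
constant across trials (no fatigue, distance-dependent uncertainty, or
block-order effects); extroversion is independent of everything by
construction. Passing tests therefore certify the *machinery* — estimator
consistency, calibration, recovery under known conditions — not the
empirical claims one would make from real data. Known limitations: the
knowledge estimator treats the two directed judgments per pair as
independent; consensus recovery is scored over assigned nodes (see above);
and the eigenvector-centrality convention (max = 1, no damping) makes
cross-wave influence comparisons sensitive to which component dominates in
sparse early waves.
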