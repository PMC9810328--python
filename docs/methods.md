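# Methods

This note records the models implemented in `oncoclade`, the assumptions
behind them, the defaults that matter, and the design decisions taken
where more than one reasonable choice existed.

## Time trees

Trees are rooted with branch lengths in millions of years (My). Node ages
are derived, not stored: the root age is the longest root-to-tip path and
every node's age is root age minus its depth, so a tip short of the
longest path is an extinct (fossil) lineage with positive `tip_age`.
Newick parsing and writing go through dendropy; grafting and pruning are
implemented on the package's own light container because clade
replacement with age reconciliation is not a stock operation.

Numerical choices:

- Zero-length input branches are replaced by ε = 1e−6 My with a warning.
  Zero branches make the Brownian covariance singular and break every GLS
  step downstream; ε is far below the resolution of any published
  divergence time.
- Supertree grafting keeps the host's stem branch and rescales all
  replacement branch lengths proportionally when the replacement's root
  age differs from the replaced crown's age by more than 1e−3 My
  (rescaling can be disabled, in which case the mismatch is an error).
  Independently calibrated source trees rarely agree exactly on a crown
  age and no principled reconciliation exists without re-dating;
  proportional rescaling preserves relative branching times within the
  replacement.
- Pruning always retains the root, so root-to-tip path lengths — and
  therefore tip ages — are preserved; internal single-child nodes are
  suppressed by summing branch lengths.
- Tip labels are exact-match keys; naming variants between source trees
  are handled by an explicit two-column synonym table, never by fuzzy
  matching.

## Continuous-trait ancestral reconstruction

Body mass is reconstructed on the natural-log scale (log₂ appears only in
reporting). Two models:

**Brownian motion (closed form).** The root state is the GLS estimate
under the unit-rate Brownian tip covariance *C* (shared root-to-MRCA path
lengths); the rate σ² is its maximum-likelihood estimate
rᵀC⁻¹r/n; internal states are the conditional Gaussian means given the
tips, which coincide with the joint-ML assignment. Interval widths use
the conditional variance plus the root-state uncertainty term. With
constant tips the model degenerates cleanly (σ² = 0, all intervals have
zero width).

**Heavy-tailed increments (MCMC).** Per-branch increments follow a
symmetric α-stable density with tail index α ∈ (0, 2]; branch scale is
(σ²/2)^½·t^(1/α) with σ² anchored to the Brownian ML fit, so α = 2
reduces *exactly* to Gaussian increments targeting the Brownian
conditional — this is what the test suite exploits as an oracle. States
at internal nodes are sampled by Metropolis-within-Gibbs (random-walk
proposals scaled by the shortest adjacent branch), initialised at the
Brownian estimates. The stable density is evaluated numerically
(scipy); a Student-t surrogate with ν = α matches the x^−(α+1) tail decay
and is available as a faster option, flagged in the output metadata. This
implements the *model class* — heavy tails that let a large jump be
absorbed on a single branch instead of dragging the neighbouring
ancestors — rather than replicating any particular published sampler.

Defaults: chain 4000 sweeps, burn-in 1000, thinning 1. A split-chain
R-hat above 1.1 on any node is recorded in the metadata and warned about,
never silent. Every stochastic operation requires an explicit seed that
is carried in the output. Point estimates are posterior medians with
central 95% credible intervals; batch-means Monte-Carlo standard errors
of the posterior means are reported for convergence-aware comparisons.

## Intrinsic cancer risk

Lifespan is predicted from mass by PGLS: ln t = β₁ + β₂ ln D with the
error covariance proportional to the Brownian tree covariance. This is
the standard reading of a Brownian "correlation structure" regression —
an intercept plus a log-mass covariate with phylogenetically correlated
errors. Residual variance uses n − 2 degrees of freedom.

Intrinsic risk is the simplified multistage proxy K = D·t⁶ (D in grams,
t in years). K itself is meaningless in absolute terms; only log-ratios
between nodes are interpreted, which also makes every fold change
invariant to the mass unit (a g→kg change shifts all log K equally — a
property test). The per-branch fold change is log₂(K₂/K₁) with K₂ the
*ancestor*, following the source definition literally: a risk decrease
toward the present is positive. Because that reads backwards to many
users, a `child_over_ancestor` flip is available and the convention used
is recorded on the output. Ancestral D uses the exponentiated ASR point
estimate; intervals propagate by applying the (monotone) risk formula to
the ASR interval endpoints. log₂K is computed in log space so large
mammal masses cannot overflow.

Lifespan observations exist only for extant species; fossil tips enter
the mass reconstruction but their lifespans (and risks) are model
predictions, not data.

## Reciprocal best hits and ECNC

Inputs are standard 21-column PSL alignment tables (0-based, half-open),
parsed and validated strictly (block arithmetic must be consistent with
the stated query/target ends; malformed lines are reported with line
numbers). No ranking score is part of the PSL convention, so "best" is
defined here as matches + repMatches − misMatches − qNumInsert −
tNumInsert, with ties broken by (score, query coverage length,
lexicographic target name) for determinism.

A *locus* — one putative gene copy — is formed by merging an isoform's
hits on the same target sequence whose target spans overlap or fall
within 10 kb (configurable). Without merging, exon-level hits would each
count as a copy. A locus is retained iff its best reciprocal hit maps
back (via the isoform→gene table) to the originating gene; loci missing
from the reciprocal table are dropped and counted in a diagnostics
report.

Copy number is then estimated by coverage over query positions n = 1..l:

    ECNC = Σₙ Cₙ / Σₙ bool(Cₙ)

with Cₙ the number of retained loci covering position n (each locus
counts once per position — the union of its blocks). Two fragments of a
split copy tile the query and contribute ECNC ≈ 1 where the raw hit
count says 2; this is the statistic's purpose. Query coordinates are
treated as protein residues throughout; the synthetic generator emits
coordinates in the same convention. ECNC is undefined (flagged, excluded
downstream) when no position is covered; whenever defined it lies in
[1, n_hits], and it equals brute-force per-position counting exactly
(property-tested on 1000 random hit sets).

Gene-level values aggregate isoforms by max (longest-signal rule; mean
available). The duplicate call is binary: state 1 iff n_loci ≥ 2 **and**
ECNC ≥ 1.5. The source analysis states only that copy number was coded
0/1; these two thresholds are this package's explicit defaults, chosen so
that a fragmented single copy (n_loci 2, ECNC ≈ 1) stays 0, and they are
serialised with every output. Query-set exclusion filters (uncharacterised
ORFs, LOC, HLA, replication-dependent histones, odorant receptors,
ribosomal proteins, zinc-finger factors, viral/repeat proteins,
Uncharacterized/Putative/Fragment names) are explicit regex lists stored
in the config, applied with set semantics and per-category removal
counts.

## Binary copy-number ASR and event calling

Characters are gene × species 0/1 states; species without a usable
genome for a gene are missing data and are integrated over both states —
never coded 0. The model is the two-state reversible chain (gain q01,
loss q10; any two-state chain satisfies detailed balance against its
stationary frequencies). Likelihoods use Felsenstein pruning with
analytic 2×2 transition matrices, vectorised across all genes with
per-node rescaling, so fitting 2000 genes on a 50-tip tree takes well
under a second. Frequency handling is configurable because "empirical
frequencies" is ambiguous for this model family: `empirical` pins the
stationary frequencies at the observed state proportions and optimises a
single overall rate; `optimized` optimises both rates freely (bounded
below at 1e−8). The model is fitted jointly across genes by default (a
per-gene option exists); the joint fit is what makes genome-scale
matrices tractable and mirrors single-model ASR practice.

Marginal ancestral states come from the standard up-down pass with the
stationary frequencies as root prior (empirical-Bayes: the fitted rates
are plugged in). Branch-specific event calls require a root, so the tree
is used as rooted even where an unrooted tree would suffice for the
likelihood. A duplication is placed on branch parent→child iff the
parent favours state 0 and the child state 1, each with BPP ≥ 0.80;
transitions whose child is confident but whose parent is not are tallied
as unreliable rather than called. Only the rootmost qualifying branch
per root-to-tip path is kept, so a gene yields at most one event per
lineage. Raising the BPP threshold can only remove events
(monotonicity, property-tested). Per-branch summaries report counts,
per-gene rates (count / genes analysed), and the gene lists consumed by
the enrichment stage.

Known limitation, by construction: a gain on a branch whose parent is
the root (or whose root-ward path is long) cannot be placed confidently,
because a single loss on the sister side explains the tip pattern about
as well — the synthetic burst planting deliberately avoids such
branches, and real analyses need an outgroup for the same reason.

## Pathway over-representation

One upper-tail hypergeometric test per gene set: P(X ≥ k) for k
foreground members of a set of size m within a background of N genes and
a foreground of s, computed via scipy's stable survival function.
The background is the post-filter query gene set; every collection is
intersected with the background before testing and sets smaller than 5
members after intersection are dropped (configurable). The enrichment
ratio is k/(s·m/N). Benjamini–Hochberg adjustment (statsmodels) with
significance flagged at q ≤ 0.25 — a deliberately permissive screening
threshold for pathway discovery. Results are invariant to input
ordering, and cancer-relevance annotation is a user-supplied label, not
computed. Specific published enrichment statistics depend on the exact
pathway-database release and gene universe and are therefore
database-dependent outputs, not package invariants.

## Prevalence

Clopper–Pearson exact intervals from Beta quantiles: lower =
Beta(α/2; x, n−x+1) (0 when x = 0), upper = Beta(1−α/2; x+1, n−x)
(1 when x = n); for x = 0 the upper bound reduces to 1 − (α/2)^(1/n).
The Beta formulation is the primary path; root-finding on the binomial
tail sums is kept as the independent test oracle (agreement to 1e−9),
and the exact interval's conservative coverage is verified by
simulation. Pooling sums x and n within user-defined groups,
order-independently, retaining source provenance. Display strings round
to 3 significant digits; full precision is retained in the numeric
columns. The bundled published count table carries the originally
printed intervals for cross-checking; three published cells are
internally inconsistent with their own counts by more than one unit in
the last printed digit (two point prevalences and one upper bound, see
`oncoclade.datasets.TABLE_ANOMALIES`) — they are flagged and never
reproduced by changing the method.

## Effect sizes

Unpaired mean difference (test − control) with a BCa bootstrap 95% CI
(percentile available) and a two-sided permutation test, both via
scipy's resampling framework with a mandatory seed. The permutation
statistic is Welch's t because clade-versus-rest group sizes are very
unbalanced; reshuffles are enumerated exhaustively whenever the number
of distinct label assignments is within the resample budget (5000 by
default) and sampled otherwise — the two-versus-two worked case is
exact: p = 1/3. Jointly degenerate groups (no variance, equal means)
return p = 1 with a zero-width interval, flagged. Doubling time is the
interpolated time from the first upward crossing of 20% confluence to
the first crossing of 40%; plate readings are normalised as fold change
over the mean no-drug (0 µM) control response, which cancels instrument
units. Which species count as the "rest" group in a clade contrast is a
configuration choice (`test_clade`), since published clade comparisons
can either exclude all related clades or only the focal one.

## Synthetic data: what it emulates, and what it does not

Every generator is a pure function of its parameter block and a seed.
Defaults describe the study system rather than convenient numbers:

- **Trees**: birth–death (0.15/0.05 per My) conditioned on 50 extant
  tips, keeping 25% of extinct lineages as fossil tips — mammal-like
  timescales with the fossil sampling the mass reconstruction needs.
- **Traits**: ln-mass Brownian rate 0.02 /My around a 1 kg root with
  compound-Poisson jumps (rate 0.01 /My, SD 1.5 ln-units). Jumps stand
  in for heavy-tailed increments *so that exact ground-truth ancestral
  values exist* — a test-harness choice, not a model claim. Lifespans
  follow the classic maximum-lifespan allometry t ≈ 4.9·D^0.15 (years,
  grams) with a small phylogenetic noise walk (0.002 /My).
- **Duplications**: background gain 3e−4 /My, loss 1e−4 /My, and two
  burst branches at 0.02 /My — the burst-on-a-stem-lineage structure —
  planted by default on long-stemmed mid-sized clades away from the
  root (see the ASR limitation above). Root states start at 0
  (single-copy), with a stationary-root option for matched-conditions
  rate-recovery checks.
- **PSL tables**: one locus per true copy, fragmentation probability
  0.15 splitting a locus across two scaffolds, 2% mismatch rate,
  optional reciprocal-error and off-target noise. Coordinates and
  formats match the reader exactly; no sequences exist — block
  coordinates and scores are synthesised, which is the point: the
  statistic under test is coverage arithmetic, not alignment quality.
- **Gene sets**: 100 pathways of 10–80 members over the gene universe,
  one planted set drawn from the dominant burst's gained genes with a
  10× overrepresented foreground.
- **Prevalence / phenotypes**: binomial counts at survey-sized n
  (275, 140, 60, 48, 25) and lognormal doubling times with clade
  offsets — mammals ≈ 32 h median, anteaters ≈ 40 h, sloths ≈ 100 h,
  matching the magnitudes reported for cultured fibroblasts.

What passing the synthetic suite shows: the estimators recover what was
planted under their own model assumptions at realistic sizes. What it
cannot show: robustness to real genome-assembly artefacts beyond simple
fragmentation, alignment-quality effects, taxon-sampling bias in
life-history tables, or the content of any particular pathway database.
Published per-lineage duplicate counts and enriched-pathway counts
depend on specific genome assemblies, a reference proteome, and a
pathway-database release; they are external-data targets, represented
here by the planted-recovery checks instead.

## Problem sizes used in the checks

The recovery checks run at 50 extant tips and 2000 genes (10 seeded
replicates for burst identification), 100-tip trees × 50 replicates for
the Brownian rate, 1000 random hit sets for the ECNC oracle, 500 random
≤ 6-taxon trees for the pruning/enumeration oracle, and 1000 null
replicates for permutation-test calibration — sizes at which the
asymptotics under test are already visible while the whole suite stays
interactive.
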