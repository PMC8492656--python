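# Methods

`chimeraopt` implements a desk-scale design-test-learn loop for chimeric
enzyme engineering by structure-guided recombination. This note documents
the models, the default parameters and why they were chosen, what the
synthetic landscape does and does not emulate, and the numerical choices
made where the design was genuinely open. No empirical claim here goes
beyond what the test suite and `scripts/acceptance.py` themselves compute.

## Sequence space

A library is defined by aligned parents, a domain split separating the
non-recombined N-terminal (AHR) domain from the recombined C-terminal (ATR)
domain, and breakpoints partitioning the ATR region into contiguous blocks.
Alignment coordinates are 0-based and half-open throughout; block indices
are reported 1-based in user-facing tables ("block 6" is the sixth block).

Chimeras are block strings (`A-ATBBAAAB`). Two chimeras whose donated
blocks happen to carry identical sequences are the same protein;
`enumerate_space` collapses them onto the lexicographically smallest block
string, so a 3-parent, 8-block library with one block conserved between two
parents holds 2·3⁷ = 4374 distinct proteins rather than 3⁸ = 6561. The AHR
domain is carried as a single label, fixed to the first parent by default
(the fixed-AHR fusion library design); the types permit any parent.

Encodings are one-hot. The *hamming* scheme indicates the amino-acid
option at each variable alignment column; the *structure* scheme indicates
the residue-pair combination at each contacting column pair. Columns
conserved across all parents contribute only a constant to a linear kernel
and are dropped by default (`keep_conserved=True` restores them for exact
dimension bookkeeping). Residue-level encoding is the default; a coarse
block-level one-hot (`scheme="block"`) is available.

Gap handling in `translate`: a chimera inherits its donor's gap characters
and they are removed from the final protein string, which is the sequence
the construct would actually have; `keep_gaps=True` preserves alignment
coordinates for structure-indexed statistics.

## Contact maps and SCHEMA disruption

Contact maps come from an ensemble of structural models: residues are in
contact when any pair of heavy atoms lies within 4.5 Å (hydrogens are
ignored — models typically lack them and their inclusion would change the
cutoff semantics; altlocs resolve to the first conformer). Each contact is
weighted by the fraction of models containing it. Sequence-adjacent pairs
(|i−j| < 2) are excluded by default: they are never broken by recombination
and carry no design signal.

The SCHEMA energy of a chimera is E = Σ w_ij·1[residue pair (s_i, s_j)
co-occurs in no single parent], and the mutation level m is the Hamming
distance to the closest parent over aligned columns. Note that in a
fixed-AHR library the "parental" chimeras are AHR-fusions: a contact
spanning the domain boundary can be broken even by an all-one-parent ATR,
so E = 0 is guaranteed only for true full parents.

## RASPP breakpoint search

RASPP trades the library-average disruption ⟨E⟩ against the average
mutation level ⟨m⟩. Library averages for the search are taken over all
block-label assignments with multiplicity (what a combinatorial assembly
physically produces); `library_averages(distinct=True)` instead averages
over the deduplicated space. Under the label-space convention ⟨E⟩
decomposes per contact, so a dynamic program can find, for each
minimum-block-length constraint, the breakpoint placement that maximizes
the contact mass retained within blocks (equivalently minimizes ⟨E⟩).
Sweeping the minimum block length from its configured floor to the
feasibility limit generates candidates; each is scored exactly, binned
along ⟨m⟩ with integer-width bins, reduced to the lowest-⟨E⟩ candidate per
bin, and filtered to the nondominated set. Ties break to the
lexicographically smallest breakpoint tuple for determinism. Assembly
constraints (e.g. Golden-Gate-compatible columns) enter as the caller's
`allowed_columns`. On small alignments the DP is verified against
exhaustive partition search in the test suite.

## Seed design

The initial batch maximizes the Gaussian mutual information between the
chosen set S and the full landscape L under the linear-kernel GP prior;
since S ⊆ L this is the Gaussian entropy H(S) = ½ log det(2πe·K_SS), a
submodular function, optimized greedily. The entropy gain of a candidate
equals ½ log(2πe·v) with v its predictive variance given S, so each greedy
step is a maximum-posterior-variance pick, computed with an incrementally
updated Cholesky factor.

Numerical choices: a jitter of 1e-8 times the mean kernel diagonal is added
before factorization (duplicate encodings make K singular); ties in gain
break to the smallest block string; σ² defaults to 1 for seeding (the
argmax at fixed subset size is invariant to it); the initial set defaults
to the parental chimeras, and `n_select` counts new additions beyond it
(`count_includes_initial=True` gives the other reading). The entropy trace
is nondecreasing only while candidates remain linearly independent of the
chosen set; past the encoding rank every conditional variance hits the
jitter floor and differential entropy must fall — the greedy loop simply
stops being informative there, which the seed sizes used here stay well
below.

## Sequence-function models

**Regression** is a Gaussian process with the homogeneous linear kernel
k(x, x′) = σ²·x·x′ over the one-hot encodings. Posterior mean and variance
use the standard Cholesky route: factor K + σ_n²I once, solve per query.
This GP is exactly Bayesian linear regression with weight prior N(0, σ²I),
which bounds capacity on small data and makes the posterior mean a dot
product with a cached weight vector — scoring all 4374 candidates is a
single matrix product. Targets are mean-centered before fitting and the
mean restored at prediction (`center_y=False` disables this); σ_n² defaults
to 1.0 mg²/L² on roughly titer-scale targets and is configurable. When
σ_n² = 0 a relative jitter keeps the factorization positive definite.

**Hyperparameter selection** scans σ² over 23 log-spaced values from 1e-6
to 1e5 (half-decade steps) by leave-one-out cross-validation, computing the
Pearson r and MSE of the LOO predictions per grid point. When the r-argmax
and MSE-argmin disagree, the chosen σ² minimizes the summed ranks of (−r,
MSE) — a deterministic balance rule. Constant targets make r undefined; the
scan then warns and selects by MSE alone. LOO is implemented by n refits
for clarity; a closed-form fast path (exact for a fixed zero prior mean,
hence `center_y=False`) is available and is required by the tests to agree
with the refit route to 1e-8.

**Classification** is Gaussian naive Bayes over the same encodings
(scikit-learn's `GaussianNB` behind the `ActivityClassifier` surface), with
a sequence labeled active when its titer exceeds a threshold of 1 mg/L by
default — the smallest titer distinguishable from blank-level noise in the
simulator; the threshold is configurable. Variances are floored at 1e-9
times the largest feature variance. Single-class training data yields a
constant predictor with a warning instead of an error, which matters in
early rounds when almost everything is inactive.

**Block contributions**: for each block b and parent label p, the mean
model-predicted titer change when substituting label p at block b instead
of the reference parent's label, averaged over a background (the full space
when enumerable, else a fixed-seed subsample of 1000). The reference column
is zero by construction, and labels donating identical block sequences get
identical effects because their encodings coincide.

## Batch UCB optimization

Candidates are scored by UCB = posterior mean + β·sd with β = 1. Batches
are assembled by hallucination: the UCB optimum joins the training set with
its posterior mean as a pseudo-observation at the same σ_n² as real data
(keeping the refit identical in kind), the model is refit, and the next
optimum is taken until the batch (default 10) is full. Hallucinations never
persist into the campaign's measurement table. The candidate pool excludes
tested chimeras, predicted-inactives (when the classifier has seen at least
2 active and 1 inactive example), and optionally chimeras more than a given
number of block exchanges from every parent. The campaign default caps the
block distance at 4 in rounds 1–3 and lifts the cap from round 4 on,
biasing early sampling toward functional sequences; both the cap value and
schedule are configuration. If the filters empty the pool the campaign
retries that round without the classifier rather than aborting.

The round model is refit each round on all accumulated real measurements
(aggregated per chimera), with σ² rechosen by LOO. Fitting on all data —
including inactive zeros — rather than on actives only was chosen because
the zeros carry most of the early information about where the landscape is
dead; `gp_on_active_only=True` gives the alternative. All randomness flows
from a single campaign seed through documented sub-seeding, so a campaign
is bit-reproducible. A `combined_ucb` objective summing per-strain UCB
scores supports multi-strain rounds.

## The synthetic landscape

The simulator stands in for the wet-lab assay so the closed loop is
testable. A chimera's noiseless titer is base + block effects + pairwise
epistasis (+ optionally a term proportional to its net interface charge),
clipped at zero, and zeroed when an inactivation rule fires. Defaults were
chosen once to mirror the statistical structure of in vivo chimera titer
data at study scale, and are not tuned thereafter:

- base 10 mg/L; per-block effects uniform on ±15 mg/L, with first-block
  effects adjusted so the three parental fusions hit 11, 25 and 8 mg/L —
  a strong, a weak and an intermediate parent of realistic magnitude;
- 10 random pairwise epistasis terms on ±8 mg/L (about half a block
  effect: present but not dominant);
- inactivation logistic in the SCHEMA energy E, midpoint at the 30th
  percentile of the library's E distribution and scale std(E)/10, decided
  once per chimera by a deterministic seed-derived draw — roughly 70% of
  the space inactive while the parents (E = 0) stay active, matching the
  flavor of seed rounds where most distant chimeras are dead. Hard-E-
  threshold and block-distance rules are available alternatives;
- replicate noise sd = 2 mg/L + 20% of the true titer (a ~54 mg/L producer
  measures at ±~13), negative draws clipped at zero;
- chain-length split C16:C14:C12 = 0.70:0.25:0.05, the long-chain-dominant
  product profile expected when the precursor pool feeds membrane lipid
  synthesis.

What it does *not* emulate: strain-to-strain substrate-pool differences
(strains are independent oracles), expression-level variation, batch and
day effects, non-Gaussian outliers, and any mechanistic relationship
between sequence and kcat. Passing the closed-loop test therefore shows
the *algorithmic* loop recovers optima of a block-additive, majority-
inactive landscape under realistic noise at the study's measurement budget
— not that any specific wet-lab titer would be reproduced.

The synthetic contact map places one pseudo-atom per column on a compact
random walk (3.8 Å steps reflected into a sphere) and builds an ensemble of
noise-perturbed copies, giving local-plus-long-range contacts with
fractional weights; it is labeled synthetic and is not a homology model.

## GC quantitation and aggregation

Even-chain analyte concentrations follow the bracketing-internal-standard
rule C_i = A_i · avg(C_{i−1}, C_{i+1}) / avg(A_{i−1}, A_{i+1}) for
i = 2, 4, …, 16; a species with a missing bracket or nonpositive standard
area is reported as a per-species error while the rest are computed.
Replicate aggregation reports the mean, the sample standard deviation
(n−1 denominator, 0 when n = 1), n, and the active flag per
(chimera, strain).

## Interface charge

Interface residues are enzyme positions with any heavy atom within 10 Å of
any atom of the docked partner chain (all-atom rather than Cα-only — the
conservative reading). Net interface charge counts K/R as +1 and D/E as −1;
histidine is neutral by default (`count_histidine=True` makes it +1, since
its protonation state at cytosolic pH is genuinely ambiguous). The
charge-titer statistic is the Pearson correlation between per-chimera net
interface charge and mean total titer, reported as undefined (with a
warning) when either side has zero variance.

## Problem sizes

Default test and acceptance runs use the full 4374-chimera space, 20-seed +
10×10-proposal campaigns over 10 random seeds, 96-point model-recovery
fits, 25 random GP-oracle toys, and ≤30-column alignments for exhaustive
RASPP and subset-selection oracles. These sizes keep every exhaustive
oracle exact and the whole suite comfortably reproducible on one CPU.

## Known limitations

- The RASPP search sweeps minimum block length as its only candidate
  generator; exotic frontiers reachable only under other constraint
  families require passing explicit `allowed_columns`.
- The fast LOO path requires `center_y=False`; with centering on, use the
  (default) refit route.
- The linear-kernel GP cannot interpolate more points than its encoding
  rank; on tiny toy spaces the entropy trace and interpolation checks must
  respect that rank (the 4374-space encodings have rank well above all
  batch sizes used).
- Structure-scheme encodings give all-zero features for residue pairs
  created by recombination but absent from every parent; two chimeras
  differing only in such novel pairs can collide under that scheme (the
  hamming scheme, the default, is injective on the distinct space).
- The deposited-data statistics check needs the external dataset placed at
  `data/protabank_nu9KXbjT4.csv`; it is not bundled.
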