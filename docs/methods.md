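# Methods

## Likelihood engine

All sequence likelihoods use Felsenstein pruning over time-reversible
models: an exchangeability matrix (the equal-exchangeability "Poisson"
model by default) combined with equilibrium frequencies, normalised to one
expected substitution per site.  Among-site rate variation uses the usual
discrete gamma with k equal-probability categories (k = 4 unless stated),
the category rate being the conditional mean of its bin.  Gap (`-`) and
missing (`?`) cells are fully ambiguous; per-site rescaling keeps deep
trees from underflowing.  Transition matrices come from the symmetrised
eigendecomposition, cached per model, so repeated evaluations (branch
optimisation, gamma-shape fitting) are cheap.

The gamma shape is fitted by bounded Brent search on [0.02, 100]
(tolerance 1e-4).  Rate-homogeneous data therefore report shapes at the
top of that range rather than a divergence.

Branch lengths are optimised by coordinate ascent, one bounded Brent
search per branch on cached inside/outside conditional vectors, with exact
recomputation between branches; the sweep loop stops when a full sweep
improves the log-likelihood by less than the tolerance.  Log-likelihood is
invariant to rerooting for these reversible models, which the test suite
asserts.

## Data treatments

*Recoding.*  SR4 pools the amino acids into `AGNPST`, `CHWY`, `DEKQR`,
`FILMV`, written as A/C/G/T so recoded data flow through any four-state
machinery.  Ambiguity codes and the non-canonical U/O become `?`; gaps are
preserved.  Custom schemes load from a residue→bin TSV.

*Fast-site removal.*  Sites are ranked by posterior-mean rate computed on
the amino-acid alignment with a user-supplied guide tree (no hidden tree
search), split into ten deciles (category 1 = fastest; ties broken by
column index so the ranking is deterministic), and removed stepwise:
`floor(f·L)` columns for each fraction f.  Masks are nested by
construction.  The combined treatment removes sites first and recodes the
survivors — rates are never estimated on recoded data.

*Composition diagnostics.*  Per-taxon frequencies exclude gaps/missing.
The heterogeneity statistic is `X²_t = N_t Σ_s (f_ts − f̄_s)²/f̄_s`
against the unweighted across-taxon mean f̄ (users wanting length-weighted
means can substitute their own reference vector).  Distances are Euclidean
or square-root Jensen–Shannon (a metric); the UPGMA ordering uses a
smallest-index tie-break so heatmap layouts are reproducible.  No p-values
are attached to X²: the chi-square distributional assumptions do not hold
for alignment columns.

## Constrained placement and treatment grids

A full tree search is out of scope; instead a fixed backbone is taken as
given and the query clade — held monophyletic with its internal topology
fixed from a LogDet/neighbour-joining subtree — is attached to each
candidate edge in turn.  Following standard evolutionary-placement
practice, only the three branch lengths the attachment creates (the two
halves of the split edge and the query stem) are re-optimised per
candidate (coordinate ascent, tolerance 1e-4, at most 50 sweeps); backbone
lengths are ML-fitted once per treatment.  Candidates are ranked by
log-likelihood; bootstrap support for a candidate is the fraction of
within-partition column resamples it wins outright, with replicates whose
top two candidates sit within 1e-6 log-units counting for neither.

Placements in the treatment grid are scored, by default, under a
deliberately simple rate-homogeneous stationary model.  This is a design
choice, not an omission: site-heterogeneous mixture models are outside
this package's scope, and the grid's purpose is to show how data-side
treatments (recoding, fast-site removal, taxon deletion) rescue inference
that a simple model gets wrong at saturated or compositionally biased
sites.  A fitted gamma shape can be enabled
(`TreatmentGridSpec.placement_alpha`), but it absorbs much of the
saturation artefact and with it the treatment effect being studied.

LogDet/paralinear distances (0.5 pseudocount on empty joint-count cells,
pairs with no shared columns flagged missing) and deterministic
neighbour joining provide the composition-robust backbone estimates; both
use explicit lowest-index tie-breaks so permuting the input order cannot
change the result.

## Undated DTL reconciliation

A gene lineage on species branch e draws one event: speciation-or-leaf
arrival (probability 1/Z), duplication (δ/Z), transfer (τ/Z) or loss
(λ/Z), with Z = 1+δ+τ+λ.  Transfer recipients are uniform over the other
branches (no time consistency — the undated model).  At a leaf the copy is
observed with probability 1−m, m being one minus the genome's estimated
completeness, so assembly incompleteness is part of the observation model.
Extinction probabilities solve
`E_e = P_L + P_S·(E_f E_g | m_e) + P_D E_e² + P_T E_e Ē` by fixed-point
iteration (tolerance 1e-10).

The family likelihood is a dynamic program over gene-tree clades ×
species branches; with a tree sample, clades carry conditional split
frequencies (CCP amalgamation), a single tree being the degenerate case.
Because speciation-loss and transfer terms couple all branches, each
clade's probability vector solves one small linear system
`(I − M)x = b` rather than an inner fixed point — exact and fast.
Origination is uniform over branches; likelihoods are conditioned on the
family being observed (divide by 1 − mean E; an unconditioned flag is kept
for extinction validation).  Unrooted gene trees average over all
rootings.  Tree-less families of size 2–3 are resolved as deterministic
caterpillars over sorted copy labels; families above a configurable cap
(default 2,000 members) are skipped with a warning.  Rates are fitted by
Nelder–Mead in log-rate space (pooled across families by default).

*Reconciliation sampling and the extinction correction.*  Reconciliations
are drawn by backtracking the DP in proportion to each term's
contribution; per-branch copies count lineages completing a branch.
Whenever the sampler invokes an extinction probability (a
speciation-loss, duplication-loss or transfer-loss term), the expected
copies and events of that unsampled sub-lineage are added from "ghost"
expectation matrices solved with the same linear operator.  This places
corrective mass exactly where the observed gene tree is blind — on
branches the lost lineage would have occupied — instead of rescaling the
visible copies.  In the validation benchmark this correction is unbiased
in aggregate (summed corrected copies match summed true copies to within
half a percent, where uncorrected copies sit ~11% low), and it is exact in
forced cases: for a root-spanning family under pure incompleteness, an
unobserved leaf receives a corrected copy number of exactly 1.  Its
limitation is equally clear: it is an expected-value correction, so for a
single family whose observation happens to be complete it adds small
spurious mass; per-family absolute error is therefore usually larger than
for the uncorrected numbers even though group-level quantities (proteome
sizes, summed event counts — everything the downstream statistics use) are
much better.  Sampled discrete event labels record lineage extinctions as
`L`; the expected per-branch loss *counts* instead come from the ghost
expectations and so count only genuine loss events.

Presence calls: copy number > 0.3 present, 0.1–0.3 maybe-present,
< 0.1 absent.  Events with sampled frequency below 0.3 are dropped by the
event filter.  Singleton families are scored as originations at their leaf
without running the DP.

## Ancestor statistics

Proteome size at a node is the number of families whose corrected copy
number clears the presence threshold (the sum of corrected copies is also
reported, since "size" is ambiguous between the two).  Duplication, loss
and origination expectations are summed over families and divided by
proteome size.  Groups of ancestors are compared with a two-sided
one-sample Wilcoxon signed-rank test against the reference group's median:
exact via dynamic programming over the signed-rank null (midranks for tied
magnitudes) for n ≤ 25, continuity-corrected normal approximation with tie
correction beyond; exact ties with the reference are dropped and at least
three informative values are required.  No multiple-testing correction is
applied, so the individual p-values remain directly interpretable;
significance stars are ≤0.05 / ≤0.01 / ≤0.001.  A two-sample
Mann–Whitney alternative sits behind a flag.

## Synthetic data: what it emulates, and what not

The family simulator draws from the *same* discrete event process the DP
integrates over, so simulator and likelihood are exact counterparts — a
deliberate choice of testability over realism.  The alignment simulator
draws per-site rates from a discrete gamma (8 classes by default) and
evolves states branchwise; lineages under a composition override use a
rate matrix rebuilt around the overridden equilibrium with the
exchangeabilities kept.  Conditioned family simulation redraws extinct
histories, mirroring the likelihood's conditioning; an unconditioned mode
feeds the extinction validation.

*The compositional-attraction benchmark* (`artifact_scenario`) is a fixed
20-taxon tree: the query pair (Euk1/2, stem 1.6 substitutions/site) is
truly sister to a short-branch ingroup pair (Hod1/2, insertion branch
0.08), while a distant outgroup pair (Kor1/2, stem 1.6) shares the query's
composition override.  The override concentrates 90% of each SR4 bin's
mass on one residue, so bin-level composition stays neutral: the
convergent signal is strong in amino-acid space and vanishes on recoding —
the designed mechanism.  Site rates follow a gamma with shape 0.5 over
1,000 columns.  These settings were chosen so the benchmark expresses its
defining property decisively (untreated placements land on the convergent
edge with triple-digit log-likelihood margins; recoding + 30% fast-site
removal recovers the true sister).

*The clade genome-dynamics experiment* gives one of two 12-leaf sister
clades 3× the duplication rate and 0.5× the loss rate (base rates δ=0.05,
τ=0.01, λ=0.25; leaf missing fractions 0.05) and asks whether the group
report stars both shifts.  Families (150 per replicate) originate at the
root branch — core families, because ancestral genome content is carried
by anciently originated families; uniform origination yields leaf-local
families and ancestor proteomes of a dozen families, in which even the
*true* per-node rates are dominated by noise.  Two clades of 12 give 11
ancestors per group, enough signed-rank power that a few inconsistent
nodes do not mask a real shift.  Pooled rates are fitted on a 60-family
subsample; each family is reconciled with 100 samples.

What the synthetic data do **not** emulate: indels and alignment
uncertainty, site-heterogeneous substitution processes (profile mixtures),
gene-tree estimation error (gene trees are either true or user-supplied),
time-consistent transfers, and any attempt to mimic the empirical
parameters of real archaeal datasets.  Passing these tests shows the
machinery is correct and the treatment logic behaves as designed under the
stated generative models — not that any particular empirical placement is
right.

## Numerical choices and degenerate inputs

Branch lengths are bounded to [1e-8, 20] substitutions/site during
optimisation; alpha to [0.02, 100].  Decile and removal ties break by
column index; NJ/UPGMA ties by lowest index; placement ties by sorted edge
identity.  Constant alignments make the gamma shape undefined and raise;
an alignment whose taxon has no ungapped symbols raises in the composition
module; dropping every taxon, empty candidate sets, missing distance
entries, negative rates or copy numbers, and frequencies outside [0,1] all
raise rather than repair.  Every stochastic routine takes an explicit seed
and is reproducible bit-for-bit under it.

## Problem sizes

The validation suite runs at deliberately modest scales — 3–32 taxa,
60–200 families, alignments of 1,000–2,000 columns, 20 replicate seeds for
the two headline experiments, 1e5 Monte-Carlo replicates for extinction —
chosen as the smallest sizes at which each estimator's sampling noise is
comfortably below the effect being measured.
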