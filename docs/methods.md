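# Methods

`biomesite` implements a complete in-silico workbench for body-site
attribution of microbiome samples: a generative model of multi-study 16S
OTU tables with planted biomarker structure, the preprocessing steps a
cross-study analysis needs, an in-silico two-source mixture procedure, a
calibrated Random-Forest classification framework, local-causal
biomarker discovery, and trait enrichment. This note records the models,
the defaults and why, the numerical choices, and the limitations.

## The generative model

Real cross-study body-site collections have three structural features
that matter downstream: class structure (body sites), batch structure
(studies with their own detection biases), and compositional counts at
log-normally distributed depth. The generator reproduces exactly these,
with four OTU categories:

* **Direct PA markers** (`n_direct_pa_per_site` per site, default 4):
  latent presence probability `p_high` (0.9) in their own site, `p_base`
  (0.3) elsewhere.
* **Direct NA markers** (default 4 per site): `p_low` (0.05) in their
  own site, `p_base` elsewhere — absence is informative.
* **Indirect OTUs** (`n_indirect`, default 25): each child adopts one
  uniformly chosen direct PA parent and is present with probability `q1`
  (0.9) if the parent is detected and `q0` (0.1) otherwise. Given the
  parent's observed state the child's law does not mention the site, so
  the conditional mutual information of (child; site | parent) is zero
  by construction — these are the associations a local-causal search
  should explain away.
* **Noise OTUs** (`n_noise`, default 200): `p_base` everywhere.

Study membership is uniform over `n_studies` (default 6). Detection bias
is one per-(study, OTU) dropout probability drawn uniformly from
`study_dropout_range` (default (0, 0.3)): a present OTU is erased with
that probability, emulating primer/amplification bias that is stable
within a study. Depth is log-normal (`depth_log_mean` 9.0,
`depth_log_sd` 0.6; median ≈ 8100 reads), rounded up, floor 1. Counts
are one multinomial draw per sample over its present OTUs with
log-normal weights (`abundance_log_mean` 0, `abundance_log_sd` 1), so
column sums equal depths exactly.

A present PA marker's weight in its own site is multiplied by
`marker_abundance_boost` (default 6). This mirrors the familiar
situation that site-characteristic taxa do not merely occur more often
but dominate their community (lactobacilli in the vagina, anaerobic
fermenters in stool); it is what gives relative abundances — the
classifier's input — a class signal beyond detection frequency.

Defaults yield 5 sites × 300 samples (1500 samples, 265 OTUs): large
enough for stable conditional G-tests at `max_k` ≤ 3 and 5-fold nested
cross-validation, small enough that the full pipeline runs in minutes on
one core.

**What the generator does not emulate:** sequence-level artifacts
(chimeras, 16S copy number), taxonomy beyond a synthetic one-genus-per-
OTU mapping, study-specific abundance (as opposed to detection) shifts,
phylogenetic correlation among OTUs, and real ecological networks deeper
than one parent–child layer. Passing tests therefore show that the
algorithms do what their definitions promise under a known data-
generating process — not that real body-site data satisfy those
assumptions.

Seeding: one master seed is expanded through `numpy.random.SeedSequence`
into independent streams for layout, presence, dropout, depth, counts,
and traits; identical configs give byte-identical outputs.

## Preprocessing

Samples detecting fewer than 20 distinct OTUs are removed (shallow or
failed runs behave as noise). Counts are divided by per-sample depth for
the classifier; presence/absence (count ≥ 1) feeds the independence
tests, which damps depth bias and makes the G-test exact. OTUs whose
detection patterns are nearly interchangeable are collapsed before
biomarker discovery: normalized mutual information (NMI) between binary
rows, complete-linkage clustering on distance 1 − NMI, tree cut at
1 − 0.9 so every within-group pair has NMI ≥ 0.9, one seeded random
representative per group. Clustering directly on the NMI scale makes the
0.9 criterion exact and testable; clustering the rows of the NMI matrix
under Euclidean distance is retained as an alternative mode but its cut
height only approximates the pairwise criterion. NMI uses plug-in
entropies in natural log, normalized by the geometric mean of the
marginal entropies (arithmetic-mean and min normalizations selectable);
a constant vector has NMI 0 by convention.

## Mixture simulation

A mixed sample of target sample t and background sample b at background
fraction F is one multinomial draw of size
n = round((1−F)·depth(t) + F·depth(b)), floor 1, from
p = (1−F)·p_t + F·p_b, where p_t, p_b are the parents' relative OTU
frequencies. F = 0 and F = 1 are exact redraw boundaries. Evaluation
sets pair every target-site validation sample with one background-site
sample drawn uniformly with replacement; the negatives are the unmixed
background-site validation samples, which makes the F → 0 limit of the
mixture AUC coincide with the unmixed baseline. Training-set
contamination replaces a chosen fraction of samples (default 50%) by
their 30% background mixtures, labels untouched.

## Classification

Features are relative abundances; the learner is a Random Forest with
class weights inverse to class frequency. Hyperparameters (trees ∈
{500, 1000, 2000}; max features ∈ {½, 1, 2}·√p, rounded, floor 1) are
chosen by macro-F1 over a stratified inner 4-fold cross-validation
inside each stratified 5-fold outer split; exact ties prefer the
smaller model. "F1" is macro-F1 (unweighted mean of per-class F1)
throughout — as the inner objective and in reports — with a
study-inverse sample weighting (w_i = 1/|study(i)|) available for
heterogeneity-corrected evaluation.

Probabilities are calibrated per class by isotonic regression fitted on
the inner out-of-fold scores of the winning configuration, then
renormalized to sum to 1 (an all-zero row falls back to uniform).
Isotonic fits are weakly monotone: flat segments tie distinct raw
scores, which would perturb tie-sensitive rank metrics. `predict_proba`
therefore adds a 1e-9 · raw-score component before renormalizing, which
keeps the per-class ranking strict, so AUC is exactly invariant under
calibration while probabilities change by less than 1e-9.

Decision thresholds for mixture detection are optimized per (target
site, background site, fraction) on mixtures of *training* samples only
(the forest and calibrators never see mixtures): candidate thresholds
are all observed scores plus midpoints, the binary-F1 maximizer is
chosen, and ties break toward the higher threshold, which for perfectly
separated scores returns the lowest positive score. The default grid —
every ordered site pair × fractions 10%…100% — has 5 × 4 × 10 = 200
entries; a fine grid starting at 1% serves trace-detection studies.

Additional evaluation utilities: row-normalized confusion matrices,
biased subsets (keep one site whole, down-sample every other site to
10% of its count, seeded), study-wise learning curves (largest study
first, remainder shuffled, model refit per cumulative set, both
weighting schemes reported on a fixed held-out set), and
feature-importance overlap between two models (predictive = impurity
importance > 0; Spearman rank correlation over the intersection,
undefined for fewer than two shared features).

## Biomarker discovery

All tests operate on the binarized, redundancy-reduced table with a
one-vs-rest site indicator per body site.

**G-test.** G = 2N·MI(X;Y|Z) in natural-log units, summed over the
strata defined by the joint conditioning assignment; empty strata are
skipped, zero cells contribute nothing, df = (levels(X)−1)(levels(Y)−1)
per non-empty stratum, p from the chi-square upper tail, and df = 0
(a constant margin) yields p = 1. No sample-size floor beyond the df
accounting is applied.

**Screen.** Every OTU is tested unconditionally against the indicator;
Benjamini–Hochberg adjustment runs over all OTUs and candidates are the
adjusted-p ≤ α survivors ordered by decreasing G (ties: OTU id
ascending). FDR control applies to this screen only; the conditioning
stage uses raw α = 0.05, matching a design in which multiplicity is
controlled before the sequential search.

**Semi-interleaved HITON-PC.** Candidates enter in priority order; each
is admitted to the tentative parents-and-children set (TPC) unless some
conditioning subset of the TPC with size ≤ `max_k` (default 3) gives
p > α, in which case it is discarded permanently; after the forward
pass, members are re-tested against subsets of the remaining TPC until
stable. `h_ps` (default 5) restricts subset enumeration to the h_ps
TPC members with the strongest unconditional association — an
efficiency cap that bounds the number of tests per candidate at
Σ_{k≤max_k} C(h_ps, k). The search can only remove screened candidates,
never add.

One caveat is inherent to one-sided parents-and-children search: a
non-neighbor can survive when all of its separating sets require a node
outside the target's parents-and-children that was itself (correctly)
discarded. The GLL remedy is the symmetry (AND) filter — keep X only if
the target also appears in X's own search — which is provably exact
under a faithful independence oracle; the validation harness applies it
when checking the search against exact d-separation, while the data
path stays one-sided (markers are intended per site, and the
false-positive mode is rare at these graph densities). True neighbors
are never dropped in either variant, because no conditioning set
separates them.

Association signs are the sign of ad − bc in the OTU × indicator 2×2
table (equivalently the Spearman sign for binary vectors); an exact
zero or constant margin is reported as indeterminate, and indeterminate
markers are excluded from PA/NA-only feature subsets. Marker strength
is the NMI with the indicator; prevalence is the number of samples
detecting the OTU; an importance percentile is attached when a trained
model is supplied.

## Trait enrichment

Traits live at the genus level in five categories (aerobicity, gram
stain, shape, spore formation, motility) and are extrapolated to member
OTUs. For each (site, association type, sub-category), the focal set is
the site's markers of that type with known status for the category; the
background is the same-type markers of all other sites. The test is the
one-tailed (greater) Fisher exact test; OTUs with unknown status are
excluded from both margins; multi-valued traits count once per
alternative. Benjamini–Hochberg adjustment runs over all records
jointly (the least anti-conservative delimitation that still controls
the whole table), and a record is flagged at adjusted p ≤ 0.05. Records
with an empty margin are skipped rather than reported.

The generator's trait layer plants one enrichment (default: anaerobes
among the first site's PA markers at probability 0.9 vs 0.2 background)
and can silence it (`trait_enrich_p = trait_background_p`) for null
calibration; a configurable fraction of genera lose each category
independently to emulate missing literature information.

## Problem sizes and numerical choices

Validation work uses the default 1500-sample dataset; fast checks use a
trees ∈ {100, 200} × multiplier ∈ {1, 2} grid, which on this data
selects models indistinguishable in held-out macro-F1 from the larger
default grid; conditional-independence structure checks use 5000
samples. Monte-Carlo assertions use 99% intervals computed from the
binomial/multinomial standard errors they test. All stochastic steps
take explicit seeds; per-stage streams derive from one master seed.
Degenerate inputs follow explicit conventions stated above (constant
vectors in NMI and the G-test, zero-sum probability rows, empty
enrichment margins, empty mixture strata).

## Known limitations

* The generator's NA-marker mechanism (depressed own-site presence) is
  a modeling device, not a claim about why real taxa avoid a site.
* Study effects are detection-only; a batch shift in abundance would
  stress the classifier in ways these simulations do not probe.
* The mixture negatives are unmixed background samples; other negative
  designs (e.g., excluding mixture partners) would shift AUC slightly.
* The discovery stage returns parents-and-children-style direct
  markers, not Markov blankets: spouse OTUs and causal orientation are
  out of scope.
* Exact semantics of the h-ps cap follow common GLL-style
  implementations (strongest-association pool restriction); other
  readings of the parameter exist.
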