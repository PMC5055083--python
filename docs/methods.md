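# Methods

This note documents the models and procedures implemented in `metscreen`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data tests do and do not demonstrate.

## Quantification by bracketed external calibration

Instrument responses are converted to concentrations per metabolite and per
24-injection block. The two calibration-standard sets flanking a block (one
before, one after) are pooled and fitted jointly; pooling the bracket is the
drift correction — a drifting response surface is approximated by the average
of its states before and after the block. Partial terminal blocks use the two
nearest standard sets.

Two curve models are supported: ordinary least squares of response on
concentration (`linear`) and OLS of log response on log concentration
(`power_law`, i.e. `response = a·conc^b`). The model is either fixed per
metabolite by configuration — screens typically keep a per-analyte choice —
or selected automatically by the smaller residual sum of squares on the log
scale, which weighs relative rather than absolute error and therefore does
not let the highest standard dominate. Weighting is unweighted OLS on the
chosen scale; nothing in the data model motivates a variance weighting
scheme, and the retained-level rule (below) already limits extrapolation.

Standard levels whose nominal concentration is more than 4× above the
highest or 4× below the lowest sample concentration of the block are
excluded before the final fit. Because sample concentrations are unknown
prior to calibration, a provisional curve on all levels supplies them; the
exclusion rule is then applied once and the curve refitted. At least two
levels must survive or the block/metabolite errors out. Inverse prediction
floors negative concentrations at zero and flags them; non-positive
responses under a power-law curve are likewise flagged.

Technical variation is summarized from the repeatedly injected pooled QC
sample as per-metabolite relative SD (SD/mean). Note this estimate includes
calibration-transfer variance (block-to-block curve wiggle), which is part
of the analytical error a QC sample is meant to monitor; the generator test
that checks recovery of the *planted injection* RSD therefore switches
standard noise off.

## Dilution and batch normalization

PQN computes per-sample factors `f_i = median_m(x_im / ref_m)` against a
reference profile (default: the median profile over strain samples — the
conventional choice; configurable) and divides each sample by its factor.
The median over metabolites makes the factor robust to the sparse genuine
concentration changes: with ≤ 2 of 19 metabolites perturbed in most strains,
the median ratio tracks biomass, not biology.

Batch correction follows a plate-screen scaling scheme: (1) overall
per-metabolite mean; (2) PQN within each batch, so that batch means are not
confounded by each batch's dilution composition; (3) per-batch per-metabolite
means; (4) each sample divided by its batch mean and multiplied by the
overall mean; (5) a final global PQN pass. Scaling is per metabolite (an
interpretation — a single pooled scaling is the alternative reading; the
per-metabolite version is what a metabolite-specific batch effect requires).
Batches with fewer than two samples are left unscaled with a warning.

One identifiability consequence is worth recording: rescaling each batch to
the global mean absorbs the batch's median dilution into the scale factor,
so after batch correction only *relative* dilution within a batch is
recoverable. The dilution factors reported by the workflow are the final-PQN
factors (used for slow-grower flagging, where the ±4% per-batch ambiguity is
immaterial); the generator-recovery test of absolute factor recovery runs on
a batch-free screen for exactly this reason.

Slow growers: implied divisions `d_i = median_divisions + log2(f_i)` with
`median_divisions = 2.79` (the screen's median culture, OD-calibrated); the
cutoff `f < 0.25` ≈ 0.8 divisions. Strain exclusion (complemented controls,
cross-contamination, outdated ORFs, slow growers) is audited per category,
never silent. Intracellular concentrations use
`amount = c_extract · V_extract` over `N_cells · V_cell` with the preset
OD 1.46, 200 µl extraction, 1.685 ml culture, 3.2·10⁷ cells/OD/ml, 45.54 fL;
the volume bookkeeping is covered by a dimensional-analysis test since the
formula (rather than its constants) is the package's own declaration.

## Robust significance model

`ScreenProfileModel.fit()` estimates the unperturbed profile with the MCD
estimator (scikit-learn's FastMCD with reweighting and consistency
correction). Support fraction h defaults to 0.75 — a standard high-breakdown
compromise: h = 0.5 maximizes breakdown but wastes efficiency, h near 1
tolerates little contamination; at ~30% perturbed strains, h = 0.75 keeps the
subset estimation inside the unperturbed majority. `h = 1` is special-cased
to the classical mean/covariance so the classical limit is exact. The MCD
subset search is seeded; near-threshold calls can move between seeds, which
the reproduction script reports as across-seed spread rather than hiding.

Tests: `D²_i = (x_i−μ̂)ᵀΣ̂⁻¹(x_i−μ̂)` against χ² with df = number of
metabolites (19 in the motivating screen after dropping the oxidation-prone
cysteine; df follows the matrix's column count). Univariate two-sided Z tests
per metabolite (deletions both raise and lower concentrations). BH adjustment
runs per family — the multivariate family across strains, and each
metabolite's univariate family across strains; a global pooled alternative is
available (`bh_family="global"`). A strain is significant when either family
calls it at adjusted p < α (default 0.01).

`summarize_effects()` reports per-metabolite relative SD (σ̂/μ̂),
per-metabolite hit counts with their median, per-strain simultaneous-change
counts and their cumulative distribution — the screen-level quantities of
interest. External (e.g. drug-treatment) profiles enter screen units as
`(profile − wt)/σ̂`.

## Consensus clustering and adaptive branch pruning

Distances are pairwise Mahalanobis, computed by Cholesky whitening with the
robust covariance; Ward linkage operates on these distances via scipy, i.e.
the squared-distance (Ward.D2-style) update — linkage dialects differ and
this one is fixed and documented. Each of the (default 500) iterations
removes a uniformly drawn 0–20% of profiles — uniform because nothing
selects another distribution on the removal fraction — re-clusters the
survivors and cuts the dendrogram at 8 depths. The consensus index is the
co-clustering count over `co_retained × 8`, so removal never deflates
similarity; pairs never co-retained are reported as missing (NaN), not 0,
and only enter the final clustering as maximally distant.

Cut depths are evenly spaced fractions (10%–80%) of the merge-height
*range*. The open design choice here was range fractions versus quantiles of
the merge-height distribution. Metabolic signatures group by shared
*location* (which metabolites move, and how far), not by reduced internal
spread — two strains with the same deletion signature are no closer to each
other than two unperturbed strains are. Quantile cuts concentrate in the
low-height region where such groups have not yet finished merging, and on
planted-module screens they drive within-module consensus toward zero;
range-fraction cuts sample the informative top region of the tree and keep
planted modules intact across most depths.

The final tree on `1 − consensus` is cut by a re-implemented hybrid adaptive
branch pruning with the three standard parameters exposed
(`min_cluster_size = 2`, `deep_split = 4`, `respect_small_clusters = True`):
forced splitting above 99% of the height range; recursive branch
decomposition where a child branch separates when its core scatter (mean
internal merge height) is below a deepSplit-mapped ceiling
(0.64/0.73/0.82/0.91/0.95 of the usable range) and the joining merge sits
above the child's scatter by a deepSplit-mapped minimum gap; a union of two
well-separated branches that are each below the minimum size is dissolved
rather than accepted as a cluster; leftover leaves are attached to the
nearest cluster by average distance (PAM-like stage) or labeled 0.
`deep_split` is the granularity dial: 4 reproduces the fine,
many-small-clusters regime appropriate at genome scale, while coarse
recoveries (e.g. a three-module test screen) are exact at 1–3; at 4, the
absolute minimum gap becomes comparable to Ward's size-driven height growth
inside a tight block and coherent modules are occasionally subdivided.

Joint clustering with external standardized profiles uses the robust
correlation matrix as the covariance on Z-score profiles (the same metric in
standardized coordinates) and reports each external profile's nearest strain
and that strain's cluster.

## Enrichment and network evaluation

The gene-set statistic is the mean per-gene D² over the term's genes (median
available); the null re-samples same-size gene sets from the universe
(`p = (1+#{null ≥ obs})/(1+n_perm)`), because the screen has one profile per
gene — gene sampling is the only exchangeable unit. Enrichment is
non-directional by construction (D² is a magnitude). Hypergeometric tests
use the upper tail; cluster annotation optionally removes the studied ORF
from both its cluster and the background (leave-one-out), so a gene never
supports its own annotation. Set-size filters default to 3–500.

The term perturbation network connects enriched terms when they share more
than 50% of the smaller term's genes (the most permissive reading of gene
"sharing"; both-directions and Jaccard variants would only remove edges) and
lie within undirected parent-child distance 2; duplicate edges are removed,
transitive reduction is not applied. Communities come from edge-betweenness
(Girvan-Newman) at the modularity maximum, with the connected-component
partition included as a candidate (the iterator itself never yields it).

Cluster assignments become fully connected within-cluster graphs
(`Σ_k C(n_k,2)` edges); orthogonality against a reference network is the
edge overlap and edge-count ratio after restricting both graphs to shared
nodes. Precision-recall descends the consensus ranking with tied scores
processed as a block (consensus indices are heavily tied); gold-standard
pair sets fix TN = 9×TP, putting the random-classifier precision at 10%.

## Synthetic screens: what they emulate, and what they do not

The generator reproduces the *structure* of a plate-based screen: observed
response `g_m(conc · f_i · b_{batch,m})(1+ε)`, linear or power-law response
functions, six-level calibration series spanning three orders of magnitude,
bracketing standards and a QC injection every 24 samples, 11 batches with
log-normal per-metabolite scalings (σ = 0.10), log-normal dilution factors
(median 1, σ = 0.25) with a configurable slow-grower tail, baselines
log-spaced over a 1000-fold dynamic range, per-metabolite technical RSD
drawn from 4–10%, correlated technical-noise blocks (ρ = 0.5), ~30% of
strains perturbed with mostly ≤ 2 affected metabolites, effect sizes in
metabolite-SD units (median 6 SD), and planted functional modules with
matching gold-standard pairs and GMT annotations. All randomness flows from
one seeded generator through deterministically derived sub-streams; a fixed
seed reproduces the screen byte-identically.

It does not emulate chromatography (no retention times, peak shapes or
integration), biological replicate structure, growth-rate-coupled biology,
missing values, or real annotation sparsity. Tests that pass on these
screens therefore certify the *pipeline's* statistical behavior —
calibration accuracy, normalization recovery, error control, clustering
recovery — under the stated noise model, not performance on any particular
instrument's data.

Two scenario-design points: (i) the planted-module recovery scenarios use
`cluster_signature_mode="disjoint"` (each module perturbs its own metabolite
panel, as functional modules hitting distinct pathways do) and strong 8-SD
effects, because the recovery claim is about the clustering machinery, not
about separating overlapping signatures; (ii) multiplicative noise makes the
variance of a strongly *elevated* metabolite grow with its level, so even
"identical" planted signatures realize with visible spread — a realism that
bounds achievable cluster purity.

## Problem sizes and numerical points

Default analysis sizes used by the test suite and the acceptance script:
null screens of 600–2,000 strains × 19 metabolites, recovery screens of 120
strains × 12 metabolites, 25–100 consensus iterations for tests (500 remains
the production default). These sizes put every recovery quantity well inside
its sampling bounds while keeping a full run in minutes on one CPU.

Degenerate inputs are handled explicitly: all-equal merge heights collapse
to a single cluster (or none, under the minimum size); never-co-retained
consensus entries are NaN; zero-variance metabolites, singular covariances,
all-zero samples, empty terms and gold standards without positives raise
errors naming the offender. Ties in the PR sweep and in `final_clusters`
label ordering are resolved deterministically (stable sorts, size-ordered
labels).

## Known limitations

* The MCD is seed-dependent; strains near the significance threshold can
  change calls between seeds. Spread is reported, not suppressed.
* The consensus normalization (divide by co-retention × cuts) and the
  range-fraction depth definition are declared choices among reasonable
  alternatives; both are configurable at the API level.
* The re-implemented branch pruning follows the published threshold ladder
  but is not a line-for-line port; at `deep_split = 4` it is deliberately
  aggressive and may subdivide tight modules (see above).
* Batch correction leaves per-batch absolute dilution unidentifiable (by
  construction of mean scaling); only relative factors are meaningful
  downstream of it.
* The screen measures one profile per strain; no replicate-level variance
  model is attempted, and the per-strain re-screen of low-concentration
  strains in the motivating study is not modeled as a merge rule (no stated
  combination procedure exists to implement).
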