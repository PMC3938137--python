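# Methods

This note records the models, defaults and numerical choices behind
`dmakit`, and what the synthetic fixtures do and do not establish about
real microarray data.

## Data model

The central object is a probe × sample intensity table (non-negative,
arbitrary fluorescence units) with an optional shape-identical table of
detection p-values — the per-probe, per-sample probability that the signal
is indistinguishable from negative-control background. Missing intensity
cells are allowed and carried as NaN; only the PPCA stage accepts them —
normalization, filtering, t-tests and clustering refuse missing values
rather than silently imputing. Group assignments carry an explicit level
order; for time courses the level order *is* the time order. Gene
identifiers are matched case-insensitively after whitespace trimming in
every set and annotation lookup, because symbol casing is inconsistent
across annotation sources.

## Normalization

Quantile normalization replaces each sample's values by the rank-wise mean
of the per-sample sorted vectors. Ties within a sample receive the mean of
the reference values at the ranks the tie occupies, which keeps the
transform idempotent and mean-preserving. Normalization operates on the
linear intensity scale; log transforms are applied downstream where a
stage calls for them (t-tests, heat maps). The canonical pipeline order is
normalize, then filter.

## Filtering

All filters follow the all-samples-fail retention rule: a probe is removed
only when every sample fails the criterion (detection p > α, or intensity
< floor), so transcripts expressed in a subset of conditions survive. The
variance filter removes the ⌊fraction × n⌋ probes with the smallest
across-sample variance (unbiased, n−1 denominator); ties at the boundary
are broken by stable input order. Every filter returns an audit record
(rule, threshold, before/after counts, removed IDs).

## Differential expression

Fold change is the ratio of linear-scale group means; the p-value is a
two-sided t-test on log2 intensities. Welch's unequal-variance form is the
default (robust to heteroscedastic groups); a pooled-variance option
exists. Probes with zero variance in both groups get p = 1 when the means
agree and p = 0 when they differ exactly. The volcano caller keeps probes
with max(FC, 1/FC) ≥ c and p < α, covering both directions. No
multiple-testing correction is applied by default — nominal p-values are
reported, with Benjamini–Hochberg adjustment available as an option.

For multi-condition (time-series) data each probe is scored by the Pearson
correlation r of its intensity vector with the sample-order ramp
A = (1, …, n), samples sorted by the time-ordered levels with ties broken
by input order. Selection uses |r| ≥ threshold so both rising and falling
trends pass. Selected probes are ranked by
(variance of timepoint means) / (pooled within-timepoint variance + ε)
with ε = 1e-9 × the global data variance guarding division by zero; the
score is this package's own definition of "separates the timepoints
strongly and quietly" — probes with clean monotone steps rank above noisy
ones of equal amplitude.

## Enrichment

Over-representation uses the hypergeometric upper tail P(X ≥ x); a
pmf-only compatibility mode reports the point mass instead, but a tail is
the defensible summary for an over-representation claim. The pmf is
evaluated through log-gamma functions so chip-scale backgrounds cannot
overflow; an integer-binomial path is kept for cross-checking (the two
agree to better than 1e-10 relative error for backgrounds up to 1000; the
log path is checked against exhaustive draw enumeration up to M = 12 in
the tests). Tail values are clipped into (0, 1]. The default background is
the post-filter probe set collapsed to genes (a gene counts once however
many probes map to it); query genes absent from the background are dropped
with a warning. For ontologies, annotations are propagated to every
ancestor (true-path rule) before per-term testing, and root terms —
annotated with essentially the whole background — are excluded from
output. Because the hypergeometric distribution is discrete, nominal
p-values are super-uniform under the null: calibration checks assert
validity (P(p ≤ t) ≤ t plus binomial slack), not exact uniformity.

## Clustering and PPCA

The heat-map/dendrogram convention is log2 transform, then gene-wise mean
centering, then clustering, so displays show relative expression patterns;
linear-scale clustering is available by flag. Supported linkages (single,
complete, average) have monotone merge heights. Dendrogram leaf order is
deterministic: at each merge the subtree containing the smaller minimum
leaf index goes left. K-means (Lloyd, Euclidean, best of 10 restarts by
within-cluster sum of squares, seeded) is delegated to scikit-learn, which
relocates empty-cluster centroids instead of failing; profile clustering
(rising vs falling waves) uses log2 + row-centered inputs.

PPCA fits x = Wz + μ + ε, z ~ N(0, I_q), ε ~ N(0, σ²I) by EM, with samples
as observations and probes as features. The mean vector is fixed at the
per-feature mean of observed entries — the exact MLE for complete data —
and EM then runs over (W, σ²) with both the latent scores and any missing
coordinates integrated in the E-step. With μ fixed this is exact EM, so
the observed-data log-likelihood is provably non-decreasing (asserted to
1e-8 relative tolerance); for incomplete data the fixed-μ choice trades a
slightly biased mean for that guarantee. Loadings are initialized from
small seeded Gaussian noise (reproducibility over cleverness); iteration
stops when the relative log-likelihood change drops below `tol` (default
1e-9) or at `max_iter`. Scores are posterior means under the fitted model;
on complete, well-conditioned data the loading subspace converges to the
top eigenvectors of the sample covariance.

## Primer design

Candidates are all windows within the length bounds on both strands.
The filter cascade is fixed: length → GC → Tm → homopolymer run → hairpin
→ self-dimer; surviving forward/reverse candidates are paired under
amplicon-length, ΔTm and cross-dimer constraints. Structure checks are
exact-complementarity run counting (longest contiguous Watson–Crick run in
any antiparallel alignment; hairpins require a reverse-complement
substring pair separated by at least the loop minimum) — deterministic and
oracle-testable, not free-energy minimization, so they screen rather than
predict folding energies. Melting temperature defaults to unified
nearest-neighbor thermodynamics with salt correction (250 nM primer,
50 mM monovalent salt), the standard model at qPCR primer lengths; the
Wallace rule 2(A+T) + 4(G+C) is available for quick estimates. Default
constraints (length 18–25, GC 0.40–0.60, Tm 57–63 °C, ΔTm ≤ 3 °C, run ≤ 4,
hairpin stem ≥ 4 with loop ≥ 3, dimer run ≤ 8, amplicon 70–200 bp) are
conventional qPCR screening values. Pair score penalizes |ΔTm|, deviation
of the amplicon from the midpoint of its allowed range, and dimer runs;
the forward × reverse feasibility matrix codes why each combination
passed or failed, which is the data behind a 2-D feasibility plot of
problematic template regions.

## Synthetic fixtures

Generators are pure functions of (parameters, seed). Expression data is
simulated on the log2 scale — baselines uniform in [6, 12], a typical
fluorescence dynamic range — and exponentiated, so planted linear fold
changes are exact in expectation. The two-group generator defaults to
2000 probes, 5 vs 5 samples, 100 probes shifted ±log2(2.5) with log2 noise
σ = 0.25. The time-course generator defaults to six ordered timepoints
(day 0 to day 14) with four replicates each, and plants monotone log2
ramps of total amplitude 2 (50 rising, 50 falling), emulating expression
waves that decay or build over an infection course. The gene-set generator
plants one set sharing 20 of 40 query genes against a 400-gene background,
with a three-layer toy ontology whose leaves partition the genes. The
template generator draws GC-0.9 background with homopolymer decoys and
plants one forward and one reverse 20-mer site, framed by homopolymer
flanks and rejection-sampled until the planted pair is the unique
combination surviving the default screen — recovery is therefore
guaranteed by construction, and the corresponding tests verify the
machinery, not luck.

What the fixtures do *not* model: probe-level vendor noise structure,
intensity-dependent variance, batch effects, cross-hybridization, probe
sets mapping to one gene, or realistic gene-set overlap structure.
Passing recovery tests therefore demonstrates that the algorithms do what
they claim under their own assumptions (Gaussian log-scale noise,
independent probes), not that a particular biological dataset would yield
a particular gene list.

## Problem sizes and numerical tolerances

The test and acceptance workloads use 1000×6 matrices for normalization
checks, 2000-probe simulations for calibration and recovery, backgrounds
up to M = 1000 for hypergeometric cross-checks, 12–20-feature matrices
with 40–150 samples for PPCA, and 400-bp templates for primer design —
sizes at which every oracle (enumeration, eigendecomposition, exhaustive
substring scans) is exact and fast. Numerical assertions use 1e-12
relative tolerance for rank-based and correlation identities, 1e-10 for
the two hypergeometric evaluation paths, and 1e-8 relative slack for EM
log-likelihood monotonicity (floating-point accumulation at convergence).

## Known limitations

No background correction, batch correction or probe-set summarization; no
moderated-variance (empirical Bayes) testing; no paired designs; no
GSEA-style rank enrichment; primer screening ignores genome-wide
specificity and intron spanning; spreadsheet ingest is out of scope —
delimited text is canonical.
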