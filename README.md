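# dmakit

Scriptable analysis of DNA-microarray expression data: everything a
point-and-click microarray suite does, as a Python library and a `dmakit`
command line — quantile normalization, background filtering, two-group and
time-series differential expression, hypergeometric pathway/GO
over-representation, hierarchical and k-means clustering, probabilistic PCA
that tolerates missing values, and RT-qPCR primer design for follow-up
validation.

It is aimed at bench biologists and bioinformaticians who have a probe ×
sample intensity matrix (exported from any array platform as delimited
text) and want a reproducible, seedable pipeline from raw intensities to
an annotated candidate-gene list, without a GUI.

## Methods at a glance

- **Quantile normalization** forces every sample to the common reference
  distribution (the rank-wise mean of the sorted samples), preserving each
  sample's probe ranking. Ties receive the mean of the reference values at
  the ranks they occupy.
- **Background filtering** removes a probe only when *every* sample fails
  the criterion — detection p-value > α, or intensity below a floor — so a
  transcript detected in a subset of samples is never lost. A third filter
  drops the fraction of probes with the lowest across-sample variance.
- **Two-group differential expression**: fold change is the ratio of
  linear-scale group means; significance is a two-sided Welch t-test on
  log2 intensities. The volcano double criterion calls a probe when
  max(FC, 1/FC) ≥ c and p < α.
- **Time-series trends**: each probe's intensity vector *B* is scored by
  the Pearson correlation *r* with the sample-order ramp
  *A* = (1, 2, …, n); probes with |r| ≥ threshold are ranked by the ratio
  of between-timepoint variance to pooled within-timepoint variance.
- **Enrichment**: for a query of *n* genes from an *M*-gene background and
  a set with *K* background members, the over-representation p-value is
  the hypergeometric upper tail
  P(X ≥ x) = Σᵢ C(K,i) C(M−K, n−i) / C(M,n), evaluated in log space. GO
  annotations are propagated to all ancestors (true-path rule) before
  per-term testing.
- **PPCA**: the Gaussian factor model x = Wz + μ + ε with isotropic noise,
  fitted by EM; missing entries are integrated out in the E-step, so 2-D
  sample maps work on incomplete matrices.
- **Primer design**: exhaustive window enumeration on both strands with a
  filter cascade (length, GC, melting temperature by Wallace rule or
  unified nearest-neighbor thermodynamics, homopolymer runs,
  hairpin/self-dimer complementarity runs), then pairing under amplicon,
  ΔTm and cross-dimer constraints, with a forward × reverse feasibility
  matrix for spotting problematic template regions.

## Worked example

```python
from dmakit import (gen_two_group, quantile_normalize, filter_by_intensity,
                    two_group_stats, select_volcano)

data, groups, truth = gen_two_group(n_probes=2000, n_de=100, fold=2.5,
                                    sigma_log2=0.25, seed=1)
data = quantile_normalize(data)
data, report = filter_by_intensity(data, floor=90)
print(f"{report.probes_before} -> {report.probes_after} probes "
      f"(floor {report.threshold})")

results = two_group_stats(data, groups, "trt", "ctrl")
hits = select_volcano(results, fc_cutoff=2.0, p_cutoff=0.05)
print(f"{len(hits)} probes differentially expressed (>=2-fold, p < 0.05)")
top = max(hits, key=lambda r: abs(r.log2_fold_change))
print(f"top probe {top.probe_id}: fold {top.fold_change:.2f}, "
      f"p = {top.p_value:.2e}")
```

prints

```
2000 -> 1963 probes (floor 90)
87 probes differentially expressed (>=2-fold, p < 0.05)
top probe P00389: fold 3.25, p = 5.51e-06
```

2000 simulated probes carry 100 planted 2.5-fold effects under log2 noise
σ = 0.25; after normalization and background filtering the volcano double
cutoff calls 87 probes, all of them planted (the handful of misses are
planted probes whose low baseline fell below the intensity floor or whose
noisy fold estimate landed under 2).

The same stages are available from the shell:

```sh
dmakit simulate two-group --seed 1 --out fixture/
dmakit normalize --expression fixture/expression.tsv --out norm.tsv
dmakit diffexp --expression norm.tsv --groups fixture/groups.tsv \
       --test trt --control ctrl --fc 2 --p 0.05 --out de.tsv
dmakit primers --template cdna.fasta --amplicon 70:200 --top 5 --out pairs.tsv
```

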