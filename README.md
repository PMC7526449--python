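# regact

Regulator activity inference and clinical stratification for systemic
sclerosis (SSc) gene-expression cohorts.

SSc is a heterogeneous autoimmune disease with skin fibrosis and internal
organ involvement; skin gene expression defines four "intrinsic" patient
subsets (fibroproliferative, inflammatory, limited, normal-like). This
package infers the per-sample activity of gene-expression regulators —
transcription factors and miRNAs represented by motif target-gene sets —
directly from expression data, and uses those activities to find
regulators that track the intrinsic subsets, rank regulators by
association with skin severity (the modified Rodnan skin score, MRSS),
stratify patients into quadrant subgroups from regulator pairs, and build
regulator→regulator interaction networks. A bundled synthetic-data
generator with planted ground truth makes every stage testable without
any external downloads.

## The statistic

For a sample with normalized expression e and a regulator with target set
g, genes are sorted by expression in decreasing order and two cumulative
distribution functions are formed: a foreground F(j) accumulating the
|e|-weight of target genes and a background B(j) over non-targets. The
preliminary activity score is

    s = F(j*) − B(j*),   j* = argmax_j |F(j) − B(j)|,   s ∈ [−1, 1]

(positive when targets concentrate among highly expressed genes), and the
final score divides s by the mean |score| over random permutations of the
target labels (default 1000), giving a normalized, sample-specific
activity. miRNA scores are negated, since miRNAs repress their targets.

Downstream: the within-between score SSW/SSB with a permutation FDR
selects regulators consistent within subsets but variable across them
(FDR < 2% in ≥ 3 cohorts); Pearson correlation with MRSS ranks regulators
per subset (top/bottom 50 flagged); pairs of positively correlated
regulators split samples into four sign quadrants, and the double-positive
group is tested for higher MRSS (rank-sum, Benjamini–Hochberg), ILD
enrichment (fold change > 1.5) and FVC decline (paired t). See
`docs/methods.md` for the full model.

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
4-cohort dataset (three two-channel cohorts, one single-channel, 60
regulators, 10 planted intrinsic regulators, one planted severe driver
pair) and write their tables under `results/`:

```sh
python analysis/01_simulate.py
python analysis/02_score_activity.py
python analysis/03_select_intrinsic.py
python analysis/04_rank_mrss_correlation.py
python analysis/05_subgroup_scan.py
python analysis/06_build_network.py
```

which prints, among other lines:

```
simulated 4 cohorts, 240 samples, 60 regulators; planted 10 intrinsic regulators and severe pair ('REG010_01', 'REG011_01')
selected 10 intrinsic regulators at FDR<2% in >=3/4 cohorts; recovered 10/10 planted, 0 non-planted
fibroproliferative: top-15 flag contains 2/2 planted MRSS drivers; best aggregate PCC +0.683
scanned 105 pairs from 15 positively MRSS-correlated regulators; 53 severe double-positive pair(s) at q<1%
planted pair ('REG010_01', 'REG011_01'): significant=True, median MRSS by group {1: 27.0, 2: 14.0, 3: 4.0, 4: 14.0}
22 pair(s) retained with ILD fold change > 1.5
  FVC decline group 1: mean +3.4 %predicted, t=8.69, p=1.75e-15
network over 38 regulators, 83 directed edges (2 self-loops); highest-degree node: MIR002 (degree 8)
```

Reading: the selection stage recovers exactly the 10 planted
subset-specific regulators; the planted severity drivers rank at the top
of the MRSS correlation; the planted pair's double-positive quadrant has
median MRSS 27 versus 4–14 in the other quadrants and is flagged
significant; and only the double-positive group shows a significant FVC
decline.

The same stages are available as a CLI (`regact score`, `regact
intrinsic`, `regact correlate`, `regact pairs`, `regact ild-scan`,
`regact fvc`, `regact network`, `regact simulate`) and as one end-to-end
pipeline, `regact run --config pipeline.yaml`, which writes every
intermediate plus a manifest with parameters, seeds and checksums.

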