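# metnorm

Paired primary-tumour / lymph-node-metastasis (PT/LNM) immune-transcriptome
analysis for nCounter-style count panels, with a healthy-tissue-background
correction, local pathway over-representation analysis, and the matching
immunohistochemistry (IHC) and survival statistics — plus a fully seeded
synthetic cohort generator so the whole pipeline is testable end to end
without any external data.

## The problem

When a breast tumour colonizes a lymph node, a naive differential-expression
comparison of the metastasis against its matched primary confounds tumour
biology with host tissue: lymph nodes are physiologically rich in
immune-related transcripts and breast tissue is not. `metnorm` implements a
staged analysis that corrects for this background:

1. **Count normalization** (per lane *s*, all PT and LNM lanes together):
   background threshold `t_s = mean(neg_s) + 2·SD(neg_s)` from the negative
   controls, with sub-threshold counts floored at `t_s`; the 4 most stable
   housekeeping probes (lowest CV of log2 counts) join the positive controls
   as normalizers; lane scale factors `f_s = G / g_s` equalize the
   normalizer geometric means; genes with mean log2 count < 6 are dropped.
2. **Healthy background ratios.** From a two-tissue FPKM table,
   `HEALTHY_g = log2(LYMPH_NODE_g / BREAST_g)` (genes below 32 FPKM in both
   tissues are dropped, and the gene universe is intersected with the count
   panel). Per matched pair *p*, `CANCER_{g,p} = log2(LNM_{g,p} / PT_{g,p})`,
   and the background-normalized ratio is `CANCER_{g,p} − HEALTHY_g`.
3. **Classification** on the per-gene median normalized ratio *M_g*:
   **enriched** if `M_g > 1`, **depleted** if `M_g < −1`; **upregulated** if
   additionally `HEALTHY_g < 0` and the median raw matched ratio is > 0
   (**downregulated** mirrored). Requiring the cancer shift to oppose the
   healthy-tissue direction stops stromal dilution from masquerading as
   tumour-cell regulation.
4. **Over-representation**: one-sided hypergeometric tail test of the
   down-regulated genes against a GMT collection, Benjamini–Hochberg
   adjusted, background restricted to annotated analysed genes.
5. **IHC validation statistics**: core intensities dichotomized
   (none/weak → negative, moderate/strong → positive), specimen status =
   maximum over informative cores, PT-vs-LNM positivity compared by a
   two-sided Fisher exact test (probability-ordering rule), and 3-year
   overall survival by tumoral status of the metastasis compared with a
   Mantel–Haenszel log-rank test after administrative censoring at 36
   months.

## Worked example

Simulate a default cohort (11 matched pairs, 730-gene panel with 8 negative,
6 positive and 40 housekeeping controls; planted 3-log2 effects; a 79-patient
IHC arm with 43 node-positive patients) and run every stage:

```bash
metnorm simulate --out-dir demo/sim --seed 42
metnorm run-all \
    --rcc-dir demo/sim/rcc --sample-sheet demo/sim/samples.tsv \
    --healthy demo/sim/healthy_fpkm.tsv --gmt demo/sim/gene_sets.gmt \
    --ihc demo/sim/ihc.tsv --clinical demo/sim/clinical.tsv \
    --out-dir demo/out
```

prints

```
gene funnel: 730 panel -> 593 expressed -> 578 on both platforms -> 360 analysed
classification: 11 enriched / 69 depleted / 3 upregulated / 33 downregulated
```

The funnel is the gene attrition through the two expression filters and the
platform intersection; of the 360 analysed genes, 3 are called LNM-upregulated
and 33 LNM-downregulated (the planted counts), while the enriched/depleted
calls include decoy genes whose healthy-tissue ratio points the same way and
which are therefore — correctly — not called up/downregulated. The IHC arm:

```bash
metnorm ihc --ihc demo/sim/ihc.tsv --clinical demo/sim/clinical.tsv --out-dir demo/ihc_out
```

```
tumoral: Fisher p = 0.002115
stromal: Fisher p = 2.236e-05
overall: Fisher p = 6.588e-05
3-year OS log-rank: chi2 = 8.100, p = 0.004427 (n = 43)
```

i.e. staining positivity differs between PT and LNM specimens in every
compartment, and losing tumoral staining in the metastasis (planted hazard
ratio 4) is detected as shorter 3-year overall survival. Outputs land as
TSVs (`classification.tsv`, `normalized_matrix.tsv`, `ora.tsv`,
`ihc_comparisons.tsv`) plus a `manifest.json` recording parameters, input
digests and per-stage gene counts.

The same analysis is available as a library — `metnorm.simulate`,
`metnorm.nanostring`, `metnorm.background`, `metnorm.ora`, `metnorm.ihc`,
`metnorm.pipeline` — returning pandas objects throughout.

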