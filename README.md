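# ovfield

Analysis pipeline for characterizing the **eye-field cell-state
transition** from time-course bulk RNA-seq and ATAC-seq of optic-vesicle
organoid differentiation — aimed at computational biologists studying how
a small set of eye-field transcription factors (Rax, Pax6, Lhx2, Six3,
Six6, …) switches on while the pluripotency programme switches off.

The pipeline integrates five kinds of evidence:

1. **Gene gating** — differential expression across the sorted day-3 →
   GFP⁺ day-4/5 contrasts defines *EF-up* genes (FDR < 0.001,
   log2FC > 1.5 in every contrast), *EF-down* genes (mirror image) and a
   *housekeeping* background (|log2FC| < 0.1 per successive day, mean
   normalized expression > 30).
2. **Trajectory clustering** — Gaussian-mixture clustering of z-scored
   trajectories (20 seeded fits per k, k by minimum mean BIC, consensus
   labels from the co-association matrix), mapped to three patterns:
   steep post-day-3 upregulation, gradual downregulation, transient.
3. **Chromatin dynamics in TADs** — consensus accessibility peaks,
   GC/width-corrected normalization, opening/closing calls
   (|Δlog2| > 1.5 between days 3 and 5), and assignment of peaks and
   genes to topologically associating domains (TADs) and inter-TAD gaps.
4. **Motifs and models** — exact-p-value PWM scanning (best strand,
   p ≤ 1e-4), hypergeometric motif enrichment of dynamic peaks against
   housekeeping-TAD peaks, an L2 logistic model whose coefficients rank
   TF motifs by how well they predict opening vs closing chromatin, and
   TF-expression ↔ peak-accessibility correlations
   (activator-like: median r > 0.5, Wilcoxon p < 1e-10 vs background).
5. **Footprinting and CRE ranking** — per-occurrence footprint scores
   from per-bp corrected tracks (central ±12 bp depletion vs 60 bp
   flanks), differential binding between days, footprint–expression
   correlation, and per-gene ranking of candidate cis-regulatory elements
   (CREs) inside the gene's TAD by summed key-TF footprint-score gains,
   with deletion intervals covering the implicated motifs.

Real sequencing data for this design is not bundled; instead the package
ships a **synthetic-data generator** that emulates the study design
(days 0–5 triplicate expression with a GFP sort at days 4–5;
accessibility for days 0–3 and 5 only) and plants known gene programmes,
TF roles, peak dynamics and per-bp footprints.  Every pipeline stage is
validated by recovering that planted truth.

## Worked example

```python
import ovfield
from ovfield.pipeline import run_pipeline

bundle = ovfield.simulate("default", seed=7)   # synthetic study, truth known
res = run_pipeline(bundle, seed=7)

print("EF-up genes:", len(res.gene_sets.ef_up),
      "| EF-down genes:", len(res.gene_sets.ef_down))
print("opening peaks:", (res.dynamic == "opening").sum(),
      "| closing:", (res.dynamic == "closing").sum())
print("clusters:", res.cluster_result.k_selected,
      "patterns:", sorted(set(res.cluster_result.patterns.values())))
print(res.logit_coefs.sort_values(ascending=False).head(4).round(2))
```

prints

```
EF-up genes: 42 | EF-down genes: 78
opening peaks: 198 | closing: 190
clusters: 3 patterns: ['gradual_down', 'transient', 'up_after_d3']
Pax6    2.09
Lhx2    1.98
Rax     1.43
Tcf7    0.38
```

The 42 recovered EF-up genes are exactly the planted steeply-upregulated
set; the three trajectory patterns match the planted programmes; and the
motif-importance model puts the three planted activator TFs on top —
their motifs are the strongest predictors of chromatin that opens across
the transition.  Continuing,

```python
calls = {c.tf: c.call for c in res.regulator_calls}
print(calls["Rax"], calls["Pou5f1"])      # activator_like repressor_like
print(res.cre_rankings["Rax"].head(1))    # top candidate CRE for Rax
```

calls Rax activator-like and Pou5f1 repressor-like from
expression–accessibility correlations in EF-up TADs, and ranks the
planted Rax enhancer (peak 48, in an inter-TAD gap, carrying bound
Rax/Pax6/Lhx2/Sox2/Otx2/Tcf3 footprints at day 5) first in its region
with a summed score-change of 17.7.

A CLI mirrors the library: `ovfield simulate --preset default`,
`ovfield expression counts.tsv`, and `ovfield run` for the full pipeline;
shared flags `--config` (YAML threshold overrides), `--seed`, `--outdir`.

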