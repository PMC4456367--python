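# armcna

Allele-specific somatic copy-number calling, whole-arm/focal alteration
classification, chromosomal-instability (CIN) profiling, expression-based
consensus subtyping and outcome statistics — the integrated workflow used to
contrast ovarian clear-cell carcinomas (few, mostly whole-arm copy-number
alterations) with high-grade serous carcinomas (many, mostly focal ones that
preferentially delete tumor suppressors such as *TP53*, *NF1*, *BRCA1*,
*RB1* and *BRCA2*).

The package is aimed at analysts working with paired tumor/normal SNP-array
signal tables and companion expression arrays, and at method developers who
need a fully synthetic, ground-truthed test bed for arm-level CNA analysis.
Every stage runs on the bundled cohort simulator, so nothing needs to be
downloaded.

## The core methods

**Allele-specific calling.** For SNP *i* and allele *a*, the relative ratio
is r_ia = T_ia / N_ia (tumor over paired-normal intensity; with replicate
probes, each side is summarized by the median after dropping one maximum and
one minimum). On this scale 0, 1 and 2 copies of an allele map to ratios
0.5, 1.0 and 1.5, attenuated toward 1 by stromal admixture:
E[r] = (1 − φ)·1 + φ·(1 + c)/2 for tumor purity φ. After a running-median
smooth along the genome, r > 1.3 calls an allele gained (1.6 copies) and
r < 0.7 lost (0.4 copies), both strict; runs of a constant per-allele state
pair become segments, categorised as

| A-state, B-state | category |
|---|---|
| loss, loss | homozygous deletion |
| loss, gain (either order) | copy-number-neutral LOH |
| one loss, other neutral | hemizygous loss |
| any gain, no loss | gain |

A segment whose probe span covers > 98% of its arm's probe span is a
**whole-arm** alteration, otherwise **focal**; each altered (sample, arm)
pair counts as one event, and a tumor is CIN-high (≥ 9 altered arms),
CIN-low (1–8) or CIN-negative (0).

**Expression subtyping.** Arrays are scaled to mean signal 100, probes kept
with max ≥ 100, mean ≥ 10 and CV ≥ 0.3, and samples subtyped by consensus
k-means: for each candidate k, many k-means runs on random 3000-gene
subsets; the consensus matrix C_ij (fraction of runs co-clustering samples
i and j) is cut by average-linkage hierarchical clustering, and the k whose
consensus matrix has the lowest rank-k NMF reconstruction error is chosen.

**Association statistics.** Two-sided Fisher exact tests (point-probability
rule), Kaplan–Meier / log-rank comparisons and Cox proportional-hazards
models (Efron ties) link subtypes to stage, chemoresponse and
progression-free survival.

## Worked example

`examples/` holds one short script per capability. For instance,
`python examples/03_cin_profiles.py` simulates 10 clear-cell-like and 10
serous-like tumors, calls CNAs at purity 0.8 / noise 0.1 and prints:

```
cin_class  high  low
histology
CCC-like      2    8
SC-like      10    0

whole-arm ratio: CCC-like 47.1%, SC-like 27.3% (Fisher p = 0.003)

Among SC-like tumors with BRCA1 LOH:
  100% also have TP53 LOH (6/6)
  100% also have NF1 LOH (6/6)
```

The serous-like archetype is called CIN-high throughout (many altered
arms), the clear-cell-like archetype mostly CIN-low; the recovered
whole-arm ratios match the planted 0.47 vs 0.22 regimes; and the planted
joint 17p/17q/13q loss shows up as perfectly co-occurring tumor-suppressor
LOH. `examples/04_expression_subtyping.py` recovers a planted 3-cluster
expression structure (chosen k = 3, ARI = 1.00), and
`examples/05_survival.py` recovers a planted protective hazard multiplier
of 0.2 as HR 0.20 [0.09, 0.48].

The full pipeline is one call (or `armcna run-all --seed 1 --out out/`
from the shell):

```python
from armcna import PipelineConfig, run_pipeline
report = run_pipeline(PipelineConfig(seed=1))
```

## Layout

- `src/armcna/genome.py` — chromosome-arm model, cytoBand I/O
- `src/armcna/simulate.py` — cohort simulator (CNA truth, signals, expression, clinical)
- `src/armcna/calling.py` — allelic ratios, smoothing, segmentation, span classes
- `src/armcna/cin.py` — CIN classes, arm-event tables, TSG LOH, profile clustering
- `src/armcna/expression.py` — normalization, filtering, consensus k-means, NMF
- `src/armcna/stats.py` — Fisher exact, Kaplan–Meier/log-rank, Cox
- `src/armcna/pipeline.py`, `src/armcna/cli.py` — orchestration and thin CLI
- `docs/methods.md` — models, parameter choices and limitations
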