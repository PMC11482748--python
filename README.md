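# myosig

Discovery of hypertrophy-associated non-coding RNAs from multi-cohort bulk
skeletal-muscle transcriptomes.

Resistance training grows muscle in some people and not measurably in
others, and the non-coding side of the transcriptome (lncRNAs, miscRNAs,
pseudogenes) is poorly captured by standard short-read workflows. `myosig`
implements, as a tested and reusable pipeline, the statistical machinery
for finding ncRNA genes linked to muscle growth across several independent
training studies:

1. **Responder phenotyping.** Each participant's percent change in leg lean
   mass, %ΔLLM = 100·(post − pre)/pre, is compared against the measurement
   instrument's technical precision: ≥ 2.5% → lean-mass responder (LMR),
   < 2.0% → no measurable response (NMLMR), the precision band [2.0, 2.5)
   is indeterminate (kept for linear modelling, excluded from group
   contrasts).
2. **Paired SAM differential expression.** Per gene, the moderated
   statistic d = mean(z) / (se(z) + s₀) on paired post-minus-pre log₂
   changes z, with the fudge factor s₀ stabilising low-variance genes.
   False-discovery rates come from sign-flip permutations:
   q = median over permutations of #{|d*| ≥ |d|} · π₀ / #{|d| observed ≥ |d|},
   monotonized in |d|. Calls require q < 0.05 and a signed fold change
   |FC| ≥ 1.2 (FC = sign(m)·2^|m|).
3. **Divergence heuristics.** A gene significant in exactly one responder
   group is group-unique when fold changes point in opposite directions or
   the between-group fold ratio is ≥ 1.2.
4. **Linear meta-filter.** Per study, Pearson r between Δexpression and
   %ΔLLM; p-values of the three largest cohorts pooled by Stouffer's
   signed-z method (Z = Σ zᵢ/√k). A gene passes when median |r| ≥ 0.2
   across studies, ≥ 4 of 5 studies agree in direction, and
   Benjamini–Hochberg FDR < 10% over the pooled p of filter passers.
5. **Signature assembly.** The union of the two group-unique lists and the
   linear set, restricted to ncRNA biotypes, with a full evidence trail
   per gene.
6. **Cell-type guilt-by-association.** On a large baseline panel, genes are
   correlated against curated markers of muscle cell populations (fibre
   types, satellite, endothelial, pericyte, immune) and assigned to the
   best-scoring type.
7. **Module enrichment.** Hypergeometric over-representation of
   co-expression modules against GMT gene sets over an expressed-gene
   background, with fold enrichment FE = (k/n)/(K/N), per-module BH
   correction, module selection rules and a cross-module term-overlap map.

A probe-level sub-pipeline (unique-mapping filter, n > 3 probe-set rule,
signal×CV QC conjunction, median summarization, quantile normalization)
rebuilds gene-level matrices from array probe data when tabular alignment
records and intensities are supplied.

Every stage is exercised end-to-end on a **synthetic-data generator** that
emulates the study design — five cohorts of 32/33/47/20/12 subjects, paired
profiles, a two-component %ΔLLM distribution, planted group-specific and
linear-association genes, and baseline profiles mixed from cell-type
signatures — so sensitivity, specificity and calibration can be verified
against known ground truth.

## Worked example

```python
from myosig import SimulationConfig
from myosig.evaluate import run_signature_workflow, score_against_truth

run = run_signature_workflow(SimulationConfig(seed=1))
print(run.labelled["label"].value_counts().to_dict())
print("unique LMR:", len(run.unique_lmr),
      "| unique NMLMR:", len(run.unique_nmlmr),
      "| linear:", len(run.linear),
      "| signature:", len(run.signature))
print(score_against_truth(run))
```

prints

```
{'LMR': 88, 'NMLMR': 50, 'INDETERMINATE': 6}
unique LMR: 50 | unique NMLMR: 15 | linear: 213 | signature: 214
{'sensitivity_lmr_de': 1.0, 'sensitivity_nmlmr_de': 1.0,
 'sensitivity_linear': 0.8913..., 'null_contamination': 0.00478...,
 'n_signature': 214.0}
```

Of 144 simulated participants, 88 are responders and 50 non-responders;
all 50 planted LMR-specific genes and 15 NMLMR-specific genes survive the
paired SAM + divergence filters, 41 of the 46 planted linear-association
genes pass the meta-filter (which also legitimately admits the strongly
shifted DE genes, hence 213 linear calls), and under 0.5% of unplanted
genes leak into the final signature.

The same run is available from a shell, stage by stage or end to end,
with every table written as TSV plus a JSON run manifest:

```bash
myosig run-all --out runs/demo --seed 1
```

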