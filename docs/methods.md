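# Methods

## Study design being emulated

The pipeline targets multi-cohort supervised-training studies of skeletal
muscle: five independent cohorts (default sizes 32, 33, 47, 20 and 12
subjects; four DXA, one MRI), each participant profiled before and after
training. Hypertrophy is defined against instrument precision rather than
any biological threshold: DXA-derived leg-lean-mass changes are only
trustworthy beyond roughly 2.0–2.4%, so ≥ 2.5% is called a response
(LMR), < 2.0% no measurable response (NMLMR), and the band between is
indeterminate. Both modalities use the same group cut-offs; the MRI
precision figure (2.3%) is carried as metadata only, and the indeterminate
band for MRI defaults to the same [2.0, 2.5) interval (configurable),
since only one pair of group cut-offs is defined. Indeterminate subjects
are excluded from group contrasts but retained for the linear analysis.

## Differential expression: moderated statistic + permutation FDR

For paired data, the per-gene statistic is d = mean(z)/(se(z) + s₀) on
subject-level post-minus-pre log₂ changes z. The fudge factor s₀ defaults
to the median of the per-gene standard errors — the simple, reproducible
choice — with the percentile-search rule (minimizing the coefficient of
variation of the spread of d across standard-error windows) available
behind `s0_rule="tusher"`.

The null is built by sign-flipping each subject's z vector (valid under
exchangeability of pre/post within subject); unpaired contrasts permute
group labels instead. For a symmetric threshold at a gene's |d|,

    q = median over permutations of #{|d*| ≥ |d|} × π₀
        ------------------------------------------------
                       #{observed |d| ≥ |d|}

with π₀ = min(1, 2 × fraction of observed d inside the interquartile
range of the pooled permuted d), and q monotonized to be non-increasing
in |d| (cumulative minimum from the least significant gene upward) and
clipped to [0, 1]. Significance requires q below the FDR cut-off
(default 5%) *and* |FC| ≥ 1.2, where FC = sign(m)·2^|m| on the mean log₂
difference m — so down-regulation is a negative fold and the magnitude
cut reads directly. Fold changes are computed on mean log-differences,
not anti-logged group means (flagged in output metadata).

Numerical details worth knowing:

* When 2ⁿ ≤ the requested permutation count the sign-flip space is
  enumerated exhaustively instead of sampled (the convention of the
  reference SAM implementation). This removes all Monte-Carlo error for
  small groups; a sampled median-of-counts estimator has irreducible
  granularity of half a null count — q can hop by 0.5/count_obs when the
  null median lands on a half-integer — so enumeration is strictly
  better whenever affordable.
* Permutation counts are configurable and seeded; 10⁴ matches full-scale
  practice, 10³ is the pipeline default at fixture scale.
* A zero denominator (se + s₀ = 0, only possible at s₀ = 0 with a
  constant gene) yields d = 0 rather than a non-number.

## Divergence heuristics

Genes significant in exactly one responder group are considered
group-unique only when the groups genuinely diverge: fold changes of
opposite sign, or a between-group ratio of fold magnitudes ≥ 1.2. Genes
significant in both groups are excluded from both unique lists (logged;
configurable, since the treatment of opposite-direction double calls is a
judgment call).

## Linear meta-filter

Per study, Pearson r between per-subject Δexpression and %ΔLLM, with
two-sided p from the exact null beta distribution of r (equivalent to the
single-covariate ANOVA F-test, which is why no general linear-model
engine exists here). Studies with fewer than 3 subjects are skipped with
a warning. P-values from the three largest cohorts are pooled with
unweighted signed Stouffer: zᵢ = Φ⁻¹(1 − pᵢ/2)·sign(rᵢ), Z = Σzᵢ/√k —
genes missing a designated study contribute nothing and √k shrinks
accordingly; p = 0 is clamped to the smallest positive double and logged.
A gene passes when (1) the median of |r| over available studies is
≥ 0.2, (2) at least 4 of 5 studies share the sign of r, and (3) its
Benjamini–Hochberg FDR, computed over the pooled p-values of the genes
passing (1) and (2) only, is < 10%. Genes with records in fewer than 4
studies are excluded and logged. BH is the assumed FDR procedure for
this branch (labelled in outputs).

A property of this published recipe to be aware of: because BH runs on
p-values *pre-selected* by the |r| filters, and the pooled cohorts are a
subset of the filtering cohorts, null genes that survive filters 1–2 have
pooled p biased small — so the realized false rate among linear calls
exceeds the nominal 10%. On the default fixture this contributes roughly
half a percent of the null-gene pool to the signature (about 1% when
counting only ncRNA nulls, the genes actually eligible). The filter
sequence is implemented as published; tightening it is a user decision.

## Signature assembly

The signature is the union of the two DE-unique lists and the linear set,
restricted to ncRNA biotypes; genes reached by several routes carry all
sources (the analysis keeps, e.g., a gene both LMR-differentially
expressed and linearly associated as a single record with both tags).

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions above.

* **Gene universe**: 22 868 genes (13 249 protein-coding, 7 173 lncRNA,
  1 192 miscRNA, 1 254 pseudogene — the post-filter biotype census of the
  emulated platform), assigned by largest remainder and shuffled.
* **Phenotype**: %ΔLLM is a two-component truncated normal — responders
  N(6.6, 3.9²) truncated above 2.5, non-responders N(−0.6, 1.8²)
  truncated below 2.0 — so latent labels and threshold classification
  agree exactly; a configurable count of gray-zone subjects (default 6)
  is drawn uniformly on [2.0, 2.5). Truncation shifts the realized group
  moments slightly above the nominal means (≈ +7.7% and −1.2%); the
  nominal parameters are the group summaries being emulated. Class
  labels are allocated to studies by a seeded shuffle (88/50/6 by
  default). Subjects, not legs, are the experimental unit.
* **Expression**: pre = μ_g + a_ig + e, post = μ_g + a_ig + e′ + effect,
  with gene means μ ~ N(7, 1.5²) log₂ units, a subject random effect
  giving intraclass correlation 0.5 between pre and post (the
  within-subject correlation is not identified by the emulated study, so
  it is exposed as a knob), and total per-measurement noise sd 0.35 log₂
  units. Planted group-DE genes (50 LMR-unique, 15 NMLMR-unique) shift
  by +0.5 log₂ post-training in their group only. Planted linear genes
  (46, exactly 1 shared with the LMR set) add β·%ΔLLM to the post
  profile with β = (r/√(1−r²))·σ_Δ/σ_pct solved in closed form so the
  population per-gene r hits the target 0.3 — auditable by direct
  recomputation on the emitted matrix.
* **Baseline mixture panel**: 437 samples with Dirichlet cell-type
  fractions (concentration 30) around a realistic muscle composition
  (fibre types ≈ 80%, endothelium 8%, satellite 4%, pericytes 3%, immune
  5%). A gene in cell type c's signature reads
  base_g + 1.5·(f_c/mean_c) + noise (sd 0.1), i.e. signal tracks the
  fold-deviation of that population's abundance, which keeps rare
  populations as recoverable as abundant ones. Markers from the curated
  panel are hosted by protein-coding genes and belong to exactly one
  signature.
* **Modules and gene sets** for the enrichment stage are synthetic
  stand-ins (one module per cell type seeded with its signature genes, a
  protein-coding core shared with a matching GMT term, plus null terms),
  generated so the selection rules have something real to select.

What the fixtures do **not** emulate: probe-level physics beyond what the
probe sub-pipeline needs, sequence content, between-study batch effects,
heavy-tailed or count-based noise, correlated null genes, and any real
ontology structure. Passing tests therefore demonstrate the statistical
machinery is correct and calibrated under the declared generative model,
not that the biological conclusions of any particular dataset transfer.

## Probe sub-pipeline

Probes are 25-mers re-aligned externally; records arrive as
(probe_id, transcript_id, n_hits). Only uniquely mapping probes
(n_hits = 1) are kept; probe-sets need more than 3 probes ("n > 3" read
strictly as ≥ 4); QC removes a probe only when its median linear-scale
signal is below the signal floor *and* its CV (sd/mean, linear scale) is
below the CV floor — the conjunction matters, as dim-but-variable probes
may track genuine low-abundance transcripts. No numeric QC defaults are
shipped: thresholds are mandatory configuration. Summarization is the
median of member-probe log₂ intensities; the cross-sample normalizer is
pluggable with quantile normalization as the default (the iterative
rank-order scheme used at full scale lives in its own publication and is
out of scope; at fixture scale the normalizer choice is immaterial). The
reference sample (closest to the all-sample median distribution) is
logged. GC correction of vendor binaries is likewise out of scope; inputs
are background-corrected intensities.

## Cell typing and modules

Marker panel (fixed defaults): type I fibres MYH7, TNNT1; type II fibres
MYH1, MYH2, ATP2A1, TNNT3; satellite PAX7, MYF5; endothelial ENG, TIE1,
PECAM1, APLNR; pericytes RGS5, HIGD1B; macrophages F13A1, SPP1; T cells
CD3D, IL7R; B cells MS4A1, CD79A. A gene's score per type is the *mean*
r over that type's markers (robust to one noisy marker; configurable);
assignment goes to the arg-max type provided the score reaches r_min
(default 0.3) and every marker of that type has BH q ≤ q_max (default
0.05) — there is no published numeric threshold for "associated", so
both are explicit configuration. Exact ties are left unassigned and
logged. Module detection itself is consumed as input (module TSV), never
computed: multiscale network construction is an independent published
method far outside desk scale. Hubs are module genes ranked by degree in
the graph of within-module pairs with correlation BH-q < 1% (top 5%,
minimum one, and none when the module has no edges).

## Enrichment

Plain upper-tail hypergeometric over-representation (not the EASE-score
variant) of module gene lists against GMT terms over an expressed
protein-coding background; module genes outside the background are
dropped from n with a log entry, terms empty after intersection are
skipped. BH runs within module across terms, mirroring per-list runs of
the usual web tools. ncRNAs absent from ontologies simply reduce n.
Module selection: ≥ 1 signature gene, size < 500, and ≥ 1 term at
q ≤ 5×10⁻⁵. The overlap map lists, for every term at q ≤ 1% in at least
one selected module, the contributing modules with their k counts, plus
the Jaccard overlap of enriched-term sets per module pair.

## Problem sizes and runtime

The default fixture (22 868 genes × 288 paired profiles, 10³
permutations) runs one full signature workflow in roughly ten seconds on
one CPU; calibration and recovery properties in the test suite use 10–20
seeds at these sizes. The permutation engine computes all sign-flip
nulls with one matrix product per batch (Σz² is sign-invariant, so only
permuted means are recomputed) and counts exceedances by binary search
on sorted null statistics.
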