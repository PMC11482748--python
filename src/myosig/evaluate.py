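"""In-memory signature workflow and ground-truth scoring.

Convenience layer over the library used for benchmarking the pipeline on
synthetic fixtures: generates a cohort, runs classification, both paired
SAM contrasts, the divergence and linear meta-filters, and scores the
assembled signature against the planted truth — without touching disk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import PairedExpressionSet
from .phenotyping import LMR, NMLMR, Thresholds, classify_table
from .sam import SamParameters, paired_sam
from .signature import (
    LinearFilterParameters,
    assemble_signature,
    divergence_filter,
    linear_filter,
    per_study_association,
    pool_by_gene,
)
from .synthetic import (
    NCRNA_BIOTYPES,
    GroundTruth,
    SimulationConfig,
    generate_annotation,
    generate_cohorts,
    generate_expression,
)


@dataclass
class SignatureRun:
    """Outputs of one synthetic end-to-end signature run."""

    labelled: pd.DataFrame
    de_lmr: pd.DataFrame
    de_nmlmr: pd.DataFrame
    unique_lmr: set[str]
    unique_nmlmr: set[str]
    linear: pd.DataFrame
    signature: pd.DataFrame
    truth: GroundTruth
    annotation: pd.DataFrame


def run_signature_workflow(
    config: SimulationConfig,
    sam_params: SamParameters | None = None,
    linear_params: LinearFilterParameters | None = None,
    thresholds: Thresholds | None = None,
) -> SignatureRun:
    """Generate a synthetic multi-study fixture and run it to a signature."""
    sam_params = sam_params or SamParameters(
        n_permutations=1000, seed=config.seed
    )
    linear_params = linear_params or LinearFilterParameters()
    annotation = generate_annotation(config)
    cohorts, true_labels = generate_cohorts(config)
    expr, truth = generate_expression(cohorts, config, true_labels, annotation)

    labelled = classify_table(cohorts, thresholds)
    ncrna_ids = annotation.index[annotation["biotype"].isin(NCRNA_BIOTYPES)]
    nc_expr = expr.subset_genes(ncrna_ids)

    groups = {
        LMR: labelled.loc[labelled["label"] == LMR, "subject_id"].tolist(),
        NMLMR: labelled.loc[labelled["label"] == NMLMR, "subject_id"].tolist(),
    }
    de_lmr = paired_sam(nc_expr, groups[LMR], sam_params, group=LMR)
    de_nmlmr = paired_sam(nc_expr, groups[NMLMR], sam_params, group=NMLMR)
    unique_lmr, unique_nmlmr = divergence_filter(de_lmr, de_nmlmr)

    indexed = labelled.set_index("subject_id")
    delta_expr, delta_llm = {}, {}
    for study, grp in indexed.groupby("study_id"):
        delta_expr[study] = nc_expr.paired_delta(grp.index.tolist())
        delta_llm[study] = grp["pct_change"]
    assoc = per_study_association(delta_expr, delta_llm)

    pooled_studies = linear_params.pooled_studies
    if pooled_studies is None:
        sizes = indexed.groupby("study_id").size().sort_values(ascending=False)
        pooled_studies = tuple(sizes.index[:3])
    pooled = pool_by_gene(assoc, pooled_studies)
    linear = linear_filter(assoc, pooled, linear_params)
    signature = assemble_signature(unique_lmr, unique_nmlmr, linear)
    return SignatureRun(
        labelled=labelled,
        de_lmr=de_lmr,
        de_nmlmr=de_nmlmr,
        unique_lmr=unique_lmr,
        unique_nmlmr=unique_nmlmr,
        linear=linear,
        signature=signature,
        truth=truth,
        annotation=annotation,
    )


def score_against_truth(run: SignatureRun) -> dict[str, float]:
    """Sensitivity per planted set and null-gene contamination of the signature."""
    sig = set(run.signature.index)
    truth = run.truth
    lmr_called = {
        g for g in sig
        if "DE_UNIQUE_LMR" in run.signature.loc[g, "sources"]
    }
    nmlmr_called = {
        g for g in sig
        if "DE_UNIQUE_NMLMR" in run.signature.loc[g, "sources"]
    }
    linear_called = {
        g for g in sig if "LINEAR" in run.signature.loc[g, "sources"]
    }
    planted = (
        truth.planted_lmr_de | truth.planted_nmlmr_de | truth.planted_linear
    )
    null_genes = set(run.annotation.index) - planted
    return {
        "sensitivity_lmr_de": (
            len(lmr_called & truth.planted_lmr_de) / len(truth.planted_lmr_de)
        ),
        "sensitivity_nmlmr_de": (
            len(nmlmr_called & truth.planted_nmlmr_de) / len(truth.planted_nmlmr_de)
        ),
        "sensitivity_linear": (
            len(linear_called & truth.planted_linear) / len(truth.planted_linear)
        ),
        "null_contamination": len(sig & null_genes) / len(null_genes),
        "n_signature": float(len(sig)),
    }


def null_fdr_proportion(
    seed: int,
    n_genes: int = 1000,
    n_subjects: int = 20,
    n_permutations: int = 1000,
    fdr_cutoff: float = 0.05,
) -> float:
    """Proportion of all-null genes called at q < cutoff in one paired run."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 97]))
    subjects = [f"s{i}" for i in range(n_subjects)]
    sample_ids = [f"{s}_pre" for s in subjects] + [f"{s}_post" for s in subjects]
    values = pd.DataFrame(
        rng.normal(7.0, 1.0, size=(n_genes, 2 * n_subjects)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=sample_ids,
    )
    samples = pd.DataFrame(
        {
            "subject_id": subjects * 2,
            "timepoint": ["pre"] * n_subjects + ["post"] * n_subjects,
        },
        index=sample_ids,
    )
    expr = PairedExpressionSet(values, samples)
    de = paired_sam(
        expr,
        subjects,
        SamParameters(n_permutations=n_permutations, seed=seed),
    )
    return float((de["q_value"] < fdr_cutoff).mean())
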