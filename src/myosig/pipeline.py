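"""End-to-end orchestration of the discovery pipeline with a run manifest.

Stage order: simulate (optional) -> classify -> probes (optional) -> de ->
signature -> celltype -> enrich. Every stage reads and writes declared
files inside the run directory, so any stage can be re-run in isolation;
the manifest records parameters, seeds and per-stage row counts, and a
failing stage leaves earlier outputs plus a manifest entry naming the
stage and cause.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .celltype import (
    MarkerPanel,
    assign_cell_types,
    hub_genes,
    marker_correlations,
    module_biotype_composition,
)
from .containers import PairedExpressionSet
from .enrichment import (
    enrich_modules,
    enrichment_overlap_map,
    read_gmt,
    select_modules,
)
from .phenotyping import (
    LMR,
    NMLMR,
    Thresholds,
    baseline_association,
    classify_table,
    summarize_groups,
)
from .probes import (
    ProbeQCThresholds,
    build_probesets,
    filter_probes_signal_cv,
    filter_unique_mappings,
    summarize_and_normalize,
)
from .sam import SamParameters, paired_sam, unpaired_sam
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
    SimulationConfig,
    generate_annotation,
    generate_cohorts,
    generate_expression,
    generate_marker_mixture,
    generate_modules_and_genesets,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Aggregated stage parameters; defaults are the printed thresholds.

    Probe-QC thresholds deliberately have no defaults: the probes stage
    refuses to run without them.
    """

    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    sam: SamParameters = field(default_factory=lambda: SamParameters(n_permutations=1000))
    linear: LinearFilterParameters = field(default_factory=LinearFilterParameters)
    celltype_r_min: float = 0.3
    celltype_q_max: float = 0.05
    module_size_max: int = 500
    term_q_max: float = 5.0e-5
    overlap_q: float = 0.01
    probe_signal_floor: float | None = None
    probe_cv_floor: float | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {
            "seed", "simulation", "thresholds", "sam", "linear",
            "celltype_r_min", "celltype_q_max", "module_size_max",
            "term_q_max", "overlap_q", "probe_signal_floor", "probe_cv_floor",
        }
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "simulation" in kwargs:
            sim = dict(kwargs["simulation"])
            for key in ("study_sizes", "modality_per_study"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            kwargs["simulation"] = SimulationConfig(**sim)
        if "thresholds" in kwargs:
            kwargs["thresholds"] = Thresholds(**kwargs["thresholds"])
        if "sam" in kwargs:
            kwargs["sam"] = SamParameters(**kwargs["sam"])
        if "linear" in kwargs:
            lin = dict(kwargs["linear"])
            if lin.get("pooled_studies") is not None:
                lin["pooled_studies"] = tuple(lin["pooled_studies"])
            kwargs["linear"] = LinearFilterParameters(**lin)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


class Manifest:
    """Incrementally written record of a pipeline run."""

    def __init__(self, run_dir: Path, config: PipelineConfig):
        self.path = run_dir / "manifest.json"
        self.payload: dict = {"config": config.to_dict(), "stages": []}
        self._flush()

    def _flush(self) -> None:
        self.path.write_text(json.dumps(self.payload, indent=1, default=str))

    def record(self, stage: str, status: str, **info) -> None:
        self.payload["stages"].append({"stage": stage, "status": status, **info})
        self._flush()


def _run_stage(manifest: Manifest, stage: str, fn):
    try:
        info = fn() or {}
    except Exception as exc:  # noqa: BLE001 - manifest must name the cause
        manifest.record(stage, "failed", error=f"{type(exc).__name__}: {exc}")
        raise
    manifest.record(stage, "completed", **info)
    return info


def stage_simulate(config: PipelineConfig, run_dir: Path) -> dict:
    sim = config.simulation.with_seed(config.seed)
    annotation = generate_annotation(sim)
    cohorts, true_labels = generate_cohorts(sim)
    expr, truth = generate_expression(cohorts, sim, true_labels, annotation)
    mixture, signatures = generate_marker_mixture(sim, annotation)
    truth.cell_signature_genes = signatures
    modules, gene_sets, background = generate_modules_and_genesets(
        sim, annotation, signatures, truth.planted_lmr_de
    )
    io.write_phenotypes(cohorts, run_dir / "phenotypes.csv")
    io.write_expression_set(
        expr, run_dir / "expression.tsv", run_dir / "samples.tsv",
        run_dir / "annotation.tsv",
    )
    io.write_matrix(mixture, run_dir / "mixture.tsv")
    io.write_ground_truth(truth, run_dir / "ground_truth.json")
    io.write_marker_panel(MarkerPanel().markers, run_dir / "marker_panel.json")
    io.write_modules(modules, run_dir / "modules.tsv")
    io.write_gmt(gene_sets, run_dir / "gene_sets.gmt")
    io.write_background(background, run_dir / "background.txt")
    return {"n_subjects": len(cohorts), "n_genes": expr.values.shape[0]}


def stage_classify(config: PipelineConfig, run_dir: Path) -> dict:
    phenotypes = io.read_phenotypes(run_dir / "phenotypes.csv")
    labelled = classify_table(phenotypes, config.thresholds)
    io.write_phenotypes(labelled, run_dir / "labelled_phenotypes.csv")
    summary = summarize_groups(labelled)
    r, p = baseline_association(labelled)
    io.write_json(
        {
            "groups": summary.reset_index().to_dict(orient="records"),
            "baseline_vs_change_r": r,
            "baseline_vs_change_p": p,
        },
        run_dir / "group_summary.json",
    )
    return {"n_participants": len(labelled),
            "n_lmr": int((labelled["label"] == LMR).sum()),
            "n_nmlmr": int((labelled["label"] == NMLMR).sum())}


def stage_probes(config: PipelineConfig, run_dir: Path) -> dict:
    if config.probe_signal_floor is None or config.probe_cv_floor is None:
        raise ValueError("probe QC thresholds must be configured explicitly")
    alignments = pd.read_csv(run_dir / "probe_alignments.tsv", sep="\t")
    intensities = io.read_matrix(run_dir / "probe_intensities.tsv")
    unique = filter_unique_mappings(alignments)
    probesets = build_probesets(unique)
    retained = filter_probes_signal_cv(
        intensities,
        ProbeQCThresholds(config.probe_signal_floor, config.probe_cv_floor),
    )
    matrix = summarize_and_normalize(intensities, probesets, retained)
    pd.DataFrame(
        {
            "transcript_id": list(probesets),
            "probe_ids": [",".join(v) for v in probesets.values()],
        }
    ).to_csv(run_dir / "probesets.tsv", sep="\t", index=False)
    io.write_matrix(matrix, run_dir / "probe_level_matrix.tsv")
    return {"n_probesets": len(probesets), "n_output_rows": matrix.shape[0]}


def _load_expression(run_dir: Path) -> PairedExpressionSet:
    return io.read_expression_set(
        run_dir / "expression.tsv", run_dir / "samples.tsv", run_dir / "annotation.tsv"
    )


def _ncrna_subset(expr: PairedExpressionSet) -> PairedExpressionSet:
    ncrna = expr.genes.index[expr.genes["biotype"].isin(NCRNA_BIOTYPES)]
    return expr.subset_genes(ncrna)


def stage_de(config: PipelineConfig, run_dir: Path) -> dict:
    expr = _ncrna_subset(_load_expression(run_dir))
    labelled = io.read_phenotypes(run_dir / "labelled_phenotypes.csv")
    params = config.sam
    groups = {
        LMR: labelled.loc[labelled["label"] == LMR, "subject_id"].tolist(),
        NMLMR: labelled.loc[labelled["label"] == NMLMR, "subject_id"].tolist(),
    }
    counts = {}
    for group, subjects in groups.items():
        de = paired_sam(expr, subjects, params, group=group)
        de.to_csv(run_dir / f"de_{group.lower()}.tsv", sep="\t")
        counts[f"n_significant_{group.lower()}"] = int(de["significant"].sum())
    # baseline contrast on pre-training samples only
    pre = expr.samples[expr.samples["timepoint"] == "pre"]
    subj_label = dict(zip(labelled["subject_id"], labelled["label"]))
    keep = pre.index[[subj_label[s] in (LMR, NMLMR) for s in pre["subject_id"]]]
    labels = pd.Series(
        [subj_label[pre.loc[s, "subject_id"]] for s in keep], index=keep
    )
    de_base = unpaired_sam(expr.values[list(keep)], labels, params,
                           group_a=LMR, group_b=NMLMR)
    de_base.to_csv(run_dir / "de_baseline.tsv", sep="\t")
    counts["n_significant_baseline"] = int(de_base["significant"].sum())
    return counts


def stage_signature(config: PipelineConfig, run_dir: Path) -> dict:
    expr = _ncrna_subset(_load_expression(run_dir))
    labelled = io.read_phenotypes(run_dir / "labelled_phenotypes.csv")
    de_lmr = pd.read_csv(run_dir / "de_lmr.tsv", sep="\t", index_col=0)
    de_nmlmr = pd.read_csv(run_dir / "de_nmlmr.tsv", sep="\t", index_col=0)
    unique_lmr, unique_nmlmr = divergence_filter(de_lmr, de_nmlmr)

    labelled = labelled.set_index("subject_id")
    delta_expr, delta_llm = {}, {}
    for study, grp in labelled.groupby("study_id"):
        subjects = grp.index.tolist()
        delta_expr[study] = expr.paired_delta(subjects)
        delta_llm[study] = grp["pct_change"]
    assoc = per_study_association(delta_expr, delta_llm)

    pooled_studies = config.linear.pooled_studies
    if pooled_studies is None:
        sizes = labelled.groupby("study_id").size().sort_values(ascending=False)
        pooled_studies = tuple(sizes.index[:3])
    pooled = pool_by_gene(assoc, pooled_studies)
    linear = linear_filter(assoc, pooled, config.linear)

    signature = assemble_signature(unique_lmr, unique_nmlmr, linear, assoc)
    signature.to_csv(run_dir / "signature.tsv", sep="\t")
    io.write_json(
        {
            "n_unique_lmr": len(unique_lmr),
            "n_unique_nmlmr": len(unique_nmlmr),
            "n_linear": int(len(linear)),
            "n_signature": int(len(signature)),
            "pooled_studies": list(pooled_studies),
        },
        run_dir / "signature_evidence.json",
    )
    return {"n_signature": int(len(signature)),
            "n_unique_lmr": len(unique_lmr),
            "n_unique_nmlmr": len(unique_nmlmr),
            "n_linear": int(len(linear))}


def stage_celltype(config: PipelineConfig, run_dir: Path) -> dict:
    mixture = io.read_matrix(run_dir / "mixture.tsv")
    annotation = io.read_annotation(run_dir / "annotation.tsv")
    panel = MarkerPanel(io.read_marker_panel(run_dir / "marker_panel.json"))
    corr = marker_correlations(mixture, panel, annotation)
    corr.to_csv(run_dir / "marker_correlations.tsv", sep="\t", index=False)
    assignments = assign_cell_types(corr, config.celltype_q_max, config.celltype_r_min)
    assignments.to_frame().to_csv(run_dir / "cell_assignments.tsv", sep="\t")

    modules = io.read_modules(run_dir / "modules.tsv")
    comp_rows, hub_rows = [], []
    for mid, genes in sorted(modules.items()):
        comp = module_biotype_composition(genes, annotation).reset_index()
        comp.insert(0, "module_id", mid)
        comp_rows.append(comp)
        hubs = hub_genes(mixture, sorted(genes)).reset_index()
        hubs.insert(0, "module_id", mid)
        hub_rows.append(hubs)
    pd.concat(comp_rows).to_csv(run_dir / "module_composition.tsv", sep="\t", index=False)
    pd.concat(hub_rows).to_csv(run_dir / "module_hubs.tsv", sep="\t", index=False)
    n_assigned = int((assignments != "unassigned").sum())
    return {"n_genes_assigned": n_assigned, "n_modules": len(modules)}


def stage_enrich(config: PipelineConfig, run_dir: Path) -> dict:
    modules = io.read_modules(run_dir / "modules.tsv")
    gene_sets = read_gmt(run_dir / "gene_sets.gmt")
    background = io.read_background(run_dir / "background.txt")
    signature = pd.read_csv(run_dir / "signature.tsv", sep="\t", index_col=0)
    results = enrich_modules(modules, gene_sets, background)
    results.to_csv(run_dir / "enrichment.tsv", sep="\t", index=False)
    selected = select_modules(
        modules, results, set(signature.index),
        size_max=config.module_size_max, term_q_max=config.term_q_max,
    )
    io.write_json({"selected_modules": selected}, run_dir / "selected_modules.json")
    if len(selected) >= 2:
        term_table, jaccard = enrichment_overlap_map(results, selected, config.overlap_q)
        term_table.to_csv(run_dir / "overlap_terms.tsv", sep="\t", index=False)
        jaccard.to_csv(run_dir / "overlap_jaccard.tsv", sep="\t", index=False)
    return {"n_modules_selected": len(selected), "n_tests": int(len(results))}


STAGES = {
    "simulate": stage_simulate,
    "classify": stage_classify,
    "probes": stage_probes,
    "de": stage_de,
    "signature": stage_signature,
    "celltype": stage_celltype,
    "enrich": stage_enrich,
}

DEFAULT_ORDER = ("simulate", "classify", "de", "signature", "celltype", "enrich")


def run_pipeline(
    config: PipelineConfig,
    run_dir,
    stages: tuple[str, ...] = DEFAULT_ORDER,
) -> Path:
    """Execute the configured stages into ``run_dir``; returns the manifest path."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(run_dir, config)
    for stage in stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        logger.info("running stage %s", stage)
        _run_stage(manifest, stage, lambda s=stage: STAGES[s](config, run_dir))
    return manifest.path
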