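"""Readers and writers for the pipeline's on-disk formats.

All tables are TSV with header rows (phenotypes are CSV); matrices carry
genes in rows and samples in columns as log2 values; gene sets use the
standard GMT layout; ground truth and reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .containers import PairedExpressionSet
from .synthetic import GroundTruth


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_sample_metadata(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t")


def read_sample_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t")


def read_annotation(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression_set(expr: PairedExpressionSet, matrix_path, samples_path,
                         annotation_path=None) -> None:
    write_matrix(expr.values, matrix_path)
    write_sample_metadata(expr.samples, samples_path)
    if annotation_path is not None:
        write_annotation(expr.genes, annotation_path)


def read_expression_set(matrix_path, samples_path, annotation_path=None) -> PairedExpressionSet:
    values = read_matrix(matrix_path)
    samples = read_sample_metadata(samples_path)
    genes = read_annotation(annotation_path) if annotation_path else None
    return PairedExpressionSet(values, samples, genes)


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "planted_lmr_de": sorted(truth.planted_lmr_de),
        "planted_nmlmr_de": sorted(truth.planted_nmlmr_de),
        "planted_linear": sorted(truth.planted_linear),
        "true_labels": truth.true_labels,
        "cell_signature_genes": {
            k: sorted(v) for k, v in truth.cell_signature_genes.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        planted_lmr_de=set(payload["planted_lmr_de"]),
        planted_nmlmr_de=set(payload["planted_nmlmr_de"]),
        planted_linear=set(payload["planted_linear"]),
        true_labels=payload["true_labels"],
        cell_signature_genes={
            k: set(v) for k, v in payload["cell_signature_genes"].items()
        },
    )


def write_marker_panel(markers: dict[str, tuple[str, ...]], path) -> None:
    Path(path).write_text(
        json.dumps({k: list(v) for k, v in markers.items()}, indent=1, sort_keys=True)
    )


def read_marker_panel(path) -> dict[str, tuple[str, ...]]:
    payload = json.loads(Path(path).read_text())
    return {k: tuple(v) for k, v in payload.items()}


def write_modules(modules: dict[str, set[str]], path) -> None:
    rows = [
        {"module_id": mid, "gene_id": g, "parent_module": ""}
        for mid in sorted(modules)
        for g in sorted(modules[mid])
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_modules(path) -> dict[str, set[str]]:
    table = pd.read_csv(path, sep="\t")
    return {
        mid: set(grp["gene_id"]) for mid, grp in table.groupby("module_id")
    }


def write_gmt(gene_sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for term in sorted(gene_sets):
            fh.write("\t".join([term, term] + sorted(gene_sets[term])) + "\n")


def write_background(background, path) -> None:
    Path(path).write_text("\n".join(sorted(background)) + "\n")


def read_background(path) -> set[str]:
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}


def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True, default=str))
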