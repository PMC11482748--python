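"""Guilt-by-association cell typing of genes via marker correlations.

Bulk muscle is a mixture of large myofibres and rarer mononuclear cells;
across a large baseline panel, a gene expressed by one cell population
co-varies with that population's abundance and hence with its canonical
marker genes. Correlating each gene against a curated marker panel
(fibre types, satellite cells, endothelium, pericytes, immune cells)
lets single-cell context be read out of bulk profiles. Module-level
summaries (biotype composition, hub genes by within-module degree) use
the same baseline panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"

# Printed marker panel for human skeletal muscle cell populations.
DEFAULT_MARKERS: dict[str, tuple[str, ...]] = {
    "type_I_fibre": ("MYH7", "TNNT1"),
    "type_II_fibre": ("MYH1", "MYH2", "ATP2A1", "TNNT3"),
    "satellite": ("PAX7", "MYF5"),
    "endothelial": ("ENG", "TIE1", "PECAM1", "APLNR"),
    "pericyte": ("RGS5", "HIGD1B"),
    "macrophage": ("F13A1", "SPP1"),
    "t_cell": ("CD3D", "IL7R"),
    "b_cell": ("MS4A1", "CD79A"),
}


@dataclass(frozen=True)
class MarkerPanel:
    """Cell type -> marker gene symbols; defaults to the curated muscle panel."""

    markers: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_MARKERS.items()}
    )

    def __post_init__(self) -> None:
        for cell_type, syms in self.markers.items():
            if len(set(syms)) != len(syms):
                raise ValueError(f"duplicate markers for {cell_type}")

    def resolve(self, annotation: pd.DataFrame) -> dict[str, dict[str, str]]:
        """Map marker symbols to gene ids via the annotation table.

        Missing markers are logged, not fatal. Returns
        {cell_type: {symbol: gene_id}}.
        """
        sym_to_id = dict(zip(annotation["symbol"], annotation.index))
        resolved: dict[str, dict[str, str]] = {}
        for cell_type, syms in self.markers.items():
            hits = {s: sym_to_id[s] for s in syms if s in sym_to_id}
            for s in set(syms) - set(hits):
                logger.warning("marker %s (%s) absent from annotation", s, cell_type)
            if hits:
                resolved[cell_type] = hits
        return resolved


def _corr_and_p(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of each row of x against each row of y, with two-sided p."""
    n = x.shape[1]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    xn = np.sqrt((xc**2).sum(axis=1))
    yn = np.sqrt((yc**2).sum(axis=1))
    denom = np.outer(xn, yn)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (xc @ yc.T) / np.where(denom > 0, denom, 1.0), 0.0)
    r = np.clip(r, -1.0, 1.0)
    p = 2.0 * stats.beta.sf(np.abs(r), (n - 2) / 2.0, (n - 2) / 2.0, loc=-1, scale=2)
    return r, np.clip(p, 0.0, 1.0)


def marker_correlations(
    baseline_expr: pd.DataFrame,
    panel: MarkerPanel,
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Pearson r of every gene against every resolvable marker.

    Returns a long table (gene_id, cell_type, marker, r, q) with q by
    Benjamini-Hochberg over all pairs tested. Needs >= 10 baseline samples.
    """
    if baseline_expr.shape[1] < 10:
        raise ValueError("baseline panel needs at least 10 samples")
    resolved = panel.resolve(annotation)
    marker_rows = [
        (cell_type, sym, gid)
        for cell_type, hits in resolved.items()
        for sym, gid in hits.items()
        if gid in baseline_expr.index
    ]
    for cell_type, hits in resolved.items():
        for sym, gid in hits.items():
            if gid not in baseline_expr.index:
                logger.warning("marker %s (%s) absent from matrix; skipped", sym, cell_type)
    if not marker_rows:
        raise ValueError("no marker could be resolved in the expression matrix")
    marker_ids = [gid for _, _, gid in marker_rows]
    r, p = _corr_and_p(
        baseline_expr.to_numpy(float), baseline_expr.loc[marker_ids].to_numpy(float)
    )
    records = []
    for j, (cell_type, sym, gid) in enumerate(marker_rows):
        records.append(
            pd.DataFrame(
                {
                    "gene_id": baseline_expr.index,
                    "cell_type": cell_type,
                    "marker": sym,
                    "r": r[:, j],
                    "p": p[:, j],
                }
            )
        )
    out = pd.concat(records, ignore_index=True)
    _, q, _, _ = multipletests(out["p"], method="fdr_bh")
    out["q"] = q
    return out.drop(columns="p")


def assign_cell_types(
    correlations: pd.DataFrame,
    q_max: float = 0.05,
    r_min: float = 0.3,
) -> pd.Series:
    """Assign each gene to its best-scoring cell type, or leave unassigned.

    The score for a cell type is the mean r over its markers; the arg-max
    type wins iff its score reaches ``r_min`` and every one of its markers'
    q-values is at or below ``q_max``. Exact ties are left unassigned.
    """
    scores = correlations.pivot_table(
        index="gene_id", columns="cell_type", values="r", aggfunc="mean"
    )
    max_q = correlations.pivot_table(
        index="gene_id", columns="cell_type", values="q", aggfunc="max"
    )
    best = scores.max(axis=1)
    tied = scores.eq(best, axis=0).sum(axis=1) > 1
    n_ties = int(tied.sum())
    if n_ties:
        logger.info("%d genes with tied best scores left unassigned", n_ties)
    winner = scores.idxmax(axis=1)
    winner_q = pd.Series(
        max_q.to_numpy()[np.arange(len(max_q)),
                         max_q.columns.get_indexer(winner)],
        index=scores.index,
    )
    assigned = (~tied) & (best >= r_min) & (winner_q <= q_max)
    out = winner.where(assigned, UNASSIGNED)
    return out.rename("cell_type").rename_axis("gene_id")


def module_biotype_composition(
    module_genes, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Biotype counts and rounded percentages for one module's genes."""
    module_genes = list(module_genes)
    if not module_genes:
        raise ValueError("empty module")
    biotypes = []
    for g in module_genes:
        if g in annotation.index:
            biotypes.append(annotation.loc[g, "biotype"])
        else:
            logger.warning("gene %s unannotated; counted as 'other'", g)
            biotypes.append("other")
    counts = pd.Series(biotypes).value_counts()
    out = pd.DataFrame({"count": counts})
    out["percent"] = (100.0 * out["count"] / len(module_genes)).round(0).astype(int)
    return out.rename_axis("biotype")


def hub_genes(
    baseline_expr: pd.DataFrame,
    module_genes,
    edge_q: float = 0.01,
    top_fraction: float = 0.05,
) -> pd.DataFrame:
    """Rank module genes by within-module co-expression degree.

    Edges are gene pairs whose pairwise-correlation BH q is below
    ``edge_q``; the top ``top_fraction`` by degree (at least one gene,
    provided any edge exists) are flagged as hubs.
    """
    module_genes = [g for g in module_genes if g in baseline_expr.index]
    if len(module_genes) < 3:
        raise ValueError("hub analysis needs a module of at least 3 genes")
    x = baseline_expr.loc[module_genes].to_numpy(float)
    r, p = _corr_and_p(x, x)
    iu = np.triu_indices(len(module_genes), k=1)
    _, q, _, _ = multipletests(p[iu], method="fdr_bh")

    graph = nx.Graph()
    graph.add_nodes_from(module_genes)
    for (i, j), qv in zip(zip(*iu), q):
        if qv < edge_q:
            graph.add_edge(module_genes[i], module_genes[j])
    degree = pd.Series(dict(graph.degree()), name="degree").astype(int)
    degree = degree.sort_values(ascending=False, kind="stable")
    degree = degree.loc[sorted(degree.index, key=lambda g: (-degree[g], g))]
    n_hubs = max(1, int(np.ceil(top_fraction * len(module_genes))))
    out = degree.to_frame()
    out["hub"] = False
    if degree.iloc[0] > 0:
        cutoff = degree.iloc[n_hubs - 1]
        out.loc[(out["degree"] >= max(cutoff, 1)), "hub"] = True
    return out.rename_axis("gene_id")
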