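"""Hypergeometric over-representation of module gene lists.

Modules (co-expression clusters consumed from an external network model)
are tested against gene-set collections in GMT format, relative to a
custom background of genes actually expressed in the tissue — never the
whole genome, which would inflate enrichment. For a module with n
background-expressed genes, of which k fall in a term covering K of the N
background genes:

    fold enrichment FE = (k/n) / (K/N)
    p = P(X >= k),  X ~ Hypergeom(N, K, n)

q-values are Benjamini-Hochberg within each module across its terms,
mirroring per-list runs of the usual web tools. Only over-representation
is tested.
"""

from __future__ import annotations

import itertools
import logging

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def read_gmt(path) -> dict[str, list[str]]:
    """Load a GMT gene-set file as {term: member genes}."""
    from gseapy.parser import read_gmt as _read_gmt  # heavy import kept lazy

    return _read_gmt(str(path))


def hypergeometric_enrichment(
    module_genes,
    gene_sets: dict[str, list[str]],
    background,
    module_id: str = "module",
) -> pd.DataFrame:
    """Over-representation of one module against every term in ``gene_sets``.

    Module genes outside the background are dropped (with a log entry);
    terms empty after background intersection are skipped.
    """
    background = set(background)
    if not background:
        raise ValueError("background set is empty")
    module_genes = set(module_genes)
    in_bg = module_genes & background
    dropped = len(module_genes) - len(in_bg)
    if dropped:
        logger.info("module %s: %d genes outside background dropped", module_id, dropped)
    n = len(in_bg)
    N = len(background)
    rows = []
    for term, members in gene_sets.items():
        term_bg = set(members) & background
        K = len(term_bg)
        if K == 0:
            logger.info("term %s empty after background intersection; skipped", term)
            continue
        k = len(in_bg & term_bg)
        fe = (k / n) / (K / N) if n > 0 and k > 0 else 0.0
        p = float(hypergeom.sf(k - 1, N, K, n)) if n > 0 else 1.0
        rows.append(
            {"module_id": module_id, "term_id": term, "k": k, "n": n, "K": K,
             "N": N, "fold_enrichment": fe, "p": min(1.0, p)}
        )
    out = pd.DataFrame(
        rows, columns=["module_id", "term_id", "k", "n", "K", "N",
                       "fold_enrichment", "p"]
    )
    if len(out):
        _, q, _, _ = multipletests(out["p"], method="fdr_bh")
        out["q"] = q
    else:
        out["q"] = pd.Series(dtype=float)
    return out


def enrich_modules(
    modules: dict[str, set[str]],
    gene_sets: dict[str, list[str]],
    background,
) -> pd.DataFrame:
    """Run :func:`hypergeometric_enrichment` per module; BH stays within-module."""
    frames = [
        hypergeometric_enrichment(genes, gene_sets, background, module_id=mid)
        for mid, genes in modules.items()
    ]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def select_modules(
    modules: dict[str, set[str]],
    results: pd.DataFrame,
    signature_genes,
    size_max: int = 500,
    term_q_max: float = 5.0e-5,
) -> list[str]:
    """Biologically relevant modules: contain >=1 signature gene, have fewer
    than ``size_max`` genes, and at least one term at q <= ``term_q_max``."""
    signature_genes = set(signature_genes)
    selected = []
    for mid, genes in modules.items():
        if not (genes & signature_genes):
            continue
        if len(genes) >= size_max:
            continue
        sub = results[(results["module_id"] == mid) & (results["q"] <= term_q_max)]
        if len(sub):
            selected.append(mid)
    return selected


def enrichment_overlap_map(
    results: pd.DataFrame,
    selected_modules,
    q_max: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-module map of shared enriched terms.

    Returns (term_table, jaccard_table): the first lists, for every term at
    q <= q_max in at least one selected module, each contributing module
    with its k count (the pie-chart decomposition); the second gives the
    Jaccard overlap of enriched-term sets for every module pair.
    """
    selected = list(selected_modules)
    if len(selected) < 2:
        raise ValueError("overlap mapping needs at least 2 selected modules")
    sub = results[results["module_id"].isin(selected)]
    enriched = sub[sub["q"] <= q_max]
    terms = sorted(enriched["term_id"].unique())
    term_rows = [
        {"term_id": t, "module_id": row["module_id"], "k": int(row["k"]),
         "q": float(row["q"])}
        for t in terms
        for _, row in enriched[enriched["term_id"] == t].iterrows()
    ]
    term_table = pd.DataFrame(term_rows, columns=["term_id", "module_id", "k", "q"])

    term_sets = {
        m: set(enriched.loc[enriched["module_id"] == m, "term_id"]) for m in selected
    }
    jac_rows = []
    for a, b in itertools.combinations(selected, 2):
        union = term_sets[a] | term_sets[b]
        jac = len(term_sets[a] & term_sets[b]) / len(union) if union else 0.0
        jac_rows.append({"module_a": a, "module_b": b, "jaccard": jac})
    return term_table, pd.DataFrame(jac_rows, columns=["module_a", "module_b", "jaccard"])
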