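"""Divergence heuristics, cross-study linear meta-filter, signature assembly.

Two complementary routes feed the final hypertrophy signature:

1. *Divergence route* — genes differentially expressed in exactly one
   responder group, kept only when the two groups truly diverge (fold
   changes in opposite directions, or a between-group fold-change ratio of
   at least 1.2).
2. *Linear route* — genes whose paired expression change tracks the percent
   change in lean mass. Pearson r and p are computed per study, p-values
   from the largest cohorts are pooled by Stouffer's signed-z method, and a
   gene passes when the across-study median |r| is >= 0.2, at least 4 of 5
   studies agree on the direction, and the Benjamini-Hochberg FDR of its
   pooled p (computed over genes passing the first two filters) is < 10%.

The signature is the union of the divergence-unique lists and the linear
set; each record carries its full evidence trail.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

SOURCE_LMR = "DE_UNIQUE_LMR"
SOURCE_NMLMR = "DE_UNIQUE_NMLMR"
SOURCE_LINEAR = "LINEAR"

_TINY_P = np.finfo(float).tiny


@dataclass(frozen=True)
class LinearFilterParameters:
    median_r_min: float = 0.2
    consistent_min: int = 4
    n_studies: int = 5
    fdr_max: float = 0.10
    # ids of the cohorts whose p-values are pooled; None = three largest by n
    pooled_studies: tuple[str, ...] | None = None


def divergence_filter(
    de_lmr: pd.DataFrame,
    de_nmlmr: pd.DataFrame,
    fc_ratio_min: float = 1.2,
) -> tuple[set[str], set[str]]:
    """Split significant genes into group-unique lists by divergence.

    A gene significant in exactly one group enters that group's unique
    list iff its fold changes point in opposite directions in the two
    groups, or the larger fold magnitude exceeds the smaller by the ratio
    threshold. Genes significant in both groups are excluded from both.
    """
    if set(de_lmr.index) != set(de_nmlmr.index):
        raise ValueError("the two DE tables must cover the same gene universe")
    nm = de_nmlmr.reindex(de_lmr.index)
    sig_l = de_lmr["significant"].to_numpy(bool)
    sig_n = nm["significant"].to_numpy(bool)
    fc_l = de_lmr["fold_change"].to_numpy(float)
    fc_n = nm["fold_change"].to_numpy(float)

    opposite = np.sign(fc_l) != np.sign(fc_n)
    mags = np.stack([np.abs(fc_l), np.abs(fc_n)])
    ratio = mags.max(axis=0) / mags.min(axis=0)
    diverges = opposite | (ratio >= fc_ratio_min)

    unique_lmr = set(de_lmr.index[sig_l & ~sig_n & diverges])
    unique_nmlmr = set(de_lmr.index[sig_n & ~sig_l & diverges])
    n_both = int((sig_l & sig_n).sum())
    if n_both:
        logger.info("excluded %d genes significant in both groups", n_both)
    return unique_lmr, unique_nmlmr


def per_study_association(
    delta_expr: dict[str, pd.DataFrame],
    delta_llm: dict[str, pd.Series],
) -> pd.DataFrame:
    """Per-gene, per-study Pearson r and two-sided p.

    ``delta_expr[study]`` is a genes x subjects matrix of paired log2
    changes; ``delta_llm[study]`` the matching percent lean-mass changes.
    Studies with fewer than 3 subjects are skipped with a warning. Gray-zone
    (indeterminate) subjects belong in these inputs: the linear analysis
    uses every participant.
    """
    frames = []
    for study, expr in delta_expr.items():
        y = delta_llm[study].reindex(expr.columns).to_numpy(float)
        n = len(y)
        if n < 3:
            logger.warning("study %s has %d subjects; skipped", study, n)
            continue
        x = expr.to_numpy(float)
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean()
        denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, (xc @ yc) / np.where(denom > 0, denom, 1.0), 0.0)
        r = np.clip(r, -1.0, 1.0)
        # two-sided p via the exact beta distribution of r under the null
        p = 2.0 * stats.beta.sf(np.abs(r), (n - 2) / 2.0, (n - 2) / 2.0, loc=-1, scale=2)
        p = np.clip(p, 0.0, 1.0)
        frames.append(
            pd.DataFrame(
                {"gene_id": expr.index, "study_id": study, "r": r, "p": p, "n": n}
            )
        )
    if not frames:
        raise ValueError("no study had enough subjects for association analysis")
    return pd.concat(frames, ignore_index=True)


def stouffer_pool(p_values, r_values) -> float:
    """Stouffer-pool two-sided p-values with direction taken from r.

    Each study contributes a signed z = Phi^{-1}(1 - p/2) * sign(r);
    pooled Z = sum(z)/sqrt(k) and the pooled two-sided p is returned.
    A single study is the identity; zero p-values are clamped.
    """
    p = np.asarray(p_values, dtype=float)
    r = np.asarray(r_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one study to pool")
    if np.any(p <= 0):
        logger.warning("clamping %d non-positive p-values", int((p <= 0).sum()))
        p = np.clip(p, _TINY_P, 1.0)
    z = stats.norm.isf(p / 2.0) * np.sign(r)
    pooled_z = z.sum() / math.sqrt(p.size)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(pooled_z))))


def pool_by_gene(
    assoc: pd.DataFrame, pooled_studies: tuple[str, ...]
) -> pd.Series:
    """Pooled p per gene over the designated studies (missing ones shrink k)."""
    sub = assoc[assoc["study_id"].isin(pooled_studies)]
    if sub.empty:
        raise ValueError(f"no association records for studies {pooled_studies}")
    p = np.clip(sub["p"].to_numpy(float), _TINY_P, 1.0)
    z = stats.norm.isf(p / 2.0) * np.sign(sub["r"].to_numpy(float))
    zf = pd.DataFrame({"z": z, "gene_id": sub["gene_id"].to_numpy()})
    grouped = zf.groupby("gene_id")["z"]
    pooled_z = grouped.sum() / np.sqrt(grouped.count())
    pooled = 2.0 * stats.norm.sf(np.abs(pooled_z.to_numpy()))
    return pd.Series(np.minimum(pooled, 1.0), index=pooled_z.index, name="pooled_p")


def linear_filter(
    assoc: pd.DataFrame,
    pooled_p: pd.Series,
    params: LinearFilterParameters | None = None,
) -> pd.DataFrame:
    """Apply the three linear-association filters; returns the passing genes.

    Output is indexed by gene id with columns median_abs_r, n_consistent,
    pooled_p, fdr. The FDR column is Benjamini-Hochberg over pooled
    p-values of the genes that passed filters 1 and 2 only.
    """
    params = params or LinearFilterParameters()
    per_gene = assoc.groupby("gene_id").agg(
        n_studies=("study_id", "nunique"),
        median_abs_r=("r", lambda v: float(np.median(np.abs(v)))),
        n_pos=("r", lambda v: int((np.asarray(v) > 0).sum())),
        n_neg=("r", lambda v: int((np.asarray(v) < 0).sum())),
    )
    few = per_gene[per_gene["n_studies"] < params.n_studies - 1]
    if len(few):
        logger.info("excluding %d genes with <%d study records", len(few),
                    params.n_studies - 1)
    per_gene = per_gene[per_gene["n_studies"] >= params.n_studies - 1]
    per_gene["n_consistent"] = per_gene[["n_pos", "n_neg"]].max(axis=1)

    pass12 = per_gene[
        (per_gene["median_abs_r"] >= params.median_r_min)
        & (per_gene["n_consistent"] >= params.consistent_min)
    ].copy()
    if pass12.empty:
        return pd.DataFrame(
            columns=["median_abs_r", "n_consistent", "pooled_p", "fdr"]
        )
    pass12["pooled_p"] = pooled_p.reindex(pass12.index)
    if pass12["pooled_p"].isna().any():
        raise ValueError("pooled p missing for genes passing filters 1-2")
    _, fdr, _, _ = multipletests(pass12["pooled_p"], method="fdr_bh")
    pass12["fdr"] = fdr
    out = pass12[pass12["fdr"] < params.fdr_max]
    return out[["median_abs_r", "n_consistent", "pooled_p", "fdr"]]


def assemble_signature(
    unique_lmr: set[str],
    unique_nmlmr: set[str],
    linear: pd.DataFrame,
    assoc: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Union the three evidence sets into the final signature table.

    Genes carried by more than one route (the CARMN-like case: linearly
    associated *and* LMR-differentially-expressed) list all sources.
    ``assoc``, when given, supplies per-study r columns for the report.
    """
    linear_genes = set(linear.index)
    all_genes = sorted(unique_lmr | unique_nmlmr | linear_genes)
    rows = []
    for g in all_genes:
        sources = [
            s
            for s, members in (
                (SOURCE_LMR, unique_lmr),
                (SOURCE_NMLMR, unique_nmlmr),
                (SOURCE_LINEAR, linear_genes),
            )
            if g in members
        ]
        rows.append(
            {
                "gene_id": g,
                "sources": ";".join(sources),
                "pooled_p": linear["pooled_p"].get(g, np.nan),
                "fdr": linear["fdr"].get(g, np.nan),
            }
        )
    out = pd.DataFrame(rows, columns=["gene_id", "sources", "pooled_p", "fdr"])
    out = out.set_index("gene_id")
    if assoc is not None:
        r_wide = assoc.pivot(index="gene_id", columns="study_id", values="r")
        r_wide.columns = [f"r_{c}" for c in r_wide.columns]
        out = out.join(r_wide, how="left")
    return out
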