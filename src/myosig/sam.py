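"""SAM-style moderated statistics with permutation false-discovery rates.

The significance-analysis-of-microarrays (SAM) statistic is a moderated
mean-to-variability ratio d = mean / (se + s0): the "fudge factor" s0
stabilises genes whose standard error is near zero, which would otherwise
dominate any t-like ranking. Significance is assessed non-parametrically:

* paired designs flip the sign of each subject's post-minus-pre vector
  (a valid permutation under the null of no within-subject change);
* unpaired designs permute the group labels.

For a symmetric threshold at |d| of a given gene, the q-value is

    q = median over permutations of #{null |d*| >= |d|} * pi0
        ----------------------------------------------------
                     #{observed |d| >= |d|}

with pi0 = min(1, 2 * fraction of observed d inside the interquartile
range of the pooled permuted d), monotonized so that q never increases
with |d|. Fold changes are computed on mean log2 differences and reported
as signed folds: FC = sign(m) * 2^|m|, so down-regulation at half
expression prints as -2.0 and the cut "|FC| >= 1.2" reads directly off
the magnitude.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import PairedExpressionSet

GROUP_BASELINE = "BASELINE"

_DE_COLUMNS = ["d_stat", "q_value", "fold_change", "significant", "group"]


@dataclass(frozen=True)
class SamParameters:
    """Tuning knobs for the SAM permutation test.

    s0 is chosen from the data (see :func:`choose_s0`) unless supplied;
    10K permutations match the full-scale analysis, smaller counts are
    appropriate at fixture scale.
    """

    s0: float | None = None
    s0_rule: str = "median"
    n_permutations: int = 10000
    seed: int = 0
    fdr_cutoff: float = 0.05
    fc_cutoff: float = 1.2

    def __post_init__(self) -> None:
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if not (0.0 < self.fdr_cutoff < 1.0):
            raise ValueError("fdr_cutoff must be in (0, 1)")
        if self.fc_cutoff < 1.0:
            raise ValueError("fc_cutoff must be >= 1 (a magnitude)")
        if self.s0_rule not in ("median", "tusher"):
            raise ValueError(f"unknown s0 rule {self.s0_rule!r}")


def choose_s0(se: np.ndarray, rule: str = "median", d_num: np.ndarray | None = None) -> float:
    """Select the fudge factor from the per-gene standard errors.

    ``median`` (default) returns the median standard error — the widely
    used SAM simplification. ``tusher`` searches se-percentile candidates
    for the value minimizing the coefficient of variation of the spread of
    d across se windows, and needs the per-gene numerators ``d_num``.
    """
    se = np.asarray(se, dtype=float)
    if se.size == 0:
        raise ValueError("cannot choose s0 from zero genes")
    if rule == "median":
        return float(np.median(se))
    if rule != "tusher":
        raise ValueError(f"unknown s0 rule {rule!r}")
    if d_num is None:
        raise ValueError("the tusher rule needs the per-gene numerators")
    d_num = np.asarray(d_num, dtype=float)
    candidates = np.percentile(se, np.arange(0, 101, 5))
    # ~25 windows keeps every window populated on fixture-sized inputs
    n_windows = min(25, max(3, se.size // 10))
    window_edges = np.quantile(se, np.linspace(0, 1, n_windows + 1))
    window_idx = np.clip(
        np.searchsorted(window_edges, se, side="right") - 1, 0, n_windows - 1
    )
    best_s0, best_cv = candidates[0], np.inf
    for alpha in candidates:
        d = d_num / (se + alpha)
        spreads = []
        for w in range(n_windows):
            dw = d[window_idx == w]
            if dw.size >= 2:
                spreads.append(1.4826 * np.median(np.abs(dw - np.median(dw))))
        spreads = np.asarray(spreads)
        if spreads.size < 2 or np.mean(spreads) == 0:
            continue
        cv = np.std(spreads) / np.mean(spreads)
        if cv < best_cv:
            best_cv, best_s0 = cv, alpha
    return float(best_s0)


def _moderated_d(num: np.ndarray, se: np.ndarray, s0: float) -> np.ndarray:
    denom = se + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return d


def _permutation_q(d_obs: np.ndarray, d_null: np.ndarray) -> np.ndarray:
    """q-values from observed d (G,) and null d (P, G) per the SAM recipe."""
    abs_obs = np.abs(d_obs)
    sorted_abs = np.sort(abs_obs)
    n_genes = abs_obs.size
    count_obs = n_genes - np.searchsorted(sorted_abs, abs_obs, side="left")

    q25, q75 = np.percentile(d_null, [25, 75])
    pi0 = min(1.0, 2.0 * float(np.mean((d_obs >= q25) & (d_obs <= q75))))

    abs_null = np.abs(d_null, out=d_null)  # |d*| in place; caller hands ownership
    abs_null.sort(axis=1)
    counts = np.empty((abs_null.shape[0], n_genes), dtype=np.int32)
    for p in range(abs_null.shape[0]):
        counts[p] = np.searchsorted(abs_null[p], abs_obs, side="left")
    np.subtract(n_genes, counts, out=counts)
    med_null = np.median(counts, axis=0)

    q_raw = med_null * pi0 / count_obs
    # monotonize: q non-increasing in |d| (cumulative min from the least
    # significant gene toward the most significant, in |d| order)
    order = np.argsort(-abs_obs, kind="stable")
    q_sorted = q_raw[order]
    q_mono = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty_like(q_raw)
    q[order] = q_mono
    return np.clip(q, 0.0, 1.0)


def _paired_null_d(z: np.ndarray, signs: np.ndarray, s0: float) -> np.ndarray:
    """Null d for sign-flip matrices ``signs`` (P, n); exploits that z^2 is
    sign-invariant so only the permuted means need a matmul."""
    n = z.shape[1]
    ss = np.sum(z * z, axis=1)
    means = z @ signs.T  # (G, P), still the per-perm sums here
    means /= n
    # se^2 = (ss - n*mean^2) / (n*(n-1)); built in place to bound memory
    denom = np.square(means)
    denom *= -n
    denom += ss[:, None]
    denom /= n * (n - 1)
    np.clip(denom, 0.0, None, out=denom)
    np.sqrt(denom, out=denom)
    denom += s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.divide(means, denom, out=means, where=denom > 0)
    d[~(denom > 0)] = 0.0
    return np.ascontiguousarray(d.T)  # (P, G)


def fold_change(expr: PairedExpressionSet, group_subjects) -> pd.Series:
    """Signed fold per gene from mean paired log2 differences."""
    z = expr.paired_delta(group_subjects).to_numpy()
    m = z.mean(axis=1)
    fc = np.where(m >= 0, 1.0, -1.0) * 2.0 ** np.abs(m)
    return pd.Series(fc, index=expr.gene_ids, name="fold_change")


def paired_sam(
    expr: PairedExpressionSet,
    group_subjects,
    params: SamParameters | None = None,
    group: str = "LMR",
    exhaustive: bool | None = None,
) -> pd.DataFrame:
    """Paired SAM analysis of post-minus-pre changes for one subject group.

    Returns a DataFrame indexed by gene id with columns d_stat, q_value,
    fold_change, significant, group. ``exhaustive`` controls the sign-flip
    null: True enumerates all 2^n patterns (n <= 20 only), False samples
    ``n_permutations`` patterns, and the default None enumerates whenever
    2^n <= n_permutations — the convention of the reference SAM package,
    which removes all Monte-Carlo error where enumeration is affordable.
    """
    params = params or SamParameters()
    zdf = expr.paired_delta(group_subjects)
    z = zdf.to_numpy(dtype=float)
    n = z.shape[1]
    if n < 3:
        raise ValueError(f"paired SAM needs at least 3 subjects, got {n}")

    mean = z.mean(axis=1)
    se = z.std(axis=1, ddof=1) / np.sqrt(n)
    s0 = params.s0 if params.s0 is not None else choose_s0(se, params.s0_rule, mean)
    d_obs = _moderated_d(mean, se, s0)

    if exhaustive is None:
        exhaustive = n <= 20 and 2**n <= params.n_permutations
    if exhaustive:
        if n > 20:
            raise ValueError("exhaustive enumeration is limited to 20 subjects")
        signs = np.array(list(itertools.product((-1.0, 1.0), repeat=n)))
    else:
        rng = np.random.default_rng(params.seed)
        signs = rng.choice((-1.0, 1.0), size=(params.n_permutations, n))
    d_null = _paired_null_d(z, signs, s0)
    q = _permutation_q(d_obs, d_null)

    m = mean
    fc = np.where(m >= 0, 1.0, -1.0) * 2.0 ** np.abs(m)
    out = pd.DataFrame(
        {
            "d_stat": d_obs,
            "q_value": q,
            "fold_change": fc,
            "significant": (q < params.fdr_cutoff) & (np.abs(fc) >= params.fc_cutoff),
            "group": group,
        },
        index=zdf.index,
    )
    out.index.name = "gene_id"
    return out


def unpaired_sam(
    baseline_expr: pd.DataFrame,
    labels: pd.Series,
    params: SamParameters | None = None,
    group_a: str | None = None,
    group_b: str | None = None,
) -> pd.DataFrame:
    """Two-group SAM on a baseline genes x samples matrix (group = BASELINE).

    ``labels`` maps sample id -> group name; d is (mean_A - mean_B) over
    (pooled se + s0) and q-values come from label permutations. FC sign is
    positive when group A is higher.
    """
    params = params or SamParameters()
    labels = labels.reindex(baseline_expr.columns)
    if labels.isna().any():
        raise ValueError("every sample column needs a group label")
    groups = sorted(labels.unique()) if group_a is None else [group_a, group_b]
    if len(groups) != 2:
        raise ValueError(f"unpaired SAM needs exactly two groups, got {groups}")
    ga, gb = groups
    mask_a = (labels == ga).to_numpy()
    mask_b = (labels == gb).to_numpy()
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    if min(n_a, n_b) < 3:
        raise ValueError("each group needs at least 3 samples")

    x = baseline_expr.to_numpy(dtype=float)[:, mask_a | mask_b]
    is_a = mask_a[mask_a | mask_b]
    n_tot = n_a + n_b

    def _two_sample_d(a_indicator: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # a_indicator: (n_tot,) 0/1; returns (num, se) per gene
        sum_a = x @ a_indicator
        mean_a = sum_a / n_a
        mean_b = (x.sum(axis=1) - sum_a) / n_b
        ss_tot = np.sum(x * x, axis=1)
        sp2 = (ss_tot - n_a * mean_a**2 - n_b * mean_b**2) / (n_tot - 2)
        se = np.sqrt(np.clip(sp2, 0.0, None) * (1.0 / n_a + 1.0 / n_b))
        return mean_a - mean_b, se

    num, se = _two_sample_d(is_a.astype(float))
    s0 = params.s0 if params.s0 is not None else choose_s0(se, params.s0_rule, num)
    d_obs = _moderated_d(num, se, s0)

    rng = np.random.default_rng(params.seed)
    d_null = np.empty((params.n_permutations, x.shape[0]))
    base = is_a.astype(float)
    for p in range(params.n_permutations):
        perm = rng.permutation(base)
        pn, pse = _two_sample_d(perm)
        d_null[p] = _moderated_d(pn, pse, s0)
    q = _permutation_q(d_obs, d_null)

    fc = np.where(num >= 0, 1.0, -1.0) * 2.0 ** np.abs(num)
    out = pd.DataFrame(
        {
            "d_stat": d_obs,
            "q_value": q,
            "fold_change": fc,
            "significant": (q < params.fdr_cutoff) & (np.abs(fc) >= params.fc_cutoff),
            "group": GROUP_BASELINE,
        },
        index=baseline_expr.index,
    )
    out.index.name = "gene_id"
    return out
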