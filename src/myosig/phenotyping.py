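"""Responder classification from changes in leg lean mass.

Participants in supervised loading studies are stratified by the percent
change in DXA-derived leg lean mass (or MRI-derived thigh muscle volume)
relative to the technical precision of the instrument: gains at or above
2.5% are called lean-mass responders (LMR), changes below 2.0% are called
"no measurable lean-mass response" (NMLMR), and the band in between —
inside the instrument's reported precision error — is indeterminate.
Indeterminate subjects are retained for linear modelling but excluded from
the two-group differential-expression contrasts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

LMR = "LMR"
NMLMR = "NMLMR"
INDETERMINATE = "INDETERMINATE"

LABELS = (LMR, NMLMR, INDETERMINATE)


@dataclass(frozen=True)
class Thresholds:
    """Group cut-offs in percent change of lean mass.

    ``lmr_min`` and ``nmlmr_max`` bound the instrument-precision gray zone
    [nmlmr_max, lmr_min); both DXA and MRI use the same group cut-offs, the
    modality-specific precision error being metadata only.
    """

    lmr_min: float = 2.5
    nmlmr_max: float = 2.0

    def __post_init__(self) -> None:
        if not (self.nmlmr_max <= self.lmr_min):
            raise ValueError(
                f"nmlmr_max ({self.nmlmr_max}) must not exceed lmr_min ({self.lmr_min})"
            )


def percent_change(pre: float, post: float) -> float:
    """Percent change 100*(post-pre)/pre; ``pre`` must be positive."""
    pre_arr = np.asarray(pre, dtype=float)
    post_arr = np.asarray(post, dtype=float)
    if np.any(pre_arr <= 0):
        raise ValueError("baseline lean mass must be positive")
    out = 100.0 * (post_arr - pre_arr) / pre_arr
    return float(out) if out.ndim == 0 else out


def classify_responder(pct: float, thresholds: Thresholds | None = None) -> str:
    """Map one percent-change value to LMR / NMLMR / INDETERMINATE."""
    thresholds = thresholds or Thresholds()
    if not math.isfinite(pct):
        raise ValueError(f"percent change must be finite, got {pct!r}")
    if pct >= thresholds.lmr_min:
        return LMR
    if pct < thresholds.nmlmr_max:
        return NMLMR
    return INDETERMINATE


def classify_table(
    phenotypes: pd.DataFrame, thresholds: Thresholds | None = None
) -> pd.DataFrame:
    """Classify a phenotype table (subject_id, study_id, modality, llm_pre, llm_post).

    Returns a copy with derived ``pct_change`` and ``label`` columns.
    """
    thresholds = thresholds or Thresholds()
    out = phenotypes.copy()
    out["pct_change"] = percent_change(
        out["llm_pre"].to_numpy(float), out["llm_post"].to_numpy(float)
    )
    out["label"] = [classify_responder(p, thresholds) for p in out["pct_change"]]
    return out


def summarize_groups(labelled: pd.DataFrame) -> pd.DataFrame:
    """Per-label n / mean / sd / min / max of percent change.

    sd of a single observation is reported as 0 with ``sd_degenerate`` set,
    so reports never carry NaN. Totals reconcile with the input count.
    """
    if len(labelled) == 0:
        raise ValueError("cannot summarize an empty participant table")
    rows = []
    for label in LABELS:
        grp = labelled.loc[labelled["label"] == label, "pct_change"]
        if len(grp) == 0:
            rows.append({"label": label, "n": 0, "mean": np.nan, "sd": np.nan,
                         "min": np.nan, "max": np.nan, "sd_degenerate": False})
            continue
        sd = float(grp.std(ddof=1)) if len(grp) > 1 else 0.0
        rows.append({
            "label": label,
            "n": int(len(grp)),
            "mean": float(grp.mean()),
            "sd": sd,
            "min": float(grp.min()),
            "max": float(grp.max()),
            "sd_degenerate": len(grp) == 1,
        })
    out = pd.DataFrame(rows).set_index("label")
    assert int(out["n"].sum()) == len(labelled)
    return out


def baseline_association(labelled: pd.DataFrame) -> tuple[float, float]:
    """Pearson r (and p) between baseline lean mass and percent change.

    Purely a reporting utility: responder status should not be explainable
    by baseline lean mass, and this quantifies that check.
    """
    r, p = stats.pearsonr(labelled["llm_pre"], labelled["pct_change"])
    return float(r), float(p)
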