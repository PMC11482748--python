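"""Probe reannotation, probe-set assembly, QC and summarization.

High-density arrays carry millions of short (25-mer) probes whose vendor
annotation drifts as reference transcriptomes are revised. The remedy is
to realign probes against the current transcriptome and rebuild the chip
definition from scratch: only uniquely mapping probes are kept, probes
targeting the same transcript form a probe-set, and probe-sets backed by
fewer than four probes are discarded as unreliable. Probes that are both
very dim and nearly invariant across a large sample panel carry no signal
and are removed (the conjunction matters: a dim but variable probe may be
a genuine low-abundance transcript). Surviving probe-sets are summarized
per sample by the median of member-probe log2 intensities and the matrix
is normalized across samples (quantile normalization by default, behind a
pluggable interface).

Alignment itself is out of scope: inputs are tabular records
(probe_id, transcript_id, n_hits) from an external aligner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MIN_PROBES = 4  # probe-sets rely on n > 3 probes


@dataclass(frozen=True)
class ProbeQCThresholds:
    """Conjunction QC rule: drop a probe iff median linear-scale signal is
    below ``signal_floor`` AND its coefficient of variation is below
    ``cv_floor``. No silent defaults: both must be supplied."""

    signal_floor: float
    cv_floor: float

    def __post_init__(self) -> None:
        if self.signal_floor < 0 or self.cv_floor < 0:
            raise ValueError("QC thresholds must be non-negative")


def filter_unique_mappings(alignments: pd.DataFrame) -> pd.Series:
    """Keep probes with exactly one transcriptome hit.

    ``alignments`` columns: probe_id, transcript_id, n_hits. Returns a
    Series probe_id -> transcript_id. Duplicate probe records that
    conflict raise; consistent duplicates collapse.
    """
    required = {"probe_id", "transcript_id", "n_hits"}
    missing = required - set(alignments.columns)
    if missing:
        raise ValueError(f"alignment table missing columns: {sorted(missing)}")
    dedup = alignments.drop_duplicates()
    conflicts = dedup["probe_id"].duplicated(keep=False)
    if conflicts.any():
        bad = sorted(dedup.loc[conflicts, "probe_id"].unique())
        raise ValueError(f"conflicting alignment records for probes: {bad[:5]}")
    unique = dedup[dedup["n_hits"] == 1]
    return pd.Series(
        unique["transcript_id"].to_numpy(), index=unique["probe_id"], name="transcript_id"
    )


def build_probesets(unique_map: pd.Series) -> dict[str, list[str]]:
    """Group uniquely mapping probes into per-transcript probe-sets.

    Transcripts backed by fewer than four probes are excluded and logged.
    """
    probesets: dict[str, list[str]] = {}
    for transcript, probes in unique_map.groupby(unique_map):
        ids = sorted(probes.index)
        if len(ids) >= MIN_PROBES:
            probesets[transcript] = ids
        else:
            logger.info(
                "transcript %s excluded: only %d unique probes", transcript, len(ids)
            )
    return probesets


def probeset_size_median(probesets: dict[str, list[str]]) -> float:
    return float(np.median([len(v) for v in probesets.values()]))


def filter_probes_signal_cv(
    intensities: pd.DataFrame, thresholds: ProbeQCThresholds
) -> pd.Index:
    """Retained probes after the low-signal AND low-CV conjunction rule.

    ``intensities`` are linear-scale, probes x samples, >= 2 samples
    (CV needs a variance). CV = sd/mean per probe.
    """
    if intensities.shape[1] < 2:
        raise ValueError("probe QC needs at least 2 samples to compute CV")
    x = intensities.to_numpy(float)
    med = np.median(x, axis=1)
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean != 0, sd / np.where(mean != 0, mean, 1.0), 0.0)
    removed = (med < thresholds.signal_floor) & (cv < thresholds.cv_floor)
    logger.info("probe QC removed %d / %d probes", int(removed.sum()), len(removed))
    return intensities.index[~removed]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Classic quantile normalization: every column gets the mean
    order-statistic distribution; within-sample ranks are preserved.

    The reference sample (the column whose distribution is closest to the
    all-sample median distribution) is identified and logged, mirroring
    reference-based normalizers.
    """
    x = matrix.to_numpy(float)
    order = np.argsort(x, axis=0)
    ranks = np.argsort(order, axis=0)
    mean_dist = np.sort(x, axis=0).mean(axis=1)
    out = mean_dist[ranks]
    med_dist = np.median(np.sort(x, axis=0), axis=1)
    dists = np.abs(np.sort(x, axis=0) - med_dist[:, None]).sum(axis=0)
    ref = matrix.columns[int(np.argmin(dists))]
    logger.info("quantile normalization reference sample: %s", ref)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


NORMALIZERS = {
    "quantile": quantile_normalize,
    "none": lambda m: m.copy(),
}


def summarize_and_normalize(
    intensities: pd.DataFrame,
    probesets: dict[str, list[str]],
    retained_probes: pd.Index | None = None,
    method: str = "quantile",
) -> pd.DataFrame:
    """Median-summarize probe-sets to log2 and normalize across samples.

    ``intensities`` are linear-scale probes x samples. Probe-sets falling
    below four probes after QC are dropped and logged; a probe referenced
    by a probe-set but absent from the intensity table is an input error.
    """
    if method not in NORMALIZERS:
        raise ValueError(f"unknown normalization method {method!r}")
    if retained_probes is None:
        retained_probes = intensities.index
    retained = set(retained_probes)
    log2 = np.log2(intensities.to_numpy(float))
    log2 = pd.DataFrame(log2, index=intensities.index, columns=intensities.columns)
    rows = {}
    for transcript, probes in probesets.items():
        absent = [p for p in probes if p not in intensities.index]
        if absent:
            raise ValueError(
                f"probe-set {transcript} references probes missing from the "
                f"intensity table: {absent[:5]}"
            )
        kept = [p for p in probes if p in retained]
        if len(kept) < MIN_PROBES:
            logger.info(
                "probe-set %s dropped: %d probes survive QC", transcript, len(kept)
            )
            continue
        rows[transcript] = log2.loc[kept].median(axis=0)
    if not rows:
        raise ValueError("no probe-set survived QC")
    summarized = pd.DataFrame(rows).T
    summarized.index.name = "transcript_id"
    return NORMALIZERS[method](summarized)
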