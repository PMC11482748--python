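"""Shared fixtures: small synthetic configurations and hand-built matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from myosig.containers import PairedExpressionSet
from myosig.synthetic import SimulationConfig


def make_paired_expr(z: np.ndarray, gene_ids=None, study_ids=None) -> PairedExpressionSet:
    """Build a paired expression set whose post-minus-pre deltas equal ``z``.

    Pre values are zero, post values are z, so the paired delta matrix is z
    exactly. ``z`` is genes x subjects.
    """
    z = np.asarray(z, dtype=float)
    n_genes, n_sub = z.shape
    subjects = [f"s{i:02d}" for i in range(n_sub)]
    gene_ids = gene_ids or [f"g{i:03d}" for i in range(n_genes)]
    sample_ids = [f"{s}_pre" for s in subjects] + [f"{s}_post" for s in subjects]
    values = pd.DataFrame(
        np.hstack([np.zeros_like(z), z]), index=gene_ids, columns=sample_ids
    )
    samples = pd.DataFrame(
        {
            "subject_id": subjects * 2,
            "study_id": (study_ids or ["study1"] * n_sub) * 2,
            "timepoint": ["pre"] * n_sub + ["post"] * n_sub,
        },
        index=sample_ids,
    )
    return PairedExpressionSet(values, samples)


@pytest.fixture
def small_config() -> SimulationConfig:
    """A 25-subject, 400-gene version of the five-study design."""
    return SimulationConfig(
        seed=7,
        study_sizes=(8, 6, 5, 3, 3),
        modality_per_study=("DXA", "DXA", "DXA", "MRI", "DXA"),
        n_genes=400,
        n_responders=15,
        n_non_responders=8,
        n_indeterminate=2,
        n_planted_lmr_de=8,
        n_planted_nmlmr_de=4,
        n_planted_linear=6,
        planted_overlap=1,
        n_mixture_samples=60,
        n_signature_genes_per_type=5,
    )
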