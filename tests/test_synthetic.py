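"""Synthetic-data generator: determinism, planted effects, ground truth."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy import stats

from myosig.phenotyping import INDETERMINATE, LMR, NMLMR, classify_table
from myosig.synthetic import (
    BIOTYPE_COUNTS,
    SimulationConfig,
    generate_annotation,
    generate_cohorts,
    generate_expression,
    generate_marker_mixture,
)


def test_default_design_has_144_participants():
    cohorts, labels = generate_cohorts(SimulationConfig(seed=0))
    assert len(cohorts) == 144
    assert cohorts.groupby("study_id").size().tolist() == [32, 33, 47, 20, 12]
    counts = pd.Series(labels).value_counts()
    assert counts[LMR] == 88 and counts[NMLMR] == 50 and counts[INDETERMINATE] == 6


def test_latent_labels_match_downstream_classification(small_config):
    """Truncated draws make latent labels and threshold classification agree."""
    cohorts, labels = generate_cohorts(small_config)
    labelled = classify_table(cohorts)
    for _, row in labelled.iterrows():
        assert labels[row["subject_id"]] == row["label"]


def test_same_seed_reproduces_everything(small_config):
    c1, l1 = generate_cohorts(small_config)
    c2, l2 = generate_cohorts(small_config)
    pd.testing.assert_frame_equal(c1, c2)
    assert l1 == l2
    e1, t1 = generate_expression(c1, small_config, l1)
    e2, t2 = generate_expression(c2, small_config, l2)
    pd.testing.assert_frame_equal(e1.values, e2.values)
    assert t1.planted_lmr_de == t2.planted_lmr_de
    m1, s1 = generate_marker_mixture(small_config)
    m2, s2 = generate_marker_mixture(small_config)
    pd.testing.assert_frame_equal(m1, m2)
    assert s1 == s2


def test_different_seed_changes_output(small_config):
    c1, _ = generate_cohorts(small_config)
    c2, _ = generate_cohorts(replace(small_config, seed=small_config.seed + 1))
    assert not c1.equals(c2)


def test_annotation_biotype_counts_follow_fractions(small_config):
    ann = generate_annotation(small_config)
    counts = ann["biotype"].value_counts()
    total = sum(BIOTYPE_COUNTS.values())
    for biotype, n in BIOTYPE_COUNTS.items():
        expected = n / total * small_config.n_genes
        assert abs(counts[biotype] - expected) <= 1


def test_paired_design_emits_two_samples_per_subject(small_config):
    cohorts, labels = generate_cohorts(small_config)
    expr, _ = generate_expression(cohorts, small_config, labels)
    per_subject = expr.samples.groupby("subject_id")["timepoint"].agg(set)
    assert all(tp == {"pre", "post"} for tp in per_subject)
    assert expr.values.shape[1] == 2 * len(cohorts)


def test_noiseless_planting_is_exact(small_config):
    """With zero noise every planted DE gene shifts by exactly the effect size
    in its own group and not at all in the other."""
    config = replace(small_config, noise_sd_log2=0.0, effect_size_log2=0.5)
    cohorts, labels = generate_cohorts(config)
    expr, truth = generate_expression(cohorts, config, labels)
    lmr = [s for s, l in labels.items() if l == LMR]
    nmlmr = [s for s, l in labels.items() if l == NMLMR]
    dz_lmr = expr.paired_delta(lmr)
    dz_nmlmr = expr.paired_delta(nmlmr)
    for g in truth.planted_lmr_de:
        assert dz_lmr.loc[g].mean() == pytest.approx(0.5)
        assert dz_nmlmr.loc[g].mean() == pytest.approx(0.0)
    null_gene = next(iter(set(expr.gene_ids) - truth.planted_lmr_de
                          - truth.planted_nmlmr_de - truth.planted_linear))
    assert dz_lmr.loc[null_gene].abs().max() == pytest.approx(0.0)


def test_planted_sets_disjoint_except_declared_overlap(small_config):
    cohorts, labels = generate_cohorts(small_config)
    _, truth = generate_expression(cohorts, small_config, labels)
    assert len(truth.planted_lmr_de & truth.planted_nmlmr_de) == 0
    assert len(truth.planted_nmlmr_de & truth.planted_linear) == 0
    assert len(truth.planted_lmr_de & truth.planted_linear) == small_config.planted_overlap
    assert len(truth.planted_lmr_de) == small_config.n_planted_lmr_de
    assert len(truth.planted_linear) == small_config.n_planted_linear


def test_planted_linear_genes_hit_target_correlation():
    """Realized per-gene Pearson r against %dLLM lands near the target
    (recomputed directly on the emitted matrix)."""
    config = SimulationConfig(seed=1, n_genes=500, n_planted_lmr_de=0,
                              n_planted_nmlmr_de=0, n_planted_linear=20,
                              planted_overlap=0, linear_r_target=0.3)
    cohorts, labels = generate_cohorts(config)
    expr, truth = generate_expression(cohorts, config, labels)
    pct = (100 * (cohorts["llm_post"] - cohorts["llm_pre"]) / cohorts["llm_pre"]).to_numpy()
    dz = expr.paired_delta(cohorts["subject_id"].tolist())
    rs = np.array([
        stats.pearsonr(dz.loc[g].to_numpy(), pct)[0] for g in truth.planted_linear
    ])
    # per-gene r carries sampling noise ~(1-r^2)/sqrt(n) ~= 0.076 at n=144;
    # the calibration target binds the ensemble mean, individual genes stay
    # within 3 sampling SDs
    assert abs(rs.mean() - 0.3) <= 0.05
    assert np.all(np.abs(rs - 0.3) <= 3 * 0.08)


def test_null_genes_average_no_change(small_config):
    """Across 20 seeds the mean |dlog2| of null genes stays within 3 SE of 0."""
    means = []
    for seed in range(20):
        config = replace(small_config, seed=seed)
        cohorts, labels = generate_cohorts(config)
        expr, truth = generate_expression(cohorts, config, labels)
        planted = truth.planted_lmr_de | truth.planted_nmlmr_de | truth.planted_linear
        null_ids = [g for g in expr.gene_ids if g not in planted]
        dz = expr.paired_delta(cohorts["subject_id"].tolist()).loc[null_ids]
        means.append(dz.to_numpy().mean())
    means = np.asarray(means)
    se = means.std(ddof=1) / np.sqrt(len(means))
    assert abs(means.mean()) <= 3 * se + 1e-12


def test_mixture_noiseless_signature_gene_tracks_its_marker(small_config):
    config = replace(small_config, mixture_noise_sd=0.0)
    matrix, signatures = generate_marker_mixture(config)
    ann = generate_annotation(config)
    sym_to_id = dict(zip(ann["symbol"], ann.index))
    endo = sorted(signatures["endothelial"])
    tie1 = sym_to_id["TIE1"]
    planted = next(g for g in endo if g != tie1)
    r = stats.pearsonr(matrix.loc[planted], matrix.loc[tie1])[0]
    assert r == pytest.approx(1.0)


def test_mixture_noisy_marker_correlation_strong(small_config):
    config = replace(small_config, mixture_noise_sd=0.1, n_mixture_samples=437, seed=2)
    matrix, signatures = generate_marker_mixture(config)
    ann = generate_annotation(config)
    sym_to_id = dict(zip(ann["symbol"], ann.index))
    tie1 = sym_to_id["TIE1"]
    planted = next(g for g in sorted(signatures["endothelial"]) if g != tie1)
    r = stats.pearsonr(matrix.loc[planted], matrix.loc[tie1])[0]
    assert r >= 0.8


@pytest.mark.parametrize(
    "kwargs",
    [
        {"study_sizes": (0, 5), "modality_per_study": ("DXA", "DXA")},
        {"biotype_fractions": {"protein_coding": 0.5, "lncRNA": 0.4}},
        {"n_planted_lmr_de": 500, "n_genes": 100},
        {"n_responders": 1},
        {"cell_fractions": {"type_I_fibre": 0.9}},
    ],
)
def test_invalid_configurations_rejected(kwargs):
    base = dict(
        study_sizes=(8, 6, 5, 3, 3),
        modality_per_study=("DXA", "DXA", "DXA", "MRI", "DXA"),
        n_genes=400,
        n_responders=15,
        n_non_responders=8,
        n_indeterminate=2,
    )
    base.update(kwargs)
    with pytest.raises(ValueError):
        SimulationConfig(**base)
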