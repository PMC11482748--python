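"""Divergence heuristics, linear meta-filter, Stouffer pooling, assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from myosig.signature import (
    LinearFilterParameters,
    assemble_signature,
    divergence_filter,
    linear_filter,
    per_study_association,
    pool_by_gene,
    stouffer_pool,
)


def _de(rows):
    out = pd.DataFrame(rows, columns=["gene_id", "fold_change", "significant"])
    out["d_stat"] = 0.0
    out["q_value"] = np.where(out["significant"], 0.01, 0.5)
    return out.set_index("gene_id")


class TestDivergenceFilter:
    @pytest.mark.parametrize(
        "fc_lmr, fc_nmlmr, expect_unique",
        [
            (1.3, -1.1, True),   # opposite directions
            (1.5, 1.2, True),    # same sign, ratio 1.25 >= 1.2
            (1.3, 1.25, False),  # same sign, ratio 1.04 < 1.2
        ],
    )
    def test_divergence_clauses(self, fc_lmr, fc_nmlmr, expect_unique):
        lmr = _de([("g1", fc_lmr, True)])
        nmlmr = _de([("g1", fc_nmlmr, False)])
        unique_lmr, unique_nmlmr = divergence_filter(lmr, nmlmr)
        assert (("g1" in unique_lmr) == expect_unique)
        assert not unique_nmlmr

    def test_gene_significant_in_both_groups_excluded(self):
        lmr = _de([("g1", 1.5, True)])
        nmlmr = _de([("g1", -1.5, True)])
        unique_lmr, unique_nmlmr = divergence_filter(lmr, nmlmr)
        assert not unique_lmr and not unique_nmlmr

    def test_mismatched_universes_rejected(self):
        with pytest.raises(ValueError):
            divergence_filter(_de([("g1", 1.0, False)]), _de([("g2", 1.0, False)]))


class TestPerStudyAssociation:
    @pytest.mark.parametrize(
        "llm, expected_r",
        [((2.0, 4.0, 6.0), 1.0), ((6.0, 4.0, 2.0), -1.0), ((1.0, 3.0, 2.0), 0.5)],
    )
    def test_known_correlations(self, llm, expected_r):
        dz = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g1"], columns=["a", "b", "c"])
        llm_s = pd.Series(llm, index=["a", "b", "c"])
        out = per_study_association({"study1": dz}, {"study1": llm_s})
        assert out["r"].iloc[0] == pytest.approx(expected_r)

    def test_p_matches_scipy(self):
        rng = np.random.default_rng(0)
        dz = pd.DataFrame(rng.normal(size=(5, 20)),
                          columns=[f"s{i}" for i in range(20)])
        llm = pd.Series(rng.normal(size=20), index=dz.columns)
        out = per_study_association({"st": dz}, {"st": llm})
        for i in range(5):
            r_ref, p_ref = stats.pearsonr(dz.iloc[i], llm)
            assert out["r"].iloc[i] == pytest.approx(r_ref)
            assert out["p"].iloc[i] == pytest.approx(p_ref, rel=1e-6)

    def test_small_studies_skipped(self):
        dz_big = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g1"], columns=list("abc"))
        dz_small = pd.DataFrame([[1.0, 2.0]], index=["g1"], columns=list("de"))
        out = per_study_association(
            {"big": dz_big, "small": dz_small},
            {"big": pd.Series([1, 2, 3.0], index=list("abc")),
             "small": pd.Series([1, 2.0], index=list("de"))},
        )
        assert set(out["study_id"]) == {"big"}


class TestStoufferPool:
    def test_single_study_identity(self):
        assert stouffer_pool([0.3], [0.5]) == pytest.approx(0.3)

    def test_all_ones_pool_to_one(self):
        assert stouffer_pool([1.0, 1.0, 1.0], [0.1, 0.2, 0.3]) == pytest.approx(1.0)

    def test_three_concordant_p05(self):
        # z = 1.95996 each, pooled Z = 1.95996*sqrt(3) = 3.3948
        pooled = stouffer_pool([0.05] * 3, [0.4, 0.3, 0.2])
        assert pooled == pytest.approx(6.9e-4, rel=2e-2)

    def test_study_order_invariance(self):
        p = [0.01, 0.2, 0.6]
        r = [0.5, -0.2, 0.3]
        assert stouffer_pool(p, r) == pytest.approx(stouffer_pool(p[::-1], r[::-1]))

    def test_global_sign_flip_leaves_pooled_p(self):
        p = [0.01, 0.2, 0.6]
        r = np.array([0.5, -0.2, 0.3])
        assert stouffer_pool(p, r) == pytest.approx(stouffer_pool(p, -r))

    def test_zero_p_clamped_not_fatal(self):
        assert 0.0 <= stouffer_pool([0.0, 0.5], [0.3, 0.3]) < 1e-10

    def test_pool_by_gene_matches_scalar_path(self):
        assoc = pd.DataFrame(
            {
                "gene_id": ["g1"] * 3 + ["g2"] * 2,
                "study_id": ["a", "b", "c", "a", "b"],
                "r": [0.3, 0.2, 0.4, -0.1, -0.3],
                "p": [0.05, 0.1, 0.2, 0.5, 0.4],
            }
        )
        pooled = pool_by_gene(assoc, ("a", "b", "c"))
        assert pooled["g1"] == pytest.approx(stouffer_pool([0.05, 0.1, 0.2], [0.3, 0.2, 0.4]))
        assert pooled["g2"] == pytest.approx(stouffer_pool([0.5, 0.4], [-0.1, -0.3]))


def _assoc_for(r_by_study, p=0.01, gene="g1"):
    rows = [
        {"gene_id": gene, "study_id": f"study{i+1}", "r": r, "p": p, "n": 30}
        for i, r in enumerate(r_by_study)
    ]
    return pd.DataFrame(rows)


class TestLinearFilter:
    def test_passing_gene(self):
        assoc = _assoc_for([0.30, 0.25, 0.22, 0.28, -0.05])
        pooled = pd.Series({"g1": 1e-4})
        out = linear_filter(assoc, pooled)
        assert list(out.index) == ["g1"]
        assert out.loc["g1", "median_abs_r"] == pytest.approx(0.25)

    def test_fails_median_filter(self):
        assoc = _assoc_for([0.15, 0.10, 0.18, 0.12, 0.19])
        out = linear_filter(assoc, pd.Series({"g1": 1e-6}))
        assert out.empty

    def test_fails_sign_consistency(self):
        assoc = _assoc_for([0.3, 0.3, -0.3, -0.3, 0.05])
        out = linear_filter(assoc, pd.Series({"g1": 1e-6}))
        assert out.empty

    def test_fails_fdr(self):
        assoc = _assoc_for([0.3, 0.3, 0.3, 0.3, 0.3])
        out = linear_filter(assoc, pd.Series({"g1": 0.5}))
        assert out.empty

    def test_gene_with_too_few_studies_excluded(self):
        assoc = _assoc_for([0.3, 0.3, 0.3])  # only 3 of 5 studies
        out = linear_filter(assoc, pd.Series({"g1": 1e-6}))
        assert out.empty

    def test_fdr_computed_over_filter12_passers_only(self):
        """A gene failing filters 1-2 must not dilute the BH correction."""
        frames = [_assoc_for([0.3] * 5, gene="good")]
        frames.append(_assoc_for([0.01] * 5, gene="bad"))
        assoc = pd.concat(frames, ignore_index=True)
        pooled = pd.Series({"good": 0.04, "bad": 0.5})
        out = linear_filter(assoc, pooled, LinearFilterParameters(fdr_max=0.05))
        # single passer: BH leaves its p untouched
        assert out.loc["good", "fdr"] == pytest.approx(0.04)


class TestBenjaminiHochberg:
    @given(
        st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=20)
    )
    @settings(max_examples=100, deadline=None)
    def test_bh_matches_brute_force_oracle(self, pvals):
        """statsmodels BH (the packaged FDR) equals the textbook definition
        q_i = min_{j: p_j >= p_i} p_(j) * m / rank(j), computed by brute force."""
        _, q, _, _ = multipletests(pvals, method="fdr_bh")
        m = len(pvals)
        order = np.argsort(pvals)
        sorted_p = np.asarray(pvals)[order]
        raw = sorted_p * m / (np.arange(m) + 1)
        brute_sorted = [min(raw[i:]) for i in range(m)]
        brute = np.empty(m)
        brute[order] = np.minimum(brute_sorted, 1.0)
        np.testing.assert_allclose(q, brute, rtol=1e-10)


class TestAssembleSignature:
    def test_union_arithmetic_matches_set_algebra(self):
        unique_lmr = {f"L{i}" for i in range(50)}
        unique_nmlmr = {f"N{i}" for i in range(15)}
        linear_genes = {"L0"} | {f"X{i}" for i in range(45)}
        linear = pd.DataFrame(
            {"median_abs_r": 0.3, "n_consistent": 5, "pooled_p": 1e-4, "fdr": 0.01},
            index=sorted(linear_genes),
        )
        sig = assemble_signature(unique_lmr, unique_nmlmr, linear)
        assert len(sig) == 110
        assert sig.loc["L0", "sources"] == "DE_UNIQUE_LMR;LINEAR"

    def test_disjoint_singletons(self):
        linear = pd.DataFrame(
            {"median_abs_r": 0.3, "n_consistent": 5, "pooled_p": 1e-4, "fdr": 0.01},
            index=["c"],
        )
        sig = assemble_signature({"a"}, {"b"}, linear)
        assert len(sig) == 3

    def test_linear_subset_of_de_adds_nothing(self):
        linear = pd.DataFrame(
            {"median_abs_r": 0.3, "n_consistent": 5, "pooled_p": 1e-4, "fdr": 0.01},
            index=["a1", "a2"],
        )
        sig = assemble_signature({"a1", "a2", "a3"}, {"b1"}, linear)
        assert len(sig) == 4
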