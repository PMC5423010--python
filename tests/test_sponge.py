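import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import hypergeom_upper_tail_exact
from mirscoppi import (
    GeneList,
    PipelineConfig,
    UndefinedScoreError,
    collaboration_score,
    cosine_score,
    generate_dataset,
    infer_sponge_network,
    pearson_with_pvalue,
    shared_mirna_pvalue,
    similarity_score,
)
from mirscoppi.datamodel import ExpressionMatrix, canonical_edge
from mirscoppi.pipeline import sponge_step


class TestPearson:
    def test_identical_vectors(self):
        r, p = pearson_with_pvalue([1, 2, 3], [1, 2, 3])
        assert r == 1.0 and p == 0.0

    def test_hand_computed_r(self):
        r, _ = pearson_with_pvalue([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6, abs=1e-12)

    def test_sign_flip(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        r, _ = pearson_with_pvalue(x, -x)
        assert r == -1.0

    def test_matches_scipy(self):
        from scipy.stats import pearsonr

        rng = np.random.default_rng(3)
        x, y = rng.normal(size=(2, 25))
        r, p = pearson_with_pvalue(x, y)
        ref = pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedScoreError):
            pearson_with_pvalue([1, 1, 1], [1, 2, 3])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_pvalue([1, 2, 3], [1, 2])


class TestSharedMiRNAPValue:
    def test_zero_shared_gives_one(self):
        assert shared_mirna_pvalue(10, 4, 6, 0) == 1.0

    def test_full_overlap_enumeration(self):
        # only one of C(10,5)=252 draws shares all 5
        assert shared_mirna_pvalue(10, 5, 5, 5) == pytest.approx(1 / 252, abs=1e-15)

    def test_small_case_enumeration(self):
        # 1 - C(2,0)C(2,2)/C(4,2) = 1 - 1/6
        assert shared_mirna_pvalue(4, 2, 2, 1) == pytest.approx(5 / 6, abs=1e-15)

    def test_against_exact_enumeration_oracle(self):
        for M in (1, 4, 7, 12):
            for N in range(M + 1):
                for K in range(M + 1):
                    for x in range(min(N, K) + 1):
                        assert shared_mirna_pvalue(M, N, K, x) == pytest.approx(
                            hypergeom_upper_tail_exact(M, N, K, x), abs=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(st.data())
    def test_non_increasing_in_x(self, data):
        M = data.draw(st.integers(2, 20))
        N = data.draw(st.integers(1, M))
        K = data.draw(st.integers(1, M))
        ps = [shared_mirna_pvalue(M, N, K, x) for x in range(min(N, K) + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_invalid_configuration_rejected(self):
        with pytest.raises(ValueError):
            shared_mirna_pvalue(5, 6, 2, 1)
        with pytest.raises(ValueError):
            shared_mirna_pvalue(5, 2, 2, 3)


class TestRegulationPatternScores:
    def test_cosine_identical_direction(self):
        assert cosine_score([0.3, -0.5], [0.3, -0.5]) == pytest.approx(1.0)

    def test_cosine_orthogonal(self):
        assert cosine_score([1, 0], [0, 1]) == 0.0

    def test_cosine_hand_case(self):
        assert cosine_score([0.6, 0.8], [0.8, 0.6]) == pytest.approx(0.96, abs=1e-12)

    def test_cosine_all_zero_rejected(self):
        with pytest.raises(UndefinedScoreError):
            cosine_score([0, 0], [1, 1])

    def test_collaboration_maximal(self):
        assert collaboration_score([1, 1, 1], [1, 1, 1]) == pytest.approx(1.0)

    def test_collaboration_half_cases(self):
        assert collaboration_score([0.5, 0.5], [0.5, 0.5]) == pytest.approx(0.5)
        # 0.75 / (sqrt(3) * sqrt(0.75)) = 0.5
        assert collaboration_score([1, 1, 1], [0.25, 0.25, 0.25]) == \
            pytest.approx(0.5, abs=1e-12)

    def test_collaboration_zero_sum_rejected(self):
        with pytest.raises(UndefinedScoreError):
            collaboration_score([0, 0], [0.5, 0.5])

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8),
           st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8))
    def test_bounds(self, a, b):
        n = min(len(a), len(b))
        a, b = np.array(a[:n]), np.array(b[:n])
        if a.sum() == 0 or b.sum() == 0:
            return
        assert 0.0 <= collaboration_score(a, b) <= 1.0 + 1e-12
        assert -1.0 <= cosine_score(a - 0.5, b - 0.5) <= 1.0 \
            if (a - 0.5).any() and (b - 0.5).any() else True

    @pytest.mark.parametrize("cos,col,expected", [
        (1.0, 1.0, 1.0),
        (0.96, 0.5, 0.73),
        (-1.0, 0.0, -0.5),
    ])
    def test_similarity_is_arithmetic_mean(self, cos, col, expected):
        assert similarity_score(cos, col) == pytest.approx(expected)


class TestRegulationProfiles:
    def test_planted_regulators_recovered(self, small_bundle, small_inference):
        bundle, truth = small_bundle
        _, _, profiles = small_inference
        for cerna, regs in truth.planted_regulators.items():
            assert set(profiles[cerna].regulators) == regs

    def test_cerna_without_measured_regulator_has_no_profile(self):
        expr_mir = ExpressionMatrix(["m1"], ["s1", "s2", "s3"],
                                    [[1.0, 2.0, 3.0]])
        expr_cer = ExpressionMatrix(["G1", "G2"], ["s1", "s2", "s3"],
                                    [[1.0, 0.0, 2.0], [0.0, 1.0, 2.0]])
        from mirscoppi import build_regulation_profiles
        from mirscoppi.datamodel import EdgeList

        targets = EdgeList({("m1", "G1"), ("mX", "G2")}, "mirna_target")
        profiles = build_regulation_profiles(expr_mir, expr_cer, targets)
        assert "G1" in profiles and "G2" not in profiles
        assert profiles["G1"].regulators == ["m1"]


def _planted_fixture(seed=11):
    """A ~20-ceRNA bundle with 2 planted pairs for condition-level checks."""
    return generate_dataset(
        n_mirna=20, n_lncrna=6, n_mrna=14, n_tumor=25, n_normal=25,
        n_pairs=2, shared_per_pair=3, n_decoy_disease=5,
        n_extra_proteins=4, n_background_ppi=4, n_diff_modules=0, seed=seed)


class TestInferSpongeNetwork:
    def test_planted_pairs_recovered_exactly(self, default_config):
        bundle, truth = _planted_fixture()
        net, candidates = sponge_step(bundle, default_config)[:2]
        assert net.edges_of_type("sponge") == truth.planted_sponge_pairs
        accepted = {c.pair for c in candidates if c.accepted}
        assert accepted == truth.planted_sponge_pairs

    def test_pairs_sharing_too_few_mirnas_are_not_candidates(
            self, small_inference, default_config):
        _, candidates, _ = small_inference
        assert all(c.stat.x >= default_config.min_shared_mirnas
                   for c in candidates)

    def test_disease_exclusion_flags_condition_one(self, default_config):
        bundle, truth = _planted_fixture()
        pair = sorted(truth.planted_sponge_pairs)[0]
        reduced = GeneList(bundle.disease_genes.symbols - {pair[0]}, "disease")
        bundle2 = dataclasses.replace(bundle, disease_genes=reduced)
        net, candidates = sponge_step(bundle2, default_config)[:2]
        assert pair not in net.edges_of_type("sponge")
        rec = next(c for c in candidates if c.pair == pair)
        assert not rec.passed_disease and rec.passed_sharing \
            and rec.passed_pattern and rec.passed_positive_corr

    def test_all_four_conditions_match_brute_force(self, small_bundle,
                                                   small_inference,
                                                   default_config):
        """Accepted set == direct evaluation of the four conditions per pair."""
        bundle, _ = small_bundle
        net, candidates, profiles = small_inference
        cfg = default_config
        expected = set()
        for c in candidates:
            ok = (c.pair[0] in bundle.disease_genes
                  and c.pair[1] in bundle.disease_genes
                  and c.stat.x >= cfg.min_shared_mirnas
                  and c.stat.p < cfg.hypergeom_alpha
                  and c.sim is not None and c.sim >= cfg.sim_threshold
                  and c.corr is not None and c.corr > 0
                  and c.corr_p < cfg.corr_alpha)
            if ok:
                expected.add(c.pair)
        assert net.edges_of_type("sponge") == expected

    def test_acceptance_monotone_in_thresholds(self, small_bundle,
                                               small_inference):
        bundle, _ = small_bundle
        _, _, profiles = small_inference
        from mirscoppi.datamodel import concat_expression

        expr = concat_expression(bundle.expr_lncrna, bundle.expr_mrna)
        loose = PipelineConfig(sim_threshold=0.3, hypergeom_alpha=0.05,
                               corr_alpha=0.05)
        strict = PipelineConfig(sim_threshold=0.6, hypergeom_alpha=0.005,
                                corr_alpha=0.005)
        e_loose, _ = infer_sponge_network(profiles, expr, bundle.disease_genes,
                                          loose, lncrna_ids=bundle.lncrna_ids)
        e_strict, _ = infer_sponge_network(profiles, expr, bundle.disease_genes,
                                           strict, lncrna_ids=bundle.lncrna_ids)
        assert e_strict.edges_of_type("sponge") <= e_loose.edges_of_type("sponge")
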