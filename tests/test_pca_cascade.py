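"""Tests for the PCA machinery and the Occam's-razor cascade."""

import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import PCA as SkPCA

from hapticrec.behavioral_prep import ZMatrix, assemble_features
from hapticrec.pca_cascade import assess_salience, dominant_measures, \
    run_cascade, run_pca, select_components


def zmatrix_from(array, measures=None, ids=None) -> ZMatrix:
    array = np.asarray(array, dtype=float)
    measures = measures or [f"m{i}" for i in range(array.shape[1])]
    ids = ids or [f"p{i}" for i in range(array.shape[0])]
    return ZMatrix(data=pd.DataFrame(array, index=ids, columns=measures),
                   oriented={m: True for m in measures})


#: salient-component expression coefficients of the published eight-measure
#: PCA, in measure order (age, lesvol, nih, pso, mac, mic, ppt, tor)
PC83_COEFFICIENTS = [0.054, -0.117, -0.149, -0.473, 0.384, 0.406, -0.213,
                     0.616]
#: salient component of the published terminal three-measure PCA
PC3MAC_COEFFICIENTS = [-0.505, 0.383, 0.774]   # pso, mac, tor


class TestRunPCA:
    def test_invariants_on_cohort(self, impaired_zmatrix):
        z, _, _ = impaired_zmatrix
        res = run_pca(z)
        coef = res.expression_coefficients
        np.testing.assert_allclose(coef.T @ coef, np.eye(coef.shape[1]),
                                   atol=1e-8)
        assert res.variance_fraction.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(res.variance_fraction) <= 1e-12)
        recon = res.patient_scores @ coef.T + res.center
        np.testing.assert_allclose(recon, z.values, atol=1e-8)
        np.testing.assert_allclose(res.project(z.values),
                                   res.patient_scores, atol=1e-8)

    def test_matches_sklearn_up_to_sign(self, impaired_zmatrix):
        z, _, _ = impaired_zmatrix
        res = run_pca(z)
        sk = SkPCA(n_components=8).fit(z.values)
        for j in range(8):
            ours = res.expression_coefficients[:, j]
            theirs = sk.components_[j]
            agreement = abs(float(ours @ theirs))
            assert agreement == pytest.approx(1.0, abs=1e-8)
        np.testing.assert_allclose(res.variance_fraction,
                                   sk.explained_variance_ratio_, atol=1e-10)

    def test_rank_one_data(self):
        direction = np.array([1.0, 2.0, -1.0])
        weights = np.arange(6, dtype=float)[:, None]
        res = run_pca(zmatrix_from(weights * direction))
        assert res.variance_fraction[0] == pytest.approx(1.0)
        assert res.rank_deficient

    def test_three_measure_matrix(self, impaired_zmatrix):
        z, _, _ = impaired_zmatrix
        res = run_pca(assemble_features(z, ["mac0", "pso0", "tor0"]))
        assert res.n_components == 3
        assert res.variance_fraction.sum() == pytest.approx(1.0)

    def test_sign_convention_tor_nonnegative(self, impaired_zmatrix):
        z, _, _ = impaired_zmatrix
        res = run_pca(z)
        tor_row = z.measures.index("tor0")
        assert np.all(res.expression_coefficients[tor_row] >= -1e-12)

    def test_published_loadings_are_unit_vectors(self):
        """The printed expression coefficients are orthonormal-basis
        columns, so they must have unit Euclidean norm."""
        assert np.linalg.norm(PC3MAC_COEFFICIENTS) == pytest.approx(1.0,
                                                                    abs=0.01)
        assert np.linalg.norm(PC83_COEFFICIENTS) == pytest.approx(1.0,
                                                                  abs=0.01)


class TestSelectComponents:
    @pytest.mark.parametrize("fractions, threshold, expected", [
        ((0.5, 0.3, 0.2), 0.8, [0, 1]),
        ((0.85, 0.1, 0.05), 0.8, [0]),
        ((0.5, 0.3, 0.2), 1.0, [0, 1, 2]),
    ])
    def test_prefix_rule(self, fractions, threshold, expected, rng):
        # build data with prescribed variance fractions along axes
        n = 200
        scales = np.sqrt(np.array(fractions))
        data = rng.standard_normal((n, 3)) * scales
        res = run_pca(zmatrix_from(data))
        res.variance_fraction = np.array(fractions)  # exact fractions
        assert select_components(res, threshold) == expected

    def test_invalid_threshold(self, impaired_zmatrix):
        z, _, _ = impaired_zmatrix
        res = run_pca(z)
        with pytest.raises(ValueError):
            select_components(res, 0.0)


class TestAssessSalience:
    def test_separated_scores_give_kw_9_8(self, rng):
        """Perfectly rank-separated patient scores for 7 vs 7 patients give
        the published Kruskal-Wallis chi-square of 9.8."""
        scores = np.concatenate([rng.uniform(2, 3, 7), rng.uniform(0, 1, 7)])
        data = np.column_stack([scores, rng.standard_normal(14)])
        res = run_pca(zmatrix_from(data, measures=["a", "b"]))
        # force component 0 to be the separating axis
        res.patient_scores = np.column_stack([scores, scores * 0])
        labels = np.array(["RTI"] * 7 + ["PTI"] * 7)
        tor9 = np.concatenate([rng.uniform(19, 30, 7), rng.uniform(0, 10, 7)])
        sal = assess_salience(res, 0, tor9, labels)
        assert sal.kw_chi2 == pytest.approx(9.8, abs=0.01)
        assert sal.salient

    def test_constant_scores_not_salient(self, rng):
        data = rng.standard_normal((14, 2))
        res = run_pca(zmatrix_from(data))
        res.patient_scores[:, 1] = 0.0
        labels = np.array(["RTI"] * 7 + ["PTI"] * 7)
        sal = assess_salience(res, 1, rng.normal(size=14), labels)
        assert not sal.salient

    def test_scores_equal_outcome_is_maximally_salient(self, rng):
        tor9 = rng.uniform(0, 30, size=14)
        data = np.column_stack([tor9, rng.standard_normal(14)])
        res = run_pca(zmatrix_from(data))
        res.patient_scores[:, 0] = tor9
        labels = np.array(["RTI"] * 7 + ["PTI"] * 7)
        sal = assess_salience(res, 0, tor9, labels)
        assert sal.r == pytest.approx(1.0)
        assert sal.p < 0.05


class TestDominantMeasures:
    def test_published_eight_measure_reduction(self):
        """Applying the dominance rule to the published salient-component
        coefficients reproduces the published 8 -> 4 reduction to the
        geometrical, timed and object recognition measures."""
        measures = ["age", "lesvol", "nih", "pso0", "mac0", "mic0", "ppt0",
                    "tor0"]
        res = run_pca(zmatrix_from(np.random.default_rng(0)
                                   .standard_normal((14, 8)),
                                   measures=measures))
        res.expression_coefficients[:, 0] = PC83_COEFFICIENTS
        dom = dominant_measures(res, 0)
        assert set(dom) == {"pso0", "mac0", "mic0", "tor0"}

    def test_singleton_and_tie(self, rng):
        res = run_pca(zmatrix_from(rng.standard_normal((10, 4))))
        res.expression_coefficients[:, 0] = [1.0, 0.0, 0.0, 0.0]
        assert dominant_measures(res, 0) == ["m0"]
        res.expression_coefficients[:, 0] = [0.5, -0.5, 0.5, -0.5]
        assert len(dominant_measures(res, 0)) == 4  # termination signal


class TestRunCascade:
    def test_default_cohort_terminal_pattern(self, impaired_zmatrix):
        """On the default synthetic cohort the cascade converges to the
        macrogeometry / picking-time / object-recognition pattern."""
        z, tor9, labels = impaired_zmatrix
        result = run_cascade(z, tor9, labels)
        assert sorted(result.terminal_measures) == ["mac0", "pso0", "tor0"]
        assert not result.inconclusive
        assert result.terminal_stage.salient.kw_p < 0.05
        assert result.terminal_threshold is not None
        # measure sets strictly shrink along the cascade
        sizes = [len(st.measures) for st in result.stages]
        assert sizes == sorted(sizes, reverse=True)
        assert len(set(map(tuple, (st.measures for st in result.stages)))) \
            == len(sizes)

    def test_three_measure_input_single_stage(self, impaired_zmatrix):
        z, tor9, labels = impaired_zmatrix
        sub = assemble_features(z, ["mac0", "pso0", "tor0"])
        result = run_cascade(sub, tor9, labels)
        assert len(result.stages) == 1
        assert sorted(result.terminal_measures) == ["mac0", "pso0", "tor0"]

    def test_single_informative_measure_recovered(self, rng):
        """With one planted informative measure among noise, the terminal
        set contains it."""
        labels = np.array(["RTI"] * 7 + ["PTI"] * 7)
        tor9 = np.concatenate([rng.uniform(19, 30, 7), rng.uniform(0, 10, 7)])
        informative = np.concatenate([rng.normal(3, 1, 7),
                                      rng.normal(-3, 1, 7)])
        data = rng.standard_normal((14, 5)) * 0.8
        data[:, 2] = informative
        result = run_cascade(zmatrix_from(data), tor9, labels)
        assert not result.inconclusive
        assert len(result.terminal_measures) <= 3
        assert "m2" in result.terminal_measures

    def test_uninformative_data_inconclusive(self, rng):
        labels = np.array(["RTI"] * 7 + ["PTI"] * 7)
        tor9 = rng.uniform(0, 30, 14)
        data = rng.standard_normal((14, 6))
        result = run_cascade(zmatrix_from(data), tor9, labels)
        # either inconclusive or (rarely) a chance pattern; must not crash
        assert isinstance(result.inconclusive, bool)

    def test_determinism(self, impaired_zmatrix):
        z, tor9, labels = impaired_zmatrix
        r1 = run_cascade(z, tor9, labels)
        r2 = run_cascade(z, tor9, labels)
        assert r1.terminal_measures == r2.terminal_measures
        assert r1.terminal_threshold == r2.terminal_threshold

    def test_serialization(self, impaired_zmatrix, tmp_path):
        import json
        z, tor9, labels = impaired_zmatrix
        result = run_cascade(z, tor9, labels)
        result.to_json(tmp_path / "cascade.json")
        payload = json.loads((tmp_path / "cascade.json").read_text())
        assert payload["terminal_measures"] == result.terminal_measures
        table = result.summary_table()
        assert len(table) == len(result.stages)


class TestParameterRecovery:
    def test_terminal_set_recovery_across_cohorts(self):
        """Over independently seeded synthetic cohorts the cascade
        recovers the planted three-measure pattern in the majority of
        runs (the full 50-cohort acceptance check lives in the acceptance
        suite)."""
        from hapticrec.behavioral_prep import impute_plegic_pso, to_zscores
        from hapticrec.config import CohortConfig
        from hapticrec.synthetic_cohort import generate_behavioral_cohort, \
            generate_control_reference
        hits = 0
        n = 15
        for seed in range(n):
            cfg = CohortConfig(seed=seed)
            table = impute_plegic_pso(generate_behavioral_cohort(cfg))
            z = to_zscores(table, generate_control_reference(cfg))
            impaired = table[table.subgroup.isin(["PTI", "RTI"])]
            zi = assemble_features(z, z.measures)
            zi.data = zi.data.loc[impaired.patient_id]
            res = run_cascade(zi, impaired["tor9"].to_numpy(float),
                              impaired["subgroup"].to_numpy())
            hits += sorted(res.terminal_measures) == ["mac0", "pso0", "tor0"]
        assert hits >= n // 2
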