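"""EMT scoring orientation, PCA correctness, probe selection/correlation."""

import numpy as np
import pandas as pd
import pytest

from cstyper.emt import (
    emt_score, load_marker_polarity, probe_emt_correlation, score_vs_content,
    top_variance_probes,
)
from cstyper.simulate import generate_expression_methylome


@pytest.fixture(scope="module")
def polarity():
    return load_marker_polarity()


@pytest.fixture(scope="module")
def archetype_matrix(polarity):
    genes = sorted(polarity)
    mes = np.array([polarity[g] == "mesenchymal" for g in genes])
    epithelial = np.where(mes, 0.5, 3.0)
    mesenchymal = np.where(mes, 3.0, 0.5)
    rng = np.random.default_rng(0)
    rows = [epithelial + rng.normal(0, 0.05, len(genes)) for _ in range(5)]
    rows += [mesenchymal + rng.normal(0, 0.05, len(genes)) for _ in range(5)]
    idx = [f"E{i}" for i in range(5)] + [f"M{i}" for i in range(5)]
    return pd.DataFrame(rows, index=idx, columns=genes)


def test_marker_panel_has_81_genes_with_valid_polarity(polarity):
    assert len(polarity) == 81
    assert set(polarity.values()) == {"epithelial", "mesenchymal"}


class TestEmtScore:
    def test_mesenchymal_archetypes_score_higher(self, archetype_matrix):
        res = emt_score(archetype_matrix)
        e_scores = res.scores[:5]
        m_scores = res.scores[5:]
        assert m_scores.min() > e_scores.max()
        assert res.scores.mean() == pytest.approx(0.0, abs=1e-9)

    def test_duplicated_samples_get_identical_scores(self, archetype_matrix):
        dup = pd.concat([archetype_matrix, archetype_matrix.iloc[[0]].rename(index={"E0": "E0b"})])
        res = emt_score(dup)
        assert res.scores["E0"] == pytest.approx(res.scores["E0b"])

    def test_matches_independent_pca_oracle(self, archetype_matrix):
        sklearn_pca = pytest.importorskip("sklearn.decomposition")
        res = emt_score(archetype_matrix)
        pca = sklearn_pca.PCA(n_components=1).fit(archetype_matrix.to_numpy())
        oracle_scores = pca.transform(archetype_matrix.to_numpy())[:, 0]
        # PC1 is defined up to sign; align before comparing
        sign = np.sign(np.dot(oracle_scores, res.scores.to_numpy()))
        np.testing.assert_allclose(res.scores, sign * oracle_scores, atol=1e-8)
        assert res.variance_explained == pytest.approx(
            pca.explained_variance_ratio_[0], abs=1e-8)

    def test_score_differences_invariant_to_per_gene_shifts(self, archetype_matrix):
        res = emt_score(archetype_matrix)
        shifted = archetype_matrix + np.random.default_rng(1).normal(0, 5, archetype_matrix.shape[1])
        res2 = emt_score(shifted)
        d1 = res.scores - res.scores.iloc[0]
        d2 = res2.scores - res2.scores.iloc[0]
        np.testing.assert_allclose(d1, d2, atol=1e-8)

    def test_gene_order_permutation_invariant(self, archetype_matrix):
        permuted = archetype_matrix.sample(frac=1, axis=1, random_state=3)
        np.testing.assert_allclose(
            emt_score(archetype_matrix).scores, emt_score(permuted).scores, atol=1e-8
        )

    def test_missing_genes_rejected_unless_subset_allowed(self, archetype_matrix):
        partial = archetype_matrix.drop(columns=["VIM", "CDH1"])
        with pytest.raises(ValueError, match="VIM"):
            emt_score(partial)
        res = emt_score(partial, allow_subset=True)
        assert len(res.loadings) == 79


class TestScoreVsContent:
    def test_monotone_scores_give_rho_one(self):
        frac = np.linspace(0, 1, 10)
        res = score_vs_content(frac * 2 - 1, frac)
        assert res["rho"] == pytest.approx(1.0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            score_vs_content([1, 2], [0.1, 0.2])


class TestTopVarianceProbes:
    def test_top_fraction_selected(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {f"s{j}": rng.normal(0, 1, 10) * np.arange(1, 11) for j in range(6)},
            index=[f"cg{i}" for i in range(10)],
        )
        top = top_variance_probes(df, fraction=0.2)
        assert len(top) == 2
        variances = df.var(axis=1)
        assert set(top) == set(variances.nlargest(2).index)

    def test_constant_probes_never_beat_variable_ones(self):
        df = pd.DataFrame({"s1": [0.5, 0.1], "s2": [0.5, 0.9]}, index=["const", "var"])
        assert top_variance_probes(df, fraction=0.5) == ["var"]

    def test_stable_under_sample_permutation(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.random((20, 8)),
                          index=[f"cg{i}" for i in range(20)],
                          columns=[f"s{j}" for j in range(8)])
        assert top_variance_probes(df) == top_variance_probes(df[df.columns[::-1]])


class TestProbeEmtCorrelation:
    def test_probe_tracking_score_ranks_first(self):
        scores = pd.Series(np.arange(8, dtype=float), index=[f"s{j}" for j in range(8)])
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {f"s{j}": [j / 10, rng.random(), rng.random()] for j in range(8)},
            index=["tracker", "noise1", "noise2"],
        )
        out = probe_emt_correlation(df, scores)
        assert out.iloc[0]["probe"] == "tracker"
        assert out.iloc[0]["rho"] == pytest.approx(1.0)

    def test_independent_probe_has_small_average_rho(self):
        rng = np.random.default_rng(4)
        scores = pd.Series(rng.normal(size=40), index=[f"s{j}" for j in range(40)])
        df = pd.DataFrame(rng.random((30, 40)), index=[f"cg{i}" for i in range(30)],
                          columns=scores.index)
        out = probe_emt_correlation(df, scores)
        assert abs(out["rho"].mean()) < 0.15


class TestGeneratedMixtures:
    def test_noise_free_mixtures_rank_exactly_by_fraction(self):
        expr, _, truth = generate_expression_methylome(
            n_samples=25, seed=5, expression_noise=0.0)
        scores = emt_score(expr).scores
        order_by_score = scores.sort_values().index
        order_by_frac = truth.set_index("sample_id")["sarcoma_fraction"].sort_values().index
        assert list(order_by_score) == list(order_by_frac)

    def test_coupled_probes_rank_top_in_correlation(self):
        expr, betas, truth = generate_expression_methylome(n_samples=60, seed=6)
        scores = emt_score(expr).scores
        top = top_variance_probes(betas)
        assert all(f"cg_mir200_{i+1}" in top for i in range(6))
        corr = probe_emt_correlation(betas.loc[top], scores)
        assert set(corr.head(6)["probe"]) == {f"cg_mir200_{i+1}" for i in range(6)}

    def test_generator_mixing_direction_matches_rho_sign(self):
        expr, _, truth = generate_expression_methylome(n_samples=40, seed=7)
        scores = emt_score(expr).scores
        res = score_vs_content(scores, truth.set_index("sample_id")["sarcoma_fraction"])
        assert res["rho"] > 0.8
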