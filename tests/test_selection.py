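"""Kruskal–Wallis screening, canonical variate analysis and feature classes."""

import numpy as np
import pandas as pd
import pytest

from memdyn.selection import (
    classify_features,
    cva_load_scores,
    fit_cva,
    kruskal_wallis,
    select_features,
)
from memdyn.simulate import TableSimSpec, generate_feature_table, make_plan

from .oracles import kruskal_h
from scipy import stats


class TestKruskalWallis:
    def test_closed_form_example(self):
        """Three tie-free groups {1,2,3},{4,5,6},{7,8,9} have H = 7.2."""
        h, _ = stats.kruskal([1, 2, 3], [4, 5, 6], [7, 8, 9])
        assert h == pytest.approx(7.2)
        assert kruskal_h([[1, 2, 3], [4, 5, 6], [7, 8, 9]]) == pytest.approx(7.2)
        raw, adj = kruskal_wallis([np.array([1, 2, 3]), np.array([4, 5, 6]),
                                   np.array([7, 8, 9])])
        assert raw == pytest.approx(float(stats.chi2.sf(7.2, 2)))
        assert adj == pytest.approx(min(1.0, raw * 150))

    def test_identical_groups(self):
        g = np.array([5.0, 5.0, 5.0])
        raw, adj = kruskal_wallis([g, g, g])
        assert raw == 1.0 and adj == 1.0

    def test_matches_rank_oracle_on_random_groups(self, rng):
        for _ in range(20):
            sizes = rng.integers(3, 8, size=3)
            pool = rng.choice(1000, size=sizes.sum(), replace=False).astype(float)
            groups = np.split(pool, np.cumsum(sizes)[:-1])
            h_expected = kruskal_h([g.tolist() for g in groups])
            h_scipy, _ = stats.kruskal(*groups)
            assert h_scipy == pytest.approx(h_expected)

    def test_type_one_error_calibrated(self, rng):
        alpha, reps, n = 0.05, 500, 200
        rej = 0
        for _ in range(reps):
            raw, _ = kruskal_wallis([rng.normal(size=n) for _ in range(3)], family=1)
            rej += raw < alpha
        ci = 3 * np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rej / reps - alpha) < ci


def two_feature_groups(rng, n_per_group=1000, separation=2.0):
    """Three groups whose means differ along feature 1 only."""
    frames = []
    for g, mu in enumerate([-separation, 0.0, separation]):
        frames.append(pd.DataFrame({
            "f1": rng.normal(mu, 1.0, n_per_group),
            "f2": rng.normal(0.0, 1.0, n_per_group),
        }))
    X = pd.concat(frames, ignore_index=True)
    y = np.repeat([1, 3, 5], n_per_group)
    return X, y


class TestFitCva:
    def test_discriminating_feature_dominates_first_vector(self, rng):
        X, y = two_feature_groups(rng, n_per_group=1500)
        model = fit_cva(X, y)
        v = model.vectors[:, 0]
        assert abs(v[1] / v[0]) < 0.05

    def test_identical_group_means_give_null_eigenvalues(self, rng):
        X, y = two_feature_groups(rng, separation=0.0)
        model = fit_cva(X, y)
        assert (np.abs(model.eigenvalues) < 0.05).all()

    def test_unit_within_group_variance_normalization(self, rng):
        X, y = two_feature_groups(rng)
        model = fit_cva(X, y, standardize=True)
        sd = X.std(axis=0, ddof=1).to_numpy()
        Z = (X.to_numpy() - X.to_numpy().mean(axis=0)) / sd
        scores = Z @ model.vectors[:, 0]
        pooled = np.concatenate([
            scores[y == g] - scores[y == g].mean() for g in (1, 3, 5)
        ])
        assert pooled @ pooled / (len(scores) - 3) == pytest.approx(1.0, rel=1e-8)

    def test_generalized_eigen_residual(self, rng):
        from memdyn.selection import _scatter_matrices

        X, y = two_feature_groups(rng)
        model = fit_cva(X, y, standardize=False)
        B, W = _scatter_matrices(X.to_numpy(), y)
        for lam, v in zip(model.eigenvalues, model.vectors.T):
            resid = np.linalg.solve(W, B @ v) - lam * v
            assert np.linalg.norm(resid) < 1e-8

    def test_single_group_rejected(self, rng):
        X, _ = two_feature_groups(rng, n_per_group=10)
        with pytest.raises(ValueError, match="two groups"):
            fit_cva(X, np.ones(len(X)))


class TestCvaLoadScores:
    def test_planted_strong_feature_ranks_first(self):
        spec = TableSimSpec(
            n_cells=30, frames_per_cell=100, n_features=30,
            archetype_plan=make_plan(30, speed_only=1, effect=10.0), seed=2,
        )
        table, _ = generate_feature_table(spec)
        from memdyn.archetypes import assign_quintiles

        q = assign_quintiles(table["cell_speed"].to_numpy())
        keep = np.isin(q, (1, 3, 5))
        model = fit_cva(table[table.attrs["feature_columns"]][keep], q[keep])
        scores = cva_load_scores(model)
        assert scores["cva_score"].idxmax() == "speed_f000"
        assert scores.loc["speed_f000", "top_half"]

    def test_top_half_size_and_tie_inclusivity(self):
        model_scores = np.array([4.0, 3.0, 2.0, 2.0, 1.0, 0.5])

        class Fake:
            feature_names = [f"f{i}" for i in range(6)]
            loads = np.sqrt(model_scores)[:, None]

        df = cva_load_scores(Fake())
        # top half of 6 is 3; f3 ties f2's boundary score and is included
        assert df["top_half"].tolist() == [True, True, True, True, False, False]


class TestClassifyFeatures:
    def test_pass_patterns_map_to_classes(self):
        idx = pd.Index(["a", "b", "c", "d"], name="feature")
        kw_s = pd.Series([1e-5, 1e-5, 0.5, 1e-5], index=idx)
        kw_c = pd.Series([0.5, 1e-5, 1e-5, 1e-5], index=idx)
        top_s = pd.Series([True, True, True, False], index=idx)
        top_c = pd.Series([True, True, True, True], index=idx)
        out = classify_features(kw_s, kw_c, top_s, top_c)
        assert out["class"].tolist() == ["speed_only", "both", "cmd_only", "cmd_only"]

    def test_end_to_end_planted_class_recovery(self):
        spec = TableSimSpec(
            n_cells=30, frames_per_cell=100, n_features=60,
            archetype_plan=make_plan(60, speed_only=3, cmd_only=3, both=3, effect=5.0),
            seed=5,
        )
        table, truth = generate_feature_table(spec)
        res = select_features(table)
        assert res.class_counts["speed_only"] == 3
        assert res.class_counts["cmd_only"] == 3
        assert res.class_counts["both"] == 3
        merged = res.per_feature.join(truth.set_index("feature")["expected_class"])
        planted = merged[merged["expected_class"] != "neither"]
        assert (planted["class"] == planted["expected_class"]).all()

    def test_selection_monotone_in_effect_size(self):
        """A planted feature never leaves the selected set as its effect grows."""
        selected = []
        for effect in (0.5, 1.5, 3.0, 5.0, 8.0):
            plan = make_plan(30, speed_only=1, effect=effect)
            table, _ = generate_feature_table(
                TableSimSpec(n_cells=25, frames_per_cell=80, n_features=30,
                             archetype_plan=plan, seed=7)
            )
            res = select_features(table)
            selected.append(res.per_feature.loc["speed_f000", "class"] == "speed_only")
        first_true = selected.index(True) if True in selected else len(selected)
        assert all(selected[first_true:])
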