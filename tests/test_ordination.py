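"""Dissimilarities, NMDS behaviour, environmental fits and permutation tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from ethnosurvey.model import IncidenceMatrix
from ethnosurvey.ordination import (
    DissimilarityMatrix,
    bray_curtis,
    envfit_factor,
    envfit_table,
    envfit_vector,
    nmds_embed,
)

from conftest import make_dataset


def _inc(values, ids=None):
    values = np.asarray(values, dtype=float)
    return IncidenceMatrix(
        informant_ids=ids or [f"I{i}" for i in range(values.shape[0])],
        item_ids=[f"S{j}" for j in range(values.shape[1])],
        values=values,
        mode="plant_space",
        binarized=False,
    )


def _dissim(points):
    points = np.asarray(points, dtype=float)
    return DissimilarityMatrix(
        ids=[f"I{i}" for i in range(len(points))],
        values=squareform(pdist(points)),
        metric="euclidean",
    )


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        d = bray_curtis(_inc([[1, 2, 3], [1, 2, 3]]))
        assert d.values[0, 1] == pytest.approx(0.0)

    def test_disjoint_rows_one(self):
        d = bray_curtis(_inc([[1, 1, 0], [0, 0, 2]]))
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_hand_computed_half(self):
        d = bray_curtis(_inc([[1, 0, 1], [0, 1, 1]]))
        assert d.values[0, 1] == pytest.approx(0.5)

    def test_two_all_zero_rows_instruct_exclusion(self):
        with pytest.raises(ValueError, match="drop_zero_rows"):
            bray_curtis(_inc([[0, 0], [0, 0], [1, 1]]))

    def test_range_symmetry_zero_diagonal(self, synth_dataset):
        from ethnosurvey.model import build_incidence_matrix

        inc = build_incidence_matrix(synth_dataset, "plant_space").drop_zero_rows()
        d = bray_curtis(inc)
        assert (d.values >= 0).all() and (d.values <= 1 + 1e-12).all()
        assert np.allclose(d.values, d.values.T)
        assert np.allclose(np.diag(d.values), 0)


class TestNmds:
    def test_unit_square_embeds_exactly(self):
        res = nmds_embed(_dissim([[0, 0], [1, 0], [1, 1], [0, 1]]), k=2, n_restarts=4, seed=0)
        assert res.stress <= 1e-4

    def test_collinear_points_near_zero_stress(self):
        res = nmds_embed(_dissim([[0, 0], [1, 0], [2, 0]]), k=2, n_restarts=2, seed=0)
        assert res.stress <= 1e-6

    def test_stress_monotone_and_beats_classical_start(self):
        rng = np.random.default_rng(3)
        d = squareform(pdist(rng.random((8, 5))))
        res = nmds_embed(
            DissimilarityMatrix(ids=list(range(8)), values=d, metric="euclidean"),
            k=2,
            n_restarts=5,
            seed=1,
        )
        hist = np.asarray(res.stress_history)
        assert np.all(np.diff(hist) <= 1e-9)
        assert res.stress <= hist[0] + 1e-12

    def test_recovers_embeddable_configuration_up_to_procrustes(self):
        from scipy.spatial import procrustes

        rng = np.random.default_rng(5)
        truth = rng.random((12, 2))
        res = nmds_embed(_dissim(truth), k=2, n_restarts=8, seed=2)
        _, _, disparity = procrustes(truth, res.scores)
        assert disparity < 1e-3

    def test_scores_centered_and_pc_rotated(self, plant_ordination):
        x = plant_ordination.scores
        assert np.allclose(x.mean(axis=0), 0, atol=1e-9)
        cov = x.T @ x
        assert abs(cov[0, 1]) < 1e-6 * cov[0, 0]

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            nmds_embed(_dissim([[0, 0], [1, 1]]), k=2)

    def test_seed_reproducibility(self):
        d = _dissim(np.random.default_rng(0).random((9, 3)))
        a = nmds_embed(d, k=2, n_restarts=3, seed=11)
        b = nmds_embed(d, k=2, n_restarts=3, seed=11)
        assert np.allclose(a.scores, b.scores)
        assert a.stress == b.stress


def _toy_ordination(n=100, seed=0, k=2):
    rng = np.random.default_rng(seed)
    scores = rng.standard_normal((n, k))
    scores -= scores.mean(axis=0)
    from ethnosurvey.ordination import OrdinationResult

    return OrdinationResult(
        ids=[f"I{i}" for i in range(n)],
        scores=scores,
        k=k,
        stress=0.1,
        n_restarts=1,
        converged=True,
        seed=seed,
    )


class TestEnvfitVector:
    def test_axis_aligned_covariate_perfect_fit(self):
        ordn = _toy_ordination(60, seed=1)
        fit = envfit_vector(ordn, ordn.scores[:, 0], n_perm=99, seed=0, name="ax1")
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert abs(fit.direction[0]) == pytest.approx(1.0, abs=1e-9)
        assert fit.p == pytest.approx(1 / 100)

    def test_r2_equals_ols_closed_form(self):
        rng = np.random.default_rng(7)
        ordn = _toy_ordination(80, seed=2)
        y = 0.3 * ordn.scores[:, 0] + rng.standard_normal(80)
        fit = envfit_vector(ordn, y, n_perm=9, seed=0)
        x = np.column_stack([np.ones(80), ordn.scores])
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        r2_ols = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert fit.r2 == pytest.approx(r2_ols, abs=1e-10)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            envfit_vector(_toy_ordination(20), np.ones(20), n_perm=9)

    def test_missing_values_dropped_pairwise_with_warning(self):
        ordn = _toy_ordination(30, seed=3)
        y = ordn.scores[:, 0].copy()
        y[:5] = np.nan
        with pytest.warns(UserWarning, match="dropped"):
            fit = envfit_vector(ordn, y, n_perm=9, seed=0)
        assert fit.n_used == 25

    def test_p_floor_and_seed_invariance(self):
        ordn = _toy_ordination(50, seed=4)
        y = ordn.scores[:, 1]
        for seed in (0, 1, 2):
            fit = envfit_vector(ordn, y, n_perm=999, seed=seed)
            assert fit.p >= 1 / 1000
            assert fit.p == pytest.approx(0.001)
        a = envfit_vector(ordn, y + 0.0, n_perm=99, seed=5)
        b = envfit_vector(ordn, y + 0.0, n_perm=99, seed=5)
        assert a.p == b.p

    def test_null_type_one_error_calibrated(self):
        """Whole-vector shuffles give a uniform p on its grid under the null."""
        rng = np.random.default_rng(10)
        ordn = _toy_ordination(50, seed=6)
        rejections = 0
        n_rep = 500
        for i in range(n_rep):
            y = rng.standard_normal(50)
            fit = envfit_vector(ordn, y, n_perm=99, seed=int(rng.integers(2**31)))
            rejections += fit.p <= 0.05
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rejections / n_rep - 0.05) < 1.96 * se + 1e-12


class TestEnvfitFactor:
    def test_separated_levels_high_r2_floor_p(self):
        ordn = _toy_ordination(40, seed=8)
        levels = np.where(ordn.scores[:, 0] > np.median(ordn.scores[:, 0]), "hi", "lo")
        ordn.scores[:, 0] += np.where(levels == "hi", 10.0, -10.0)
        ordn.scores -= ordn.scores.mean(axis=0)
        fit = envfit_factor(ordn, levels, n_perm=999, seed=0)
        assert fit.r2 > 0.9
        assert fit.p == pytest.approx(0.001)
        assert set(fit.centroids) == {"hi", "lo"}

    def test_identical_levels_near_zero_r2(self):
        ordn = _toy_ordination(200, seed=9)
        levels = np.array(["a", "b"] * 100)
        fit = envfit_factor(ordn, levels, n_perm=199, seed=0)
        assert fit.r2 < 0.05
        assert fit.p > 0.05

    def test_single_level_rejected(self):
        with pytest.raises(ValueError, match="levels"):
            envfit_factor(_toy_ordination(10), ["x"] * 10, n_perm=9)

    def test_singleton_levels_flagged_degenerate(self):
        ordn = _toy_ordination(5, seed=10)
        with pytest.warns(UserWarning, match="degenerate"):
            fit = envfit_factor(ordn, [f"L{i}" for i in range(5)], n_perm=9, seed=0)
        assert fit.degenerate
        assert fit.r2 == pytest.approx(1.0)


class TestEnvfitTable:
    def test_all_regions_run_attempts_five_variables(self, synth_dataset, plant_ordination):
        fits, failures = envfit_table(
            plant_ordination, synth_dataset.informants, n_perm=49, seed=0
        )
        attempted = {f.variable for f in fits} | set(failures)
        assert attempted == {"elevation_m", "age", "gender", "region", "community"}
        assert len(fits) == 5  # default synthetic age coverage passes the threshold

    def test_single_region_excludes_region_factor(self):
        rows = [(f"I{i}", f"S{i % 4}", "food") for i in range(12)]
        informants = [
            (f"I{i}", "SJ", f"c{i % 3}", 1000 + 100 * (i % 3), ["female", "male"][i % 2], 40)
            for i in range(12)
        ]
        ds = make_dataset(rows, informant_rows=informants)
        from ethnosurvey.model import build_incidence_matrix

        inc = build_incidence_matrix(ds, "plant_space").drop_zero_rows()
        res = nmds_embed(bray_curtis(inc), k=2, n_restarts=3, seed=0)
        fits, failures = envfit_table(res, ds.informants, n_perm=19, seed=0)
        assert "region" not in {f.variable for f in fits} | set(failures)

    def test_low_age_coverage_skips_age(self, synth_dataset, plant_ordination):
        fits, failures = envfit_table(
            plant_ordination, synth_dataset.informants, n_perm=19, seed=0, age_coverage=0.99
        )
        assert "age" in failures and "coverage" in failures["age"]
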