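"""Group model, Moran's I, distance decay and acceleration tests."""

import json
import math
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from betachron import (
    ValidationError,
    acceleration_test,
    distance_decay,
    fit_group_model,
    morans_i,
)
from betachron.dissimilarity import BetaSeries, PairwiseBeta
from betachron.inference import (
    EARTH_RADIUS_KM,
    haversine_km,
    inverse_distance_weights,
)


def make_summaries(n_per_group=10, effect=0.0, seed=0, metric="median_beta_jac"):
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    flags = np.repeat([False, True], n_per_group)
    values = rng.normal(0.4, 0.05, n) + effect * flags
    return pd.DataFrame(
        {
            "study_id": [f"s{i}" for i in range(n)],
            "alien_flag": flags,
            "latitude": rng.uniform(-40, 60, n),
            "longitude": rng.uniform(-120, 150, n),
            metric: values,
        }
    )


class TestGroupModel:
    def test_exact_linear_recovery(self):
        """Invaded values exactly 0.2 above uninvaded, no residual variance."""
        df = make_summaries(n_per_group=6, effect=0.0, seed=1)
        df["median_beta_jac"] = 0.3 + 0.2 * df["alien_flag"].astype(float)
        res = fit_group_model(df, "median_beta_jac")
        assert res.alien.coef == pytest.approx(0.2, abs=1e-10)
        assert res.n == 12

    def test_identical_groups_null(self):
        df = make_summaries(n_per_group=8, effect=0.0, seed=2)
        # mirror values so the two groups are literally identical
        half = df.iloc[:8]["median_beta_jac"].to_numpy()
        df["median_beta_jac"] = np.concatenate([half, half])
        df["latitude"] = np.tile(df["latitude"].iloc[:8].to_numpy(), 2)
        df["longitude"] = np.tile(df["longitude"].iloc[:8].to_numpy(), 2)
        res = fit_group_model(df, "median_beta_jac")
        assert res.alien.coef == pytest.approx(0.0, abs=1e-12)
        assert res.alien.p == pytest.approx(1.0, abs=1e-9)

    def test_one_group_only_is_degenerate(self):
        df = make_summaries(n_per_group=5)
        df["alien_flag"] = True
        with pytest.raises(ValidationError, match="degenerate"):
            fit_group_model(df, "median_beta_jac")

    def test_rank_deficiency_names_column(self):
        df = make_summaries(n_per_group=5, seed=3)
        df["longitude"] = 12.0  # constant -> collinear with the intercept
        with pytest.raises(ValidationError, match="longitude"):
            fit_group_model(df, "median_beta_jac")

    def test_missing_response_column(self):
        with pytest.raises(ValidationError, match="median_rank_diff"):
            fit_group_model(make_summaries(), "median_rank_diff")

    def test_covariate_terms_reported(self):
        df = make_summaries(n_per_group=10, seed=4)
        df["median_beta_jac"] += 0.001 * df["longitude"]
        res = fit_group_model(df, "median_beta_jac")
        assert set(res.terms) == {"intercept", "alien_flag", "latitude", "longitude"}
        assert res.terms["longitude"].coef == pytest.approx(0.001, rel=0.5)


class TestMoransI:
    def coords(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return np.column_stack([rng.uniform(-40, 60, n), rng.uniform(-120, 150, n)])

    def test_expected_value_closed_form(self):
        rng = np.random.default_rng(5)
        res = morans_i(rng.normal(size=11), self.coords(11, seed=5))
        assert res.expected == pytest.approx(-0.1)

    def test_invariance_to_affine_value_changes(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=20)
        c = self.coords(20, seed=6)
        base = morans_i(x, c)
        shifted = morans_i(x + 100.0, c)
        scaled = morans_i(3.5 * x, c)
        for other in (shifted, scaled):
            assert other.I == pytest.approx(base.I, abs=1e-12)
            assert other.p == pytest.approx(base.p, abs=1e-12)

    def test_permutation_null_mean(self):
        """Mean of I over label permutations ~ -1/(n-1) (permutation oracle)."""
        n, n_perm = 30, 1000
        rng = np.random.default_rng(7)
        x = rng.normal(size=n)
        c = self.coords(n, seed=7)
        w = inverse_distance_weights(c)
        sims = np.empty(n_perm)
        for i in range(n_perm):
            sims[i] = morans_i(rng.permutation(x), weights=w).I
        expected = -1 / (n - 1)
        assert abs(sims.mean() - expected) < 3 * sims.std(ddof=1) / np.sqrt(n_perm)

    def test_clustered_values_detected(self):
        """Two spatial clusters with cluster-constant values -> positive I."""
        rng = np.random.default_rng(8)
        c1 = np.column_stack([rng.normal(10, 0.5, 15), rng.normal(10, 0.5, 15)])
        c2 = np.column_stack([rng.normal(-30, 0.5, 15), rng.normal(120, 0.5, 15)])
        coords = np.vstack([c1, c2])
        values = np.concatenate([np.full(15, 1.0), np.full(15, 2.0)])
        values += rng.normal(0, 1e-3, 30)  # break exact constancy within clusters
        res = morans_i(values, coords)
        assert res.I > res.expected
        assert res.p < 0.05

    def test_degenerate_inputs_rejected(self):
        c = self.coords(10, seed=9)
        with pytest.raises(ValidationError, match="constant"):
            morans_i(np.ones(10), c)
        with pytest.raises(ValidationError, match="n >= 3"):
            morans_i([1.0, 2.0], c[:2])
        with pytest.raises(ValidationError, match="coincident"):
            morans_i(np.arange(5.0), np.tile([[10.0, 20.0]], (5, 1)))

    def test_matches_r_ape_reference(self, tmp_path):
        """Cross-check I, sd and p against the ape implementation in R."""
        rng = np.random.default_rng(10)
        n = 12
        x = rng.normal(size=n)
        coords = self.coords(n, seed=10)
        w = inverse_distance_weights(coords)
        ours = morans_i(x, weights=w, row_standardize=True)
        np.savetxt(tmp_path / "x.txt", x)
        np.savetxt(tmp_path / "w.txt", w)
        script = tmp_path / "moran.R"
        script.write_text(
            'x <- scan("%s"); w <- matrix(scan("%s"), nrow=%d, byrow=TRUE)\n'
            "res <- ape::Moran.I(x, w)\n"
            'cat(jsonlite::toJSON(res, digits=12))\n'
            % (tmp_path / "x.txt", tmp_path / "w.txt", n)
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)],
            capture_output=True, text=True, check=True,
        )
        ref = {k: v[0] for k, v in json.loads(out.stdout).items()}
        assert ours.I == pytest.approx(ref["observed"], abs=1e-9)
        assert ours.expected == pytest.approx(ref["expected"], abs=1e-12)
        assert ours.sd == pytest.approx(ref["sd"], abs=1e-9)
        assert ours.p == pytest.approx(ref["p.value"], abs=1e-9)


class TestDistanceDecay:
    def test_antipodal_distance(self):
        d = haversine_km(0.0, 0.0, 0.0, 180.0)
        assert d == pytest.approx(math.pi * EARTH_RADIUS_KM, rel=1e-12)

    def test_monotone_construction_gives_rho_one(self):
        # sites on one meridian at positions with all pairwise gaps distinct
        # (no ties): value differences proportional to distance give rho = 1
        lat = np.array([0.0, 1.0, 3.0, 7.0, 12.0, 20.0, 30.0, 44.0])
        coords = np.column_stack([lat, np.zeros(8)])
        values = 0.01 * lat
        _, rho, p = distance_decay(values, coords)
        assert rho == pytest.approx(1.0)
        assert p < 0.01

    def test_identical_values_give_nan_with_warning(self):
        coords = np.column_stack([np.linspace(0, 50, 6), np.zeros(6)])
        with pytest.warns(UserWarning, match="degenerate"):
            table, rho, p = distance_decay(np.full(6, 0.5), coords)
        assert math.isnan(rho) and math.isnan(p)
        assert (table["abs_diff"] == 0).all()
        assert len(table) == 15  # all unordered pairs

    def test_spearman_matches_rank_then_pearson(self):
        """scipy's rho equals brute-force rank-transform + Pearson."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(4, 21))
            x, y = rng.normal(size=n), rng.normal(size=n)
            rho = stats.spearmanr(x, y).statistic
            brute = stats.pearsonr(stats.rankdata(x), stats.rankdata(y)).statistic
            assert rho == pytest.approx(brute, abs=1e-12)


def beta_series_with(values, study_id="s"):
    pairs = tuple(
        PairwiseBeta(
            year_from=2000 + i, year_to=2001 + i, gap=1,
            a=1, b=1, c=1, beta_jac=v, beta_jtu=v, beta_jne=0.0,
        )
        for i, v in enumerate(values)
    )
    return BetaSeries(study_id=study_id, pairs=pairs)


class TestAcceleration:
    def test_three_censuses_not_applicable(self):
        res = acceleration_test(beta_series_with([0.1, 0.2]))
        assert res.applicable is False
        assert math.isnan(res.rho)

    def test_monotone_increase_gives_rho_one(self):
        res = acceleration_test(beta_series_with([0.1, 0.2, 0.3, 0.4]))
        assert res.applicable
        assert res.rho == pytest.approx(1.0)

    def test_constant_dissimilarity_is_nan_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            res = acceleration_test(beta_series_with([0.3, 0.3, 0.3]))
        assert res.applicable
        assert math.isnan(res.rho)
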