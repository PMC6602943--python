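"""Rankit standardisation, exponential rank transform, domains and index."""

import numpy as np
import pandas as pd
import pytest
import sympy

from ahah import ValidationError, construct_index, diagnostics, exp_transform, rankit
from ahah.index_construction import (
    build_index,
    decile_from_rank,
    domain_score,
    ordinal_ranks,
    orient,
)
from ahah.indicators import CATEGORIES, INDICATOR_NAMES, SPEC_BY_NAME


def phi_inv_hp(p) -> float:
    """High-precision standard normal quantile via sympy's erfinv."""
    return float(sympy.sqrt(2) * sympy.erfinv(2 * sympy.Rational(p) - 1).evalf(30))


def exp_transform_hp(R) -> float:
    """High-precision evaluation of X = -23 ln(1 - R(1 - e^(-100/23)))."""
    Rr = sympy.Rational(R)
    return float(
        (-23 * sympy.log(1 - Rr * (1 - sympy.exp(sympy.Rational(-100, 23))))).evalf(30)
    )


class TestOrient:
    def test_flip_negates_distances(self):
        s = pd.Series([1.0, 5.0, 10.0])
        out = orient(s, SPEC_BY_NAME["fastfood"])
        assert list(out) == [-1.0, -5.0, -10.0]
        assert out.idxmax() == 0  # the 1 km zone is now least healthy

    def test_keep_is_identity(self):
        s = pd.Series([1.0, 5.0])
        assert orient(s, SPEC_BY_NAME["gp"]).equals(s)

    def test_green_flip(self):
        s = pd.Series([0.0, 1e4])
        out = orient(s, SPEC_BY_NAME["green"])
        assert list(out) == [0.0, -1e4]


class TestRankit:
    def test_single_value_maps_to_zero(self):
        assert rankit([3.7]) == pytest.approx([0.0], abs=1e-15)

    def test_three_values_match_quantile_oracle(self):
        scores = rankit([10.0, -2.0, 5.0])
        expect = {phi_inv_hp(sympy.Rational(1, 6)), 0.0, phi_inv_hp(sympy.Rational(5, 6))}
        assert phi_inv_hp(sympy.Rational(5, 6)) == pytest.approx(0.9674, abs=1e-4)
        for got, want in zip(sorted(scores), sorted(expect)):
            assert got == pytest.approx(want, abs=1e-10)

    @pytest.mark.parametrize("n", [2, 5, 17, 100])
    def test_matches_high_precision_oracle(self, n):
        rng = np.random.default_rng(n)
        values = rng.normal(size=n)
        scores = rankit(values)
        ranks = np.argsort(np.argsort(values)) + 1
        for r, s in zip(ranks, scores):
            assert abs(s - phi_inv_hp(sympy.Rational(2 * int(r) - 1, 2 * n))) < 1e-10

    def test_antisymmetric_for_distinct_values(self):
        scores = np.sort(rankit(np.random.default_rng(1).normal(size=41)))
        assert np.allclose(scores, -scores[::-1], atol=1e-12)
        assert abs(scores.mean()) < 1e-6

    def test_ties_get_average_ranks(self):
        scores = rankit([1.0, 1.0, 2.0])
        # tied pair shares rank 1.5 -> Phi^-1(1/3)
        assert scores[0] == scores[1] == pytest.approx(phi_inv_hp(sympy.Rational(1, 3)), abs=1e-12)

    def test_applying_twice_is_identity(self):
        values = np.random.default_rng(2).normal(size=30)
        once = rankit(values)
        assert np.array_equal(rankit(once), once)

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValidationError, match="non-finite"):
            rankit(pd.Series([1.0, np.nan], index=["Za", "Zb"]))


class TestExpTransform:
    def test_full_rank_is_exactly_100(self):
        assert abs(exp_transform(1.0) - 100.0) < 1e-9

    def test_vanishes_at_zero(self):
        assert 0 < exp_transform(1e-9) < 1e-6

    def test_midpoint_matches_high_precision_oracle(self):
        assert exp_transform(0.5) == pytest.approx(15.647, abs=1e-3)
        assert exp_transform(0.5) == pytest.approx(
            exp_transform_hp(sympy.Rational(1, 2)), abs=1e-12
        )

    def test_strictly_increasing_on_grid(self):
        grid = np.linspace(1e-6, 1.0, 10_000)
        x = exp_transform(grid)
        assert np.all(np.diff(x) > 0)
        assert np.all((x > 0) & (x <= 100.0 + 1e-12))

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.0001, np.nan])
    def test_domain_errors(self, bad):
        with pytest.raises(ValidationError):
            exp_transform(bad)


class TestDomainScore:
    def _scores(self, n=50, seed=3):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.normal(size=(n, 14)),
            index=[f"Z{i:03d}" for i in range(n)],
            columns=list(INDICATOR_NAMES),
        )

    def test_identical_columns_return_that_column(self):
        df = self._scores()
        for c in ["gambling", "offlicence", "tobacconist", "pubs"]:
            df[c] = df["fastfood"]
        out = domain_score(df, "retail")
        assert np.allclose(out, df["fastfood"])

    def test_opposite_columns_cancel(self):
        df = self._scores()
        df["gambling"] = -df["fastfood"]
        df["tobacconist"] = -df["pubs"]
        df["offlicence"] = 0.0
        assert np.allclose(domain_score(df, "retail"), 0.0, atol=1e-15)

    def test_matches_independent_row_mean(self):
        df = self._scores()
        out = domain_score(df, "health")
        cols = ["gp", "hospital", "pharmacy", "dentist", "leisure"]
        for z in df.index:
            assert out[z] == pytest.approx(sum(df.loc[z, c] for c in cols) / 5, rel=1e-12)

    def test_missing_indicator_named(self):
        df = self._scores().drop(columns=["pharmacy"])
        with pytest.raises(ValidationError, match="pharmacy"):
            domain_score(df, "health")


class TestRanksAndDeciles:
    def test_ordinal_ranks_tie_break_by_zone_code(self):
        s = pd.Series([1.0, 1.0, 0.5], index=["Zb", "Za", "Zc"])
        r = ordinal_ranks(s)
        assert r["Zc"] == 1 and r["Za"] == 2 and r["Zb"] == 3

    def test_deciles_partition_evenly_at_100(self):
        ranks = np.arange(1, 101)
        deciles = decile_from_rank(ranks, 100)
        assert all(np.bincount(deciles)[1:] == 10)

    def test_decile_sizes_differ_by_at_most_one(self):
        for n in (37, 50, 101):
            counts = np.bincount(decile_from_rank(np.arange(1, n + 1), n))[1:]
            assert counts.max() - counts.min() <= 1


class TestBuildIndex:
    def test_all_worst_domains_give_index_100(self):
        df = pd.DataFrame(
            {"retail_X": [100.0], "health_X": [100.0], "physical_X": [100.0]},
            index=pd.Index(["Z0"], name="zone_code"),
        )
        out = build_index(df)
        assert out.loc["Z0", "index_score"] == 100.0

    def test_single_zone_degenerate_case(self):
        table = pd.DataFrame(
            [np.arange(14) + 1.0], columns=list(INDICATOR_NAMES),
            index=pd.Index(["Z0"], name="zone_code"),
        )
        res = construct_index(table)
        d = res.domains
        assert d.loc["Z0", "index_score"] == pytest.approx(100.0)
        assert d.loc["Z0", "index_decile"] == 1

    def test_missing_domain_named(self):
        df = pd.DataFrame({"retail_X": [10.0], "health_X": [10.0]},
                          index=pd.Index(["Z0"], name="zone_code"))
        with pytest.raises(ValidationError, match="physical"):
            build_index(df)


class TestPipelineInvariance:
    def test_km_to_miles_changes_nothing_downstream(self, default_components):
        """Strictly monotone rescaling of every distance indicator leaves
        all ranks, R, X, index scores and deciles identical."""
        base = construct_index(default_components)
        scaled = default_components.copy()
        for c in CATEGORIES:
            scaled[c] = scaled[c] * 0.621371
        other = construct_index(scaled)
        pd.testing.assert_frame_equal(base.domains, other.domains)
        pd.testing.assert_frame_equal(base.component_deciles, other.component_deciles)


class TestCancellationResistance:
    def test_exponential_index_penalises_one_bad_domain(self):
        """A zone best-ranked in two domains but worst in one must sit
        further above its linear rank-average than an all-middling zone."""
        N = 10
        mid = np.array([0.5, 0.5, 0.5])
        spiky = np.array([1 / N, 1 / N, 1.0])
        gap_mid = exp_transform(mid).mean() - 100 * mid.mean()
        gap_spiky = exp_transform(spiky).mean() - 100 * spiky.mean()
        assert gap_spiky > gap_mid


class TestDiagnostics:
    def test_self_correlation_is_one(self, default_components):
        corr = diagnostics(default_components)
        assert np.allclose(np.diag(corr), 1.0)

    def test_negated_column_gives_minus_one(self, default_components):
        t = default_components.copy()
        t["gp"] = -t["fastfood"]
        corr = diagnostics(t)
        assert corr.loc["gp", "fastfood"] == pytest.approx(-1.0)

    def test_zero_variance_column_is_undefined_not_propagated(self, tmp_path):
        from ahah.io import UNDEFINED_MARKER, write_csv_table

        t = pd.DataFrame(
            {c: np.random.default_rng(0).uniform(1, 5, 20) for c in INDICATOR_NAMES},
            index=pd.Index([f"Z{i:03d}" for i in range(20)], name="zone_code"),
        )
        t["so2"] = 1.0  # constant
        corr = diagnostics(t)
        assert corr.loc["so2"].drop("so2").isna().all()
        assert corr.loc["fastfood", "pubs"] == corr.loc["fastfood", "pubs"]  # not NaN
        path = tmp_path / "corr.csv"
        write_csv_table(corr.rename_axis("indicator").reset_index(), path)
        assert UNDEFINED_MARKER in path.read_text()

    def test_distance_indicators_positively_correlated(self, default_components):
        """Services and hazards co-cluster in the urban core, so all 10
        distance indicators correlate positively across zones."""
        corr = diagnostics(default_components)[list(CATEGORIES)].loc[list(CATEGORIES)]
        off_diag = corr.values[np.triu_indices(len(CATEGORIES), 1)]
        assert (off_diag > 0).all()

    def test_spearman_supported(self, default_components):
        corr = diagnostics(default_components, method="spearman")
        assert np.allclose(np.diag(corr), 1.0)
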