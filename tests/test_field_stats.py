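"""Survey statistics against closed-form and enumeration oracles."""

import numpy as np
import pandas as pd
import pytest

import reefspectra as rs


def make_survey(rug_a, biom_a, rug_p, biom_p, regions_a=None, regions_p=None):
    """Survey from per-treatment rugosity/biomass vectors."""
    rows = []
    for i, (r, b) in enumerate(zip(rug_a, biom_a)):
        reg = regions_a[i] if regions_a else f"ra{i % 2}"
        rows.append(("a%d" % i, reg, "absent", r, b))
    for i, (r, b) in enumerate(zip(rug_p, biom_p)):
        reg = regions_p[i] if regions_p else f"rp{i % 2}"
        rows.append(("p%d" % i, reg, "present", r, b))
    return pd.DataFrame(
        rows, columns=["site_id", "region", "mangrove_status", "rugosity", "carnivore_biomass"]
    )


class TestRugosityRegression:
    def test_exact_recovery_on_collinear_points(self):
        rug = np.array([1.0, 1.5, 2.0, 2.5, 3.0])
        biom = 10.0 ** (3.20 + 0.589 * rug)
        df = make_survey(rug, biom, [1.0, 2.0, 3.0], [100.0, 120.0, 90.0])
        fit = rs.rugosity_regression(df, "absent")
        assert fit.slope == pytest.approx(0.589, abs=1e-10)
        assert fit.intercept == pytest.approx(3.20, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.p_value < 1e-6

    def test_constant_biomass_flat_fit(self):
        df = make_survey([1.0, 2.0, 3.0], [50.0] * 3, [1.0, 2.0, 3.0], [40.0, 45.0, 50.0])
        fit = rs.rugosity_regression(df, "absent")
        assert fit.slope == 0.0 and fit.r_squared == 0.0

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        rug = 1.0 + 2.0 * rng.random(10)
        biom = 10.0 ** (2.0 + 0.3 * rug + rng.normal(0, 0.2, 10))
        df = make_survey(rug, biom, [1.0, 2.0, 3.0], [10.0, 20.0, 30.0])
        fit = rs.rugosity_regression(df, "absent")
        # brute-force normal equations
        y = np.log10(biom)
        x = np.column_stack([np.ones(10), rug])
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        assert fit.intercept == pytest.approx(beta[0], rel=1e-9)
        assert fit.slope == pytest.approx(beta[1], rel=1e-9)

    def test_too_few_points(self):
        df = make_survey([1.0, 2.0], [10.0, 20.0], [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match=">= 3"):
            rs.rugosity_regression(df, "absent")


class TestVarianceContrast:
    def test_exchangeable_treatments_tie(self):
        vals = [10.0, 20.0, 30.0, 40.0]
        df = make_survey([1, 2, 3, 4], vals, [1, 2, 3, 4], vals)
        out = rs.variance_contrast(df)
        assert out.median_abs_z_absent == pytest.approx(out.median_abs_z_present)
        assert out.p_value == pytest.approx(1.0)

    def test_dispersed_treatment_has_larger_median(self):
        tight = [99.0, 100.0, 101.0, 100.5]
        spread = [10.0, 60.0, 150.0, 300.0]
        df = make_survey([1, 2, 3, 4], tight, [1, 2, 3, 4], spread)
        out = rs.variance_contrast(df)
        assert out.median_abs_z_present > out.median_abs_z_absent
        assert out.more_dispersed == "present"

    def test_z_scores_standardised_by_construction(self):
        rng = np.random.default_rng(1)
        df = make_survey(
            1 + 2 * rng.random(6), 10 ** rng.normal(2, 0.4, 6),
            1 + 2 * rng.random(6), 10 ** rng.normal(2, 0.8, 6),
        )
        z = rs.variance_contrast(df).z_scores
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_u_statistic_matches_all_pairs_count(self):
        biom_a = [12.0, 55.0, 70.0, 130.0]
        biom_p = [8.0, 40.0, 95.0, 260.0]
        df = make_survey([1, 2, 3, 4], biom_a, [1, 2, 3, 4], biom_p)
        out = rs.variance_contrast(df)
        z = out.z_scores
        abs_a = np.abs(z[df["mangrove_status"] == "absent"].to_numpy())
        abs_p = np.abs(z[df["mangrove_status"] == "present"].to_numpy())
        u_brute = sum(
            1.0 if a > b else (0.5 if a == b else 0.0) for a in abs_a for b in abs_p
        )
        assert out.u_statistic == pytest.approx(u_brute)

    def test_degenerate_zero_sd(self):
        df = make_survey([1, 2], [5.0, 5.0], [1, 2], [5.0, 5.0])
        with pytest.raises(ValueError, match="SD"):
            rs.variance_contrast(df)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(3)
        df = make_survey(
            1 + 2 * rng.random(5), 10 ** rng.normal(2, 0.3, 5),
            1 + 2 * rng.random(5), 10 ** rng.normal(2, 0.6, 5),
        )
        a = rs.variance_contrast(df)
        b = rs.variance_contrast(df.sample(frac=1.0, random_state=0))
        assert a.p_value == pytest.approx(b.p_value)
        assert a.median_abs_z_absent == pytest.approx(b.median_abs_z_absent)


class TestConfoundCheck:
    def test_identical_distributions_not_significant(self):
        rug = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        regions = ["r1", "r1", "r1", "r2", "r2", "r2"]
        df = make_survey(rug, [10.0] * 6, rug, [20.0] * 6, regions, ["r3", "r3", "r3", "r4", "r4", "r4"])
        out = rs.rugosity_confound_check(df)
        assert out.statistic == pytest.approx(0.0, abs=1e-12)
        assert out.p_value == pytest.approx(1.0)

    def test_region_mean_aggregation_on_two_region_toy(self):
        df = make_survey(
            [1.0, 3.0, 2.0, 4.0], [10.0] * 4,
            [1.5, 2.5, 2.0, 3.0], [20.0] * 4,
            ["r1", "r1", "r2", "r2"], ["r3", "r3", "r4", "r4"],
        )
        out = rs.rugosity_confound_check(df)
        assert out.mean_rugosity_absent == pytest.approx(np.mean([2.0, 3.0]))
        assert out.mean_rugosity_present == pytest.approx(np.mean([2.0, 2.5]))

    def test_shifted_distributions_detected(self):
        # regions differ by 3 site-level SDs: the region-mean test should
        # reject at the 1% level in nearly every realisation
        n_sig = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n_reg, per = 5, 6
            rug_a = np.concatenate([np.clip(2.0 + 0.2 * rng.standard_normal(per), 1.0, None) for _ in range(n_reg)])
            rug_p = np.concatenate([np.clip(2.6 + 0.2 * rng.standard_normal(per), 1.0, None) for _ in range(n_reg)])
            regions_a = [f"ra{k // per}" for k in range(n_reg * per)]
            regions_p = [f"rp{k // per}" for k in range(n_reg * per)]
            df = make_survey(rug_a, [10.0 + k for k in range(30)], rug_p,
                             [10.0 + k for k in range(30)], regions_a, regions_p)
            if rs.rugosity_confound_check(df).p_value < 0.01:
                n_sig += 1
        assert n_sig >= 19

    def test_single_region_insufficient(self):
        df = make_survey([1.0, 2.0], [1.0, 2.0], [1.0, 2.0], [3.0, 4.0],
                         ["r1", "r1"], ["r2", "r2"])
        with pytest.raises(ValueError, match="regions"):
            rs.rugosity_confound_check(df)


class TestValidation:
    def test_mixed_status_region_rejected(self):
        df = make_survey([1.0, 2.0, 3.0], [1, 2, 3], [1.0, 2.0, 3.0], [1, 2, 3],
                         ["r1", "r1", "r1"], ["r1", "r2", "r2"])
        with pytest.raises(ValueError, match="mixed"):
            rs.validate_survey(df)

    def test_subunit_rugosity_rejected(self):
        df = make_survey([0.5, 2.0, 3.0], [1, 2, 3], [1.0, 2.0, 3.0], [1, 2, 3])
        with pytest.raises(ValueError, match="rugosity"):
            rs.validate_survey(df)
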