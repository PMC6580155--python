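"""Synthetic cohort generator: mixture draws, calibration, reproducibility."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from propcontest.cohort import (
    CohortConfig,
    CohortConfigError,
    ConditionParams,
    calibrate_condition,
    default_config,
    draw_bid,
    generate_cohort,
    mixture_moments,
    read_cohort,
    write_cohort,
    _DEFAULT_TARGETS,
)


class TestDrawBid:
    def test_degenerate_point_mass(self, rng):
        p = ConditionParams("x", p_eq=1.0, mu=30, sigma_u=0, sigma_eps=5)
        assert all(draw_bid(p, 0.0, rng) == 20.0 for _ in range(20))

    def test_noiseless_continuous(self, rng):
        p = ConditionParams("x", p_eq=0.0, mu=31, sigma_u=0, sigma_eps=0)
        assert all(draw_bid(p, 0.0, rng) == 31.0 for _ in range(5))

    def test_truncation_keeps_bids_in_bounds(self, rng):
        p = ConditionParams("x", p_eq=0.0, mu=78, sigma_u=0, sigma_eps=6)
        draws = [draw_bid(p, 0.0, rng) for _ in range(300)]
        assert max(draws) <= 80.0 and min(draws) >= 0.0

    def test_integer_mode_rounds(self, rng):
        p = ConditionParams("x", p_eq=0.0, mu=30, sigma_u=0, sigma_eps=8)
        draws = [draw_bid(p, 0.0, rng, integer=True) for _ in range(50)]
        assert all(float(d).is_integer() for d in draws)

    def test_degenerate_center_outside_bounds_rejected(self, rng):
        p = ConditionParams("x", p_eq=0.0, mu=79, sigma_u=0, sigma_eps=0)
        with pytest.raises(CohortConfigError):
            draw_bid(p, 5.0, rng)  # center 84 with zero noise


class TestGenerateCohort:
    def test_default_dimensions(self, default_cohort):
        assert len(default_cohort) == 1800
        counts = default_cohort.groupby("condition")["participant_id"].nunique()
        assert (counts == 30).all()
        per_participant = default_cohort.groupby("participant_id")["period"].count()
        assert (per_participant == 20).all()

    def test_all_equilibrium_config(self):
        conds = tuple(
            ConditionParams(label, p_eq=1.0, mu=30, sigma_u=0, sigma_eps=5)
            for label in ("anodal", "cathodal", "sham")
        )
        cfg = replace(default_config(seed=3), conditions=conds)
        t = generate_cohort(cfg)
        assert (t["bid"] == 20.0).all()

    def test_seed_determinism_byte_identical_csv(self, tmp_path):
        cfg = replace(default_config(seed=42), participants_per_condition=5, periods=4)
        p1 = write_cohort(generate_cohort(cfg), tmp_path / "a.csv", config=cfg)
        p2 = write_cohort(generate_cohort(cfg), tmp_path / "b.csv", config=cfg)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seeds_differ(self):
        a = generate_cohort(default_config(seed=1))
        b = generate_cohort(default_config(seed=2))
        assert not np.array_equal(a["bid"], b["bid"])

    def test_demographics_constant_within_participant(self, small_cohort):
        for col in ("female", "age", "major", "gpa", "income"):
            assert (small_cohort.groupby("participant_id")[col].nunique() == 1).all()

    def test_positive_intraclass_correlation(self):
        """sigma_u > 0 must induce dependence of bids within participants."""
        cfg = replace(default_config(seed=11), participants_per_condition=150)
        t = generate_cohort(cfg)
        t = t[t["condition"] == "sham"]
        grand = t["bid"].mean()
        between = t.groupby("participant_id")["bid"].mean().var(ddof=1)
        within = t.groupby("participant_id")["bid"].var(ddof=1).mean()
        # between-participant variance of means exceeds the pure within-noise floor
        assert between > within / 20 * 1.5

    def test_invalid_config_rejected(self):
        with pytest.raises(CohortConfigError):
            CohortConfig(participants_per_condition=0)
        with pytest.raises(CohortConfigError):
            ConditionParams("x", p_eq=1.5, mu=30, sigma_u=1, sigma_eps=1)


class TestCalibration:
    @pytest.mark.parametrize("label", ["anodal", "cathodal", "sham"])
    def test_moment_match_at_default_parameters(self, label):
        """Frozen defaults reproduce their calibration targets."""
        target_mean, target_sd, p_eq = _DEFAULT_TARGETS[label]
        params = next(c for c in default_config().conditions if c.label == label)
        assert params.p_eq == p_eq
        mean, sd = mixture_moments(params)
        assert mean == pytest.approx(target_mean, abs=1e-3)
        assert sd == pytest.approx(target_sd, abs=1e-3)

    def test_calibrate_roundtrip(self):
        params = calibrate_condition("x", 28.0, 9.5, 0.15)
        mean, sd = mixture_moments(params)
        assert mean == pytest.approx(28.0, abs=1e-6)
        assert sd == pytest.approx(9.5, abs=1e-6)

    def test_empirical_moments_converge_to_configured_targets(self):
        """Large cohort: empirical mean/SD approach the numeric mixture moments."""
        cfg = replace(default_config(seed=5), participants_per_condition=400)
        t = generate_cohort(cfg)
        for params in cfg.conditions:
            bids = t.loc[t["condition"] == params.label, "bid"]
            mean, sd = mixture_moments(params)
            assert bids.mean() == pytest.approx(mean, abs=0.25)
            assert bids.std(ddof=1) == pytest.approx(sd, abs=0.35)

    def test_equilibrium_share_converges_to_p_eq(self):
        cfg = replace(default_config(seed=6), participants_per_condition=400)
        t = generate_cohort(cfg)
        for params in cfg.conditions:
            bids = t.loc[t["condition"] == params.label, "bid"]
            frac = (bids == 20.0).mean()
            # continuous component hits exactly 20 with probability 0
            assert frac == pytest.approx(params.p_eq, abs=0.02)


class TestIO:
    def test_roundtrip_and_sidecar(self, tmp_path, small_cohort):
        cfg = default_config(seed=7)
        path = write_cohort(small_cohort, tmp_path / "cohort.csv", config=cfg)
        back = read_cohort(path)
        pd.testing.assert_frame_equal(
            back, small_cohort, check_exact=False, rtol=1e-9
        )
        meta = path.with_suffix(".meta.json")
        assert meta.exists()
        assert '"seed": 7' in meta.read_text()

    def test_schema_error_lists_missing_columns(self, tmp_path):
        bad = pd.DataFrame({"participant_id": ["a"], "bid": [20.0]})
        bad.to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(ValueError, match="condition"):
            read_cohort(tmp_path / "bad.csv")
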