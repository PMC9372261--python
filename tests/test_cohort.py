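"""Synthetic cohort generator: determinism, moments, structure, contamination."""

import io

import numpy as np
import pandas as pd
import pytest

from modmod import (
    ConfigurationError,
    GeneratorConfig,
    discretize_to_items,
    equation_moments,
    fit_interaction,
    generate_cohort,
    generate_latents,
    write_cohort,
)
from modmod.cohort import DEFAULT_COEFFICIENTS, SCALE_ORDER
from modmod.scales import SCALES, item_columns, score_frame
from modmod.screening import exclusion_flags


def _csv_bytes(frame):
    buf = io.StringIO()
    write_cohort(frame, buf)
    return buf.getvalue()


class TestConfigValidation:
    def test_non_positive_definite_correlations_rejected(self):
        bad = np.array([[1, 0.9, -0.9], [0.9, 1, 0.9], [-0.9, 0.9, 1]])
        with pytest.raises(ConfigurationError, match="positive definite"):
            GeneratorConfig(latent_correlations=bad).validate()

    def test_contamination_rates_must_sum_below_one(self):
        cfg = GeneratorConfig(contamination={"incomplete": 0.6, "patterned": 0.5})
        with pytest.raises(ConfigurationError, match="sum to < 1"):
            cfg.validate()

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        cfg = GeneratorConfig(n_respondents=50, seed=9,
                              contamination={"incomplete": 0.1})
        path = tmp_path / "gen.yaml"
        path.write_text(yaml.safe_dump(cfg.to_mapping()))
        loaded = GeneratorConfig.from_yaml(path)
        assert loaded.to_mapping() == cfg.to_mapping()


class TestDeterminism:
    def test_same_config_same_seed_byte_identical(self):
        cfg = GeneratorConfig(
            n_respondents=300, seed=42, contamination={"incomplete": 0.05}
        )
        assert _csv_bytes(generate_cohort(cfg)) == _csv_bytes(generate_cohort(cfg))

    def test_contamination_does_not_perturb_clean_records(self):
        clean = generate_cohort(GeneratorConfig(n_respondents=400, seed=13))
        dirty = generate_cohort(
            GeneratorConfig(
                n_respondents=400, seed=13, contamination={"incomplete": 0.05}
            )
        )
        untouched = ~exclusion_flags(dirty).any(axis=1)
        pd.testing.assert_frame_equal(
            clean.loc[untouched], dirty.loc[untouched]
        )


class TestLatents:
    def test_noiseless_additive_limit_is_exact(self):
        coefs = DEFAULT_COEFFICIENTS.copy()
        coefs[[3, 5, 6, 7]] = 0.0  # no interactions
        cfg = GeneratorConfig(
            n_respondents=200, seed=1, true_coefficients=coefs, noise_sd=1e-12
        )
        lat = generate_latents(cfg)
        fitted = fit_interaction(lat["x"], lat["m"], lat["y"], w=lat["w"])
        np.testing.assert_allclose(fitted.params, coefs, atol=1e-9)
        assert fitted.r_squared == pytest.approx(1.0)

    def test_refit_recovers_generating_coefficients(self):
        cfg = GeneratorConfig(n_respondents=50_000, seed=2)
        lat = generate_latents(cfg)
        fitted = fit_interaction(lat["x"], lat["m"], lat["y"], w=lat["w"])
        np.testing.assert_allclose(
            fitted.params, cfg.true_coefficients, atol=0.02
        )

    def test_identity_correlations_give_independent_predictors(self):
        cfg = GeneratorConfig(
            n_respondents=10_000, seed=3, latent_correlations=np.eye(3)
        )
        lat = generate_latents(cfg)
        corr = np.corrcoef(lat[["x", "m", "w"]].to_numpy(), rowvar=False)
        off_diag = corr[np.triu_indices(3, 1)]
        assert np.all(np.abs(off_diag) < 0.03)

    def test_analytic_outcome_moments_match_simulation(self):
        cfg = GeneratorConfig(n_respondents=200_000, seed=4)
        lat = generate_latents(cfg)
        mean, sd = equation_moments(
            cfg.latent_correlations, cfg.true_coefficients, cfg.noise_sd
        )
        assert lat["y"].mean() == pytest.approx(mean, abs=0.01)
        assert lat["y"].std(ddof=1) == pytest.approx(sd, abs=0.01)


class TestDiscretize:
    @pytest.mark.parametrize(
        "scale,total,expected_items",
        [("dep", 0, 0), ("dep", 27, 3)],
    )
    def test_boundary_totals_pin_all_items(self, scale, total, expected_items):
        items = discretize_to_items([total], SCALES[scale], 0)
        assert (items == expected_items).all()

    def test_binary_scale_total_is_count_of_ones(self):
        items = discretize_to_items([13], SCALES["fs"], 0)
        assert items.sum() == 13
        assert set(items.ravel()) <= {0, 1}

    def test_sums_preserved_and_in_range(self, rng):
        totals = rng.uniform(-5, 40, size=200)
        scale = SCALES["is"]
        items = discretize_to_items(totals, scale, 11)
        clipped = np.clip(np.rint(totals), 0, 36)
        np.testing.assert_array_equal(items.sum(axis=1), clipped)
        assert items.min() >= scale.item_min and items.max() <= scale.item_max

    def test_same_seed_identical(self):
        totals = np.linspace(0, 36, 50)
        a = discretize_to_items(totals, SCALES["is"], 5)
        b = discretize_to_items(totals, SCALES["is"], 5)
        np.testing.assert_array_equal(a, b)


class TestMomentAndStructureRecovery:
    def test_scale_moments_recovered(self, clean_cohort):
        scores = score_frame(clean_cohort)
        cfg = GeneratorConfig()
        n = len(scores)
        for name in SCALE_ORDER:
            mean, sd = cfg.scale_means[name], cfg.scale_sds[name]
            mc_se_mean = sd / np.sqrt(n)
            mc_se_sd = sd / np.sqrt(2 * n)
            assert abs(scores[name].mean() - mean) < 3 * mc_se_mean, name
            assert abs(scores[name].std(ddof=1) - sd) < 3 * mc_se_sd, name

    def test_correlation_round_trip(self, clean_scores):
        r = np.corrcoef(
            clean_scores[["is", "dep"]].to_numpy(dtype=float), rowvar=False
        )[0, 1]
        assert r == pytest.approx(0.399, abs=0.05)


class TestContamination:
    def test_class_counts_exact(self):
        cfg = GeneratorConfig(
            n_respondents=1000,
            seed=6,
            contamination={"incomplete": 0.02, "straight_line": 0.013,
                           "patterned": 0.007},
        )
        flags = exclusion_flags(generate_cohort(cfg))
        assert int(flags["incomplete"].sum()) == 20
        assert int(flags["straight_line"].sum()) == 13
        assert int(flags["patterned"].sum()) == 7
        # each contaminated record violates exactly one rule
        assert int(flags.sum(axis=1).max()) == 1

    def test_incomplete_records_bear_missing_items(self):
        cfg = GeneratorConfig(
            n_respondents=1000, seed=8, contamination={"incomplete": 0.02}
        )
        cohort = generate_cohort(cfg)
        item_cols = [c for c in cohort.columns if c not in ("id", "gender")]
        n_missing = int(cohort[item_cols].isna().any(axis=1).sum())
        assert n_missing == 20

    def test_too_much_contamination_for_n_rejected(self):
        # rates sum below 1 but the rounded class counts exceed n
        cfg = GeneratorConfig(
            n_respondents=2,
            contamination={"incomplete": 0.26, "straight_line": 0.26,
                           "patterned": 0.26},
        )
        with pytest.raises(ConfigurationError, match="too small"):
            generate_cohort(cfg)


def test_gender_fraction_matches_configuration(clean_cohort):
    frac = (clean_cohort["gender"] == "female").mean()
    assert frac == pytest.approx(0.5965, abs=3 * np.sqrt(0.6 * 0.4 / len(clean_cohort)))
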