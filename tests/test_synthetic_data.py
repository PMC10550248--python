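"""Generator determinism, back-solving and structural guarantees."""

import dataclasses
from datetime import date

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crossfence.core_io import ConfigError, validate_cadence
from crossfence.growth import vb_curve
from crossfence.synthetic_data import (
    EviSimSpec,
    PopulationSpec,
    default_population_specs,
    gen_evi,
    gen_landmarks,
    gen_specimens,
    symmetric_template,
)
from crossfence.demography import age_from_molar_index


class TestGenSpecimens:
    def test_counts_and_female_fraction_envelope(self):
        specs = default_population_specs()
        records = gen_specimens(specs, seed=101)
        counts = records.groupby("property").size()
        assert counts["dingoes_rare"] == 115 and counts["dingoes_common"] == 51
        for pop, spec in specs.items():
            n_f = ((records["property"] == pop) & (records["sex"] == "female")).sum()
            lo = stats.binom.ppf(0.005, spec.n, spec.female_prop)
            hi = stats.binom.ppf(0.995, spec.n, spec.female_prop)
            assert lo <= n_f <= hi, pop

    def test_molar_index_inverts_age(self):
        records = gen_specimens(default_population_specs(), seed=5)
        np.testing.assert_allclose(
            age_from_molar_index(records["molar_index"].to_numpy()),
            records["age_days"],
            rtol=1e-10,
        )

    def test_zero_noise_traits_sit_on_generating_curves(self):
        specs = default_population_specs()
        for spec in specs.values():
            spec.noise_sd = {t: 0.0 for t in spec.noise_sd}
        records = gen_specimens(specs, seed=7)
        for pop, spec in specs.items():
            sub = records[records["property"] == pop]
            for trait in ("cranial_size", "weight_kg", "pes_length_cm"):
                for sex in ("female", "male"):
                    s = sub[sub["sex"] == sex]
                    expected = vb_curve(s["age_years"], *spec.vb_params[trait][sex])
                    np.testing.assert_allclose(s[trait], expected, rtol=1e-12)

    def test_same_seed_identical_tables(self):
        a = gen_specimens(default_population_specs(), seed=3)
        b = gen_specimens(default_population_specs(), seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_ages_respect_population_ranges(self):
        specs = default_population_specs()
        records = gen_specimens(specs, seed=9)
        for pop, spec in specs.items():
            ages = records.loc[records["property"] == pop, "age_years"]
            lo, hi = spec.age_range_years
            assert ages.between(lo, hi).all()

    def test_degenerate_age_range_rejected(self):
        with pytest.raises(ConfigError, match="age range"):
            PopulationSpec(
                name="x", n=10, female_prop=0.5, age_range_years=(2.0, 2.0),
                vb_params={}, noise_sd={},
            )


class TestGenLandmarks:
    def test_fixed_seed_identical_coordinates(self, small_records):
        a = gen_landmarks(small_records, seed=9)
        b = gen_landmarks(small_records, seed=9)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.coordinates, cb.coordinates)

    def test_centroid_size_matches_cranial_trait(self, small_records):
        from crossfence.morphometrics import centroid_size

        configs = gen_landmarks(small_records, seed=9)
        sizes = np.array([centroid_size(c) for c in configs])
        np.testing.assert_allclose(sizes, small_records["cranial_size"], rtol=1e-9)

    def test_negative_asym_sd_rejected(self, small_records):
        with pytest.raises(ConfigError, match="asym_sd"):
            gen_landmarks(small_records, asym_sd=-0.1)

    def test_template_is_mirror_symmetric(self):
        template, pairing = symmetric_template(14)
        refl = template * np.array([-1.0, 1.0, 1.0])
        for left, right in pairing.pairs:
            np.testing.assert_allclose(template[left], refl[right], atol=1e-12)
        np.testing.assert_allclose(template[list(pairing.midline), 0], 0.0, atol=1e-12)

    def test_template_too_small_rejected(self):
        with pytest.raises(ConfigError, match="k >= 8"):
            symmetric_template(6)


class TestGenEvi:
    def test_observation_count_arithmetic(self):
        # 2 cells/site over 11 years at 16-day cadence:
        # 2 sites * 2 cells * ceil(11 * 365.25 / 16) = 4 * 252 rows
        spec = EviSimSpec(n_cells_per_site=2, start=date(2011, 1, 1), end=date(2022, 1, 1))
        df = gen_evi(spec, seed=1)
        assert len(df) == 2 * 2 * int(np.ceil(11 * 365.25 / 16))

    def test_cadence_is_exactly_16_days(self):
        df = gen_evi(EviSimSpec(n_cells_per_site=1), seed=2)
        assert validate_cadence(df) == 16

    def test_no_offset_no_noise_sites_identical(self):
        spec = EviSimSpec(n_cells_per_site=1, site_offset=0.0, noise_sd=0.0)
        df = gen_evi(spec, seed=3)
        north = df[df["site"] == "north"]["evi"].to_numpy()
        south = df[df["site"] == "south"]["evi"].to_numpy()
        np.testing.assert_array_equal(north, south)

    def test_fixed_seed_identical_output(self):
        a = gen_evi(EviSimSpec(), seed=4)
        b = gen_evi(EviSimSpec(), seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_negative_values_retained(self):
        df = gen_evi(EviSimSpec(baseline=0.0, noise_sd=0.1), seed=5)
        assert (df["evi"] < 0).any()

    def test_end_before_start_rejected(self):
        with pytest.raises(ConfigError, match="must follow"):
            EviSimSpec(start=date(2020, 1, 1), end=date(2019, 1, 1))

    def test_offset_onset_limits_offset(self):
        onset = date(2016, 1, 1)
        spec = EviSimSpec(n_cells_per_site=1, site_offset=0.5, noise_sd=0.0,
                          offset_onset=onset)
        df = gen_evi(spec, seed=6)
        wide = df.pivot(index="date", columns="site", values="evi")
        gap = wide["south"] - wide["north"]
        assert np.allclose(gap[wide.index < pd.Timestamp(onset)], 0.0)
        assert np.allclose(gap[wide.index >= pd.Timestamp(onset)], 0.5)


class TestPipelineRecovery:
    """Generated data pushed through the estimators recovers its own truth."""

    def test_vb_parameters_recovered_within_three_se(self):
        from crossfence.growth import fit_vb

        spec = default_population_specs()["dingoes_rare"]
        spec = dataclasses.replace(spec, n=150, female_prop=0.999)  # ~all female
        records = gen_specimens({"dingoes_rare": spec}, seed=77)
        females = records[records["sex"] == "female"]
        fit = fit_vb(females["age_years"], females["weight_kg"])
        truth = spec.vb_params["weight_kg"]["female"]
        for name, tval in zip(("L_inf", "k_growth", "t0"), truth):
            assert abs(fit.params[name] - tval) < 3 * fit.se[name], name

    def test_site_offset_detected_reliably(self):
        """A 1-sd site offset is flagged at alpha=0.05 in >=9 of 10 runs."""
        from crossfence.vegetation import clamp_nonnegative, seasonal_anomaly, site_anomaly_test

        base = EviSimSpec()
        spec = dataclasses.replace(base, site_offset=1.0 * base.marginal_noise_sd)
        rejections = 0
        for i in range(10):
            evi = gen_evi(spec, seed=300 + i)
            anomalies = seasonal_anomaly(clamp_nonnegative(evi).observations)
            res = site_anomaly_test(anomalies, n_iter=199, seed=i)
            rejections += res.p <= 0.05
        assert rejections >= 9
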