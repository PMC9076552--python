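import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cysexpose import exposure_quant as eq
from cysexpose import synthetic_data as sd
from cysexpose.exposure_quant import (
    Chromatogram,
    LabelScheme,
    LabelStep,
    SCHEMES,
    channel_proportions,
    exposure_fraction,
    fit_standard_curve,
    integrate_xic,
    quantify,
    resolve_scheme,
)


class TestIntegrateXic:
    def test_rectangular_pulse(self):
        # height 50, width 2 (rt window clips exactly to the pulse)
        t = np.arange(0.0, 10.01, 0.1)
        inten = np.where((t >= 2) & (t <= 4), 50.0, 0.0)
        chrom = Chromatogram(t, np.full_like(t, 500.0), inten)
        area = integrate_xic(chrom, 500.0, rt_window=(2.0, 4.0))
        assert area == pytest.approx(50.0 * 2.0, rel=1e-6)

    def test_gaussian_peak_closed_form(self):
        A, mu, sigma = 1000.0, 5.0, 0.2
        t = np.arange(0.0, 10.0, 1.0 / 60.0)  # 1-s sampling
        inten = A * np.exp(-0.5 * ((t - mu) / sigma) ** 2)
        chrom = Chromatogram(t, np.full_like(t, 836.357), inten)
        area = integrate_xic(chrom, 836.357)
        assert area == pytest.approx(A * sigma * math.sqrt(2 * math.pi), rel=0.01)

    def test_out_of_tolerance_returns_zero(self):
        t = np.arange(0.0, 1.0, 0.1)
        chrom = Chromatogram(t, np.full_like(t, 900.0), np.ones_like(t))
        assert integrate_xic(chrom, 500.0, mz_tol_ppm=10) == 0.0

    def test_rt_window_restricts(self):
        t = np.arange(0.0, 10.01, 0.1)
        inten = np.where((t >= 2) & (t <= 4), 60.0, 0.0)
        chrom = Chromatogram(t, np.full_like(t, 500.0), inten)
        assert integrate_xic(chrom, 500.0, rt_window=(5.0, 10.0)) == 0.0

    def test_empty_chromatogram_rejected(self):
        with pytest.raises(ValueError):
            Chromatogram(np.array([]), np.array([]), np.array([]))

    def test_generated_chromatogram_area(self):
        species = [
            {"species_id": "s", "mz": 836.357, "rt_min": 5.0, "sd_min": 0.15,
             "height": 800.0},
        ]
        df, truth = sd.gen_chromatograms(species, sampling_s=1.0, seed=0)
        chrom = Chromatogram(df.rt_min.values, df.mz.values, df.intensity.values)
        assert integrate_xic(chrom, 836.357) == pytest.approx(
            truth["areas_min"]["s"], rel=0.01
        )


class TestExposureFraction:
    def test_arithmetic(self):
        assert exposure_fraction(930, 70) == pytest.approx(0.93)

    def test_zero_first(self):
        assert exposure_fraction(0, 5) == 0.0

    def test_symmetry(self):
        assert exposure_fraction(3.3, 3.3) == 0.5

    def test_both_zero_is_missing(self):
        with pytest.raises(ValueError, match="missing"):
            exposure_fraction(0, 0)


class TestChannelProportions:
    def test_three_channels(self):
        props = channel_proportions({"L": 50, "H": 30, "NEM": 20})
        assert props == {"L": 0.5, "H": 0.3, "NEM": 0.2}

    def test_single_nonzero(self):
        props = channel_proportions({"L": 10, "H": 0})
        assert props == {"L": 1.0, "H": 0.0}

    @given(
        areas=st.dictionaries(
            st.sampled_from(["a", "b", "c"]),
            st.floats(min_value=0.01, max_value=1e6),
            min_size=2,
        ),
        scale=st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_scale_invariance_and_unit_sum(self, areas, scale):
        props = channel_proportions(areas)
        scaled = channel_proportions({k: v * scale for k, v in areas.items()})
        assert sum(props.values()) == pytest.approx(1.0, abs=1e-9)
        for k in areas:
            assert props[k] == pytest.approx(scaled[k], rel=1e-9)

    def test_zero_total_missing(self):
        with pytest.raises(ValueError):
            channel_proportions({"L": 0, "H": 0})


def oracle_classes(scheme):
    """Channel bookkeeping oracle on the scheme graph, independent of
    LabelScheme.channel_classes: walk steps in order, assign the first
    observable channel (or the displacement channel of a reversible native
    step) to exposed, the last to occluded, any middle one to the
    deactivation class."""
    native = [s for s in scheme.steps if s.context == "native-exposed"][0]
    first = native.displaced_by if native.reversible else native.name
    rest = [s.name for s in scheme.steps if not s.reversible and s.name != first]
    mapping = {first: "exposed-step1", rest[-1]: "occluded"}
    for mid in rest[:-1]:
        mapping[mid] = "exposed-on-deactivation"
    return mapping


class TestResolveScheme:
    def test_two_label_direct(self):
        res = resolve_scheme("two-label", {"IAM-light": 0.65, "IAM-heavy": 0.35})
        assert res.exposed_fraction == pytest.approx(0.65)

    def test_mmts_scheme_displacement_channel(self):
        res = resolve_scheme("mmts", {"IAM-light": 0.8, "IAM-heavy": 0.2})
        assert res.exposed_fraction == pytest.approx(0.8)

    def test_three_label_classes(self):
        res = resolve_scheme(
            "three-label",
            {"IAM-light": 0.6, "IAM-heavy": 0.3, "NEM": 0.1},
        )
        assert res.class_proportions == pytest.approx(
            {
                "exposed-step1": 0.6,
                "exposed-on-deactivation": 0.3,
                "occluded": 0.1,
            }
        )

    @pytest.mark.parametrize("name", sorted(SCHEMES))
    def test_matches_bookkeeping_oracle(self, name):
        assert SCHEMES[name].channel_classes == oracle_classes(SCHEMES[name])

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError, match="no generating step"):
            resolve_scheme("two-label", {"IAM-light": 0.5, "bogus": 0.5})

    def test_classes_conserve_mass(self):
        res = resolve_scheme(
            "three-label", {"IAM-light": 0.5, "IAM-heavy": 0.25, "NEM": 0.25}
        )
        assert sum(res.class_proportions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_mmts_requires_displacement(self):
        with pytest.raises(ValueError, match="displacement"):
            LabelScheme(
                "bad",
                (
                    LabelStep("MMTS", "MMTS", "native-exposed", reversible=True),
                    LabelStep("IAM-heavy", "IAM-heavy", "denatured-reduced"),
                ),
            )


class TestExposureFromTable:
    def test_noiseless_recovery(self):
        table, _ = sd.gen_peak_table({"A-state": 0.65, "D-state": 0.93}, cv=0.0)
        out = eq.exposure_from_table(table).set_index("species_id")
        assert out.loc["A-state", "exposed_fraction"] == pytest.approx(0.65, abs=1e-12)
        assert out.loc["D-state", "exposed_fraction"] == pytest.approx(0.93, abs=1e-12)

    def test_isotope_role_swap_invariance(self):
        kw = dict(n_replicates=6, cv=0.05, seed=11)
        t1, _ = sd.gen_peak_table({"c": 0.4}, **kw)
        t2, _ = sd.gen_peak_table(
            {"c": 0.4}, first_channel="IAM-heavy", second_channel="IAM-light", **kw
        )
        f1 = eq.exposure_from_table(t1, "two-label").exposed_fraction[0]
        f2 = eq.exposure_from_table(t2, "two-label-swapped").exposed_fraction[0]
        assert f1 == pytest.approx(f2, abs=1e-12)

    def test_parameter_recovery_small(self):
        # the full 1000-dataset version runs in test_acceptance; this is a
        # quick smoke at n=200
        fractions = {f"ds{i}": 0.39 for i in range(200)}
        table, _ = sd.gen_peak_table(fractions, n_replicates=6, cv=0.05, seed=5)
        out = eq.exposure_from_table(table)
        assert out.exposed_fraction.mean() == pytest.approx(0.39, abs=0.02)

    def test_interval_coverage(self):
        # the 95% t-interval (mean +/- t*SE across replicates) covers the
        # true fraction in >= 90% of 1000 simulated datasets
        from scipy import stats

        f, n_rep = 0.65, 6
        fractions = {f"ds{i:04d}": f for i in range(1000)}
        table, _ = sd.gen_peak_table(fractions, n_replicates=n_rep, cv=0.05, seed=17)
        out = eq.exposure_from_table(table)
        tcrit = stats.t.ppf(0.975, n_rep - 1)
        lo = out.exposed_fraction - tcrit * out.standard_error
        hi = out.exposed_fraction + tcrit * out.standard_error
        coverage = ((lo <= f) & (f <= hi)).mean()
        assert coverage >= 0.90

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            eq.exposure_from_table(pd.DataFrame({"species_id": [], "area": []}))


class TestStandardCurve:
    def test_exact_line(self):
        amounts = [10, 20, 50, 100]
        ratios = [0.01 * a for a in amounts]
        curve = fit_standard_curve(amounts, ratios)
        assert curve.slope == pytest.approx(0.01, abs=1e-12)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0)
        assert quantify(0.5 * 100.0, 100.0, curve) == pytest.approx(50.0)

    def test_equal_response_of_light_and_heavy(self, rng):
        # shared response factor; both channels ratioed against the same IS
        amounts = np.array([5.0, 10.0, 25.0, 50.0, 100.0])
        response = 0.02
        light = fit_standard_curve(
            amounts, response * amounts * (1 + rng.normal(0, 0.01, 5))
        )
        heavy = fit_standard_curve(
            amounts, response * amounts * (1 + rng.normal(0, 0.01, 5))
        )
        assert light.slope == pytest.approx(heavy.slope, rel=0.05)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            fit_standard_curve([5, 5, 5], [1, 2, 3])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_standard_curve([1, 2], [1, 2])

    def test_zero_is_area_rejected(self):
        curve = fit_standard_curve([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError):
            quantify(1.0, 0.0, curve)
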