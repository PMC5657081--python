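"""Group statistics: summaries, mixed models, pairwise tests, derived arithmetic."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import physfix as pf
from physfix.errors import ConfigurationError


def make_table(
    seed=0,
    n_specimens=12,
    cycles=(60, 120, 180),
    group_effects=(0.0, 0.0, 0.0),
    specimen_sd=1.0,
    noise_sd=0.5,
    base=5.0,
    marker=False,
    marker_sd=0.0,
):
    """Balanced repeated-measures table with known ground truth."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_specimens):
        u = rng.normal(0, specimen_sd)
        labels = ("cranial", "lateral", "caudal", "medial") if marker else (None,)
        v = {lbl: rng.normal(0, marker_sd) for lbl in labels}
        for g, eff in zip(("three", "two", "one"), group_effects):
            for c in cycles:
                for lbl in labels:
                    row = {
                        "specimen": f"S{s:02d}",
                        "pin_group": g,
                        "cycle": c,
                        "y": base + eff + u + v[lbl] + rng.normal(0, noise_sd),
                    }
                    if marker:
                        row["marker"] = lbl
                    rows.append(row)
    return pd.DataFrame(rows)


class TestSummarizeGroups:
    def test_mean_and_sample_sd(self):
        table = pd.DataFrame(
            {
                "specimen": list("abc") * 2,
                "pin_group": ["one"] * 3 + ["two"] * 3,
                "cycle": [60] * 6,
                "y": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            }
        )
        out = pf.summarize_groups(table).set_index("pin_group")
        assert out.loc["one", "mean"] == 2.0
        assert out.loc["one", "sd"] == pytest.approx(1.0)
        assert out.loc["one", "n"] == 3

    def test_single_value_group_rejected(self):
        table = pd.DataFrame(
            {"specimen": ["a", "a", "b"], "pin_group": ["one", "two", "two"], "cycle": [60] * 3, "y": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(ConfigurationError):
            pf.summarize_groups(table)

    def test_specimen_level_aggregation(self):
        table = make_table(seed=1, n_specimens=4)
        out = pf.summarize_groups(table, by_specimen=True)
        assert (out["n"] == 4).all()


class TestMixedModel:
    def test_degenerate_random_effects_match_ols(self):
        # balanced design with no specimen variance: fixed effects equal OLS
        import statsmodels.formula.api as smf

        table = make_table(seed=2, n_specimens=8, specimen_sd=0.0, group_effects=(0, 1, 2))
        res = pf.fit_mixed_model(table)
        ols = smf.ols("y ~ C(pin_group) + C(cycle)", table).fit()
        for name, value in res.fixed_effects.items():
            assert value == pytest.approx(ols.params[name], abs=1e-6)

    def test_strong_group_effect_detected(self):
        table = make_table(seed=3, group_effects=(0.0, 2.0, 4.0))
        res = pf.fit_mixed_model(table)
        assert res.p_values["pin_group"] < 1e-6
        assert res.p_values["cycle"] > 0.01

    def test_specimen_relabel_invariance(self):
        table = make_table(seed=4, group_effects=(0, 1, 2))
        relabeled = table.copy()
        mapping = {f"S{i:02d}": f"B{99 - i}" for i in range(12)}
        relabeled["specimen"] = relabeled["specimen"].map(mapping)
        a = pf.fit_mixed_model(table)
        b = pf.fit_mixed_model(relabeled)
        for k in a.fixed_effects:
            assert a.fixed_effects[k] == pytest.approx(b.fixed_effects[k], abs=1e-8)

    def test_marker_variance_component_recovered(self):
        table = make_table(seed=5, marker=True, marker_sd=1.0, noise_sd=0.3, n_specimens=8)
        res = pf.fit_mixed_model(table, pf.MixedModelSpec(marker_intercept=True))
        assert res.random_variances["marker"] == pytest.approx(1.0, abs=0.6)

    def test_single_level_factor_rejected(self):
        table = make_table(seed=6, cycles=(60,))
        with pytest.raises(ConfigurationError):
            pf.fit_mixed_model(table)

    def test_agrees_with_lme4(self, tmp_path):
        """Independent oracle: lme4 ML fit of the same model and LRT."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable: lme4 oracle cannot run")
        table = make_table(seed=7, n_specimens=8, group_effects=(0.0, 0.8, 1.6))
        csv = tmp_path / "table.csv"
        table.to_csv(csv, index=False)
        rfile = tmp_path / "oracle.R"
        rfile.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(lme4))
                d <- read.csv("{csv}")
                d$pin_group <- factor(d$pin_group); d$cycle <- factor(d$cycle)
                full <- lmer(y ~ pin_group + cycle + (1|specimen), d, REML=FALSE)
                red  <- lmer(y ~ cycle + (1|specimen), d, REML=FALSE)
                p <- anova(red, full)$`Pr(>Chisq)`[2]
                cat(fixef(full), p, sep="\\n")
                """
            )
        )
        out = subprocess.run(
            ["Rscript", str(rfile)], capture_output=True, text=True, check=True
        ).stdout.split()
        r_fixef = np.array(out[:5], dtype=float)
        r_p = float(out[5])
        res = pf.fit_mixed_model(table)
        ours = np.array(list(res.fixed_effects.values()))
        np.testing.assert_allclose(ours, r_fixef, atol=1e-4)
        assert res.p_values["pin_group"] == pytest.approx(r_p, abs=1e-4)


class TestPairwise:
    def test_null_rarely_significant(self):
        flags = []
        for seed in range(30):
            table = make_table(seed=seed, n_specimens=10)
            for p in pf.pairwise_group_tests(table, force=True).values():
                flags.append(p > 0.05)
        assert np.mean(flags) >= 0.85

    def test_separated_groups_significant(self):
        table = make_table(seed=1, group_effects=(0.0, 0.0, 2.5), noise_sd=0.5, specimen_sd=0.0)
        p = pf.pairwise_group_tests(table, force=True)[("one", "three")]
        assert p < 0.001

    def test_single_specimen_rejected(self):
        table = make_table(seed=1, n_specimens=2).query("specimen == 'S00'")
        with pytest.raises(ConfigurationError):
            pf.pairwise_group_tests(table, force=True)

    def test_gatekeeping(self):
        table = make_table(seed=1)
        with pytest.raises(ConfigurationError):
            pf.pairwise_group_tests(table, overall_p=0.5)

    def test_holm_never_smaller_than_raw(self):
        table = make_table(seed=2, group_effects=(0.0, 1.0, 2.0))
        raw = pf.pairwise_group_tests(table, force=True)
        adj = pf.pairwise_group_tests(table, force=True, holm=True)
        assert all(adj[k] >= raw[k] - 1e-15 for k in raw)


class TestCompareSystems:
    def test_identical_samples_ratio_one(self):
        vals = np.array([1.0, 2.0, 3.0])
        ratio, _ = pf.compare_systems(vals, vals)
        assert ratio == 1.0

    def test_benchmark_group_means_give_2_6(self):
        mts = [v[0] for v in pf.reference.GROUP_GROSS_MTS.values()]
        motion = [v[0] for v in pf.reference.GROUP_GROSS_MOTION.values()]
        ratio, _ = pf.compare_systems(mts, motion)
        assert round(ratio, 2) == 2.60

    def test_simulated_slippage_round_trip(self):
        p = pf.ConstructParams(1.10, 5.08, angle_noise_sd=0.0)
        proto = pf.LoadProtocol(n_cycles=2)
        trace = pf.generate_trace(proto, p, seed=0)
        geo = pf.RigGeometry(position_noise_sd=0.0)
        markers = pf.generate_markers(trace, geo, p, seed=0)
        axis = pf.estimate_axis([m for m in markers.values() if m.segment != "epiphysis"])
        win = pf.cycle_window(trace, 2)
        mts = [pf.gross_cycle_displacement(trace, win)] * 2
        t0 = trace.time[win.start]
        motion = [
            pf.marker_cycle_displacement(m, t0, t0 + 2.0, axis)
            for m in markers.values()
            if m.segment == "epiphysis"
        ]
        ratio, _ = pf.compare_systems(mts, motion)
        assert ratio == pytest.approx(2.6, rel=0.05)

    def test_degenerate_variances_rejected(self):
        with pytest.raises(ConfigurationError):
            pf.compare_systems([1.0, 1.0], [2.0, 2.0])


class TestDerivedArithmetic:
    def test_ratio_examples(self):
        assert round(pf.ratio_and_percent(4.22, 2.75), 2) == 1.53
        assert pf.ratio_and_percent(3.3, 3.3) == 1.0

    def test_percent_convention(self):
        assert round(pf.ratio_and_percent(2.75, 2.34, "percent"), 2) == 14.91

    @given(a=st.floats(0.1, 100), b=st.floats(0.1, 100))
    def test_percent_symmetric(self, a, b):
        assert pf.ratio_and_percent(a, b, "percent") == pytest.approx(
            pf.ratio_and_percent(b, a, "percent"), abs=1e-12
        )

    def test_zero_denominator_rejected(self):
        with pytest.raises(ConfigurationError):
            pf.ratio_and_percent(1.0, 0.0)


class TestImplantArea:
    def test_three_pins(self):
        area, frac, oversized = pf.implant_area_fraction(3, 3.0, 30.0)
        assert round(area) == 21
        assert frac == pytest.approx(3.0)
        assert not oversized

    def test_zero_pins(self):
        area, frac, _ = pf.implant_area_fraction(0, 3.0, 30.0)
        assert (area, frac) == (0.0, 0.0)

    def test_one_pin(self):
        _, frac, _ = pf.implant_area_fraction(1, 3.0, 30.0)
        assert frac == pytest.approx(1.0)

    @given(scale=st.floats(0.1, 10))
    def test_fraction_scale_invariant(self, scale):
        _, f1, _ = pf.implant_area_fraction(2, 3.0, 30.0)
        _, f2, _ = pf.implant_area_fraction(2, 3.0 * scale, 30.0 * scale)
        assert f2 == pytest.approx(f1, rel=1e-12)

    def test_oversized_flag(self):
        *_, oversized = pf.implant_area_fraction(1, 31.0, 30.0)
        assert oversized
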