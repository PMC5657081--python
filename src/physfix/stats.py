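"""Group comparison statistics for the repeated-measures torsion study.

Responses (stiffness, toggle, gross displacement from machine or markers)
are modelled with linear mixed-effects models: pin group and load cycle as
categorical fixed effects, a random intercept per specimen (every bone is
tested with three, two and one pins), and — for marker-derived responses —
an additional random intercept per marker site nested in specimen.  Fixed
factors are assessed by likelihood-ratio tests between maximum-likelihood
fits of nested models, mirroring the chi-square model-comparison workflow
used with lme4.  Pairwise follow-up uses paired t-tests on specimen-level
means (same bones across groups), uncorrected by default with an optional
Holm adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

from .errors import ConfigurationError, FittingError

__all__ = [
    "MixedModelSpec",
    "MixedModelResult",
    "summarize_groups",
    "fit_mixed_model",
    "pairwise_group_tests",
    "compare_systems",
    "ratio_and_percent",
    "implant_area_fraction",
]

REQUIRED_COLUMNS = ("specimen", "pin_group", "cycle", "y")


def _check_table(table: pd.DataFrame, need_marker: bool = False) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ConfigurationError(f"measurement table missing column(s) {missing}")
    if need_marker and "marker" not in table.columns:
        raise ConfigurationError("marker-level model requires a 'marker' column")
    if table["y"].isna().any():
        raise ConfigurationError("measurement table contains missing responses")
    return table


@dataclass(frozen=True)
class MixedModelSpec:
    """Fixed/random-effect structure of the group-comparison model.

    fixed: categorical factor names (default pin group and load cycle);
    specimen_intercept: random intercept per bone; marker_intercept: random
    intercept per marker site nested in bone (marker-derived responses only).
    """

    fixed: tuple[str, ...] = ("pin_group", "cycle")
    specimen_intercept: bool = True
    marker_intercept: bool = False

    def formula(self, drop: str | None = None) -> str:
        terms = [f"C({f})" for f in self.fixed if f != drop]
        return "y ~ " + (" + ".join(terms) if terms else "1")


@dataclass
class MixedModelResult:
    """Maximum-likelihood mixed-model fit plus likelihood-ratio factor tests."""

    fixed_effects: dict[str, float]
    fixed_se: dict[str, float]
    random_variances: dict[str, float]
    residual_variance: float
    loglike: float
    p_values: dict[str, float] = field(default_factory=dict)
    lr_statistics: dict[str, float] = field(default_factory=dict)
    singular: bool = False
    converged: bool = True


def summarize_groups(
    table: pd.DataFrame, by_specimen: bool = False
) -> pd.DataFrame:
    """Per-pin-group n, mean and sample SD (n-1 denominator).

    With ``by_specimen=True`` each specimen is first collapsed to its mean
    over cycles/markers, so n is the number of bones per group.
    """
    _check_table(table)
    data = table
    if by_specimen:
        data = (
            table.groupby(["pin_group", "specimen"], observed=True)["y"]
            .mean()
            .reset_index()
        )
    out = (
        data.groupby("pin_group", observed=True)["y"]
        .agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    if (out["n"] < 2).any() or out["n"].isna().any():
        raise ConfigurationError("each pin group needs >= 2 observations")
    return out


def _fit_ml(formula: str, table: pd.DataFrame, spec: MixedModelSpec):
    vc = {"marker": "0 + C(marker)"} if spec.marker_intercept else None
    model = smf.mixedlm(formula, table, groups=table["specimen"], re_formula="1", vc_formula=vc)
    res = None
    errors: dict[str, str] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "bfgs", "powell", "cg"):
            try:
                cand = model.fit(reml=False, method=method)
            except Exception as exc:  # noqa: BLE001 - optimizer-specific failure
                errors[method] = str(exc)
                continue
            if np.isfinite(cand.llf) and np.all(np.isfinite(cand.params)):
                res = cand
                break
            errors[method] = "non-finite log-likelihood or estimates"
    if res is None:
        raise FittingError(
            "mixed-model fit failed with every optimizer", {"formula": formula, **errors}
        )
    return res


def fit_mixed_model(
    table: pd.DataFrame,
    spec: MixedModelSpec | None = None,
    test_factors: tuple[str, ...] | None = None,
) -> MixedModelResult:
    """Fit the mixed model by ML and test each fixed factor by likelihood ratio.

    Each factor's p-value comes from a chi-square likelihood-ratio test of
    the full model against the model with that factor removed (both ML).
    ``test_factors`` restricts which factors get an LRT (default: all).
    Singular (near-zero) random-intercept variances are reported via the
    ``singular`` flag, never silently dropped.
    """
    spec = spec or MixedModelSpec()
    _check_table(table, need_marker=spec.marker_intercept)
    for f in spec.fixed:
        if table[f].nunique() < 2:
            raise ConfigurationError(f"fixed factor {f!r} needs >= 2 levels")
    if table["specimen"].nunique() < 2:
        raise ConfigurationError("need >= 2 specimens")

    full = _fit_ml(spec.formula(), table, spec)
    fixed = {k: float(v) for k, v in full.fe_params.items()}
    fixed_se = {k: float(full.bse_fe[k]) for k in full.fe_params.index}
    resid = float(full.scale)
    rand = {"specimen": float(np.squeeze(full.cov_re)) if spec.specimen_intercept else 0.0}
    if spec.marker_intercept:
        rand["marker"] = float(full.vcomp[0])
    singular = any(v < 1e-8 * resid for v in rand.values())

    p_values: dict[str, float] = {}
    lr_stats: dict[str, float] = {}
    for f in spec.fixed if test_factors is None else test_factors:
        reduced = _fit_ml(spec.formula(drop=f), table, spec)
        lr = 2.0 * (full.llf - reduced.llf)
        df = len(full.fe_params) - len(reduced.fe_params)
        lr_stats[f] = float(max(lr, 0.0))
        p_values[f] = float(sps.chi2.sf(max(lr, 0.0), df))

    return MixedModelResult(
        fixed_effects=fixed,
        fixed_se=fixed_se,
        random_variances=rand,
        residual_variance=resid,
        loglike=float(full.llf),
        p_values=p_values,
        lr_statistics=lr_stats,
        singular=singular,
        converged=bool(getattr(full, "converged", True)),
    )


def pairwise_group_tests(
    table: pd.DataFrame,
    holm: bool = False,
    overall_p: float | None = None,
    alpha: float = 0.05,
    force: bool = False,
) -> dict[tuple[str, str], float]:
    """Paired t-tests between pin groups on specimen-level means.

    The same bones are tested in every group, so comparisons are paired.
    Gatekept: if ``overall_p`` is given and exceeds ``alpha``, pairwise
    testing is refused unless ``force=True``.  P-values are raw by default;
    ``holm=True`` applies a Holm step-down adjustment.
    """
    _check_table(table)
    if overall_p is not None and overall_p > alpha and not force:
        raise ConfigurationError(
            f"overall factor p={overall_p:.3g} > alpha={alpha}: pairwise tests gated "
            "(pass force=True to override)"
        )
    means = (
        table.groupby(["pin_group", "specimen"], observed=True)["y"].mean().unstack("specimen")
    )
    groups = list(means.index)
    if means.isna().any().any():
        raise ConfigurationError("paired tests need every specimen measured in every group")
    if means.shape[1] < 2:
        raise ConfigurationError("paired tests need >= 2 specimens")
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1 :]]
    raw = {
        (a, b): float(sps.ttest_rel(means.loc[a], means.loc[b]).pvalue) for a, b in pairs
    }
    if not holm:
        return raw
    order = sorted(raw, key=raw.get)
    m = len(order)
    adj, prev = {}, 0.0
    for i, pair in enumerate(order):
        prev = max(prev, min(1.0, (m - i) * raw[pair]))
        adj[pair] = prev
    return adj


def compare_systems(mts_values, motion_values) -> tuple[float, float]:
    """Machine vs motion-capture displacement: (ratio of means, Welch p-value)."""
    a = np.asarray(mts_values, dtype=float)
    b = np.asarray(motion_values, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ConfigurationError("both samples need n >= 2")
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        raise ConfigurationError("degenerate (zero) variance in both samples")
    if b.mean() == 0.0:
        raise ConfigurationError("motion-analysis mean is zero: ratio undefined")
    p = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
    return float(a.mean() / b.mean()), p


def ratio_and_percent(mean_a: float, mean_b: float, mode: str = "ratio") -> float:
    """Derived arithmetic on two group means.

    ``ratio``: mean_a / mean_b.  ``percent``: percentage separation of the
    two means relative to the larger one, (larger - smaller) / larger * 100
    — symmetric in argument order.
    """
    if mode == "ratio":
        if mean_b == 0.0:
            raise ConfigurationError("zero denominator in ratio")
        return mean_a / mean_b
    if mode == "percent":
        hi, lo = max(mean_a, mean_b), min(mean_a, mean_b)
        if hi == 0.0:
            raise ConfigurationError("zero denominator in percent mode")
        return (hi - lo) / hi * 100.0
    raise ConfigurationError("mode must be 'ratio' or 'percent'")


def implant_area_fraction(
    n_pins: int, pin_diameter: float, physis_diameter: float
) -> tuple[float, float, bool]:
    """Combined pin cross-sectional area (mm^2) and its share of the physis (%).

    Returns ``(combined_area, fraction_percent, oversized)`` where
    ``oversized`` flags a pin diameter at or above the physis diameter.
    Fraction is invariant to rescaling both diameters together.
    """
    if pin_diameter <= 0 or physis_diameter <= 0:
        raise ConfigurationError("diameters must be > 0")
    if n_pins < 0:
        raise ConfigurationError("n_pins must be >= 0")
    area = n_pins * np.pi * (pin_diameter / 2.0) ** 2
    fraction = area / (np.pi * (physis_diameter / 2.0) ** 2) * 100.0
    return float(area), float(fraction), pin_diameter >= physis_diameter
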