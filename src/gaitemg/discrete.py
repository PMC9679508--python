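"""Discrete stride-level statistics: side mirroring, mixed-model condition
contrasts, false-discovery-rate adjustment, and the induction-sufficiency
rule.

Right-sided inductions are mirrored onto the left so all data can be
pooled as lame-side (LS) / non-lame-side (NLS): signed asymmetry variables
are multiplied by -1 and left/right labels are swapped.  Condition
contrasts use a linear mixed model (condition fixed, subject random
intercept, optionally a per-subject random slope on stride speed to
correct for uncontrolled over-ground speed), reported as estimated
marginal means with FDR-adjusted p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError

#: signed asymmetry variables that flip under left/right mirroring
SIGNED_ASYMMETRY_VARS = (
    "min_diff_poll", "max_diff_poll", "min_diff_withers", "max_diff_withers",
    "min_diff_pelvis", "max_diff_pelvis", "hip_hike",
)

#: motion asymmetry reference values (mm) for sufficient induced lameness
POLL_THRESHOLD_MM = 13.0
PELVIS_THRESHOLD_MM = 5.0


def mirror_for_side(table: pd.DataFrame, induction_side: str) -> pd.DataFrame:
    """Express stride data as lame side (LS) / non-lame side (NLS).

    ``side='right'``: signed asymmetry variables are negated and left/right
    labels map to NLS/LS.  ``side='left'``: values unchanged, left/right
    map to LS/NLS.  Applying the transform twice restores the original
    values (involution on the signed variables).
    """
    if induction_side not in ("left", "right"):
        raise ConfigurationError(f"induction side must be left or right, got {induction_side!r}")
    out = table.copy()
    if induction_side == "right":
        for col in SIGNED_ASYMMETRY_VARS:
            if col in out.columns:
                out[col] = -out[col]
        mapping = {"left": "NLS", "right": "LS"}
    else:
        mapping = {"left": "LS", "right": "NLS"}
    if "side" in out.columns:
        out["side_role"] = out["side"].map(lambda s: mapping.get(s, s))
    return out


@dataclass
class ConditionContrast:
    """Estimated marginal means and the baseline-vs-induced contrast."""

    variable: str
    em_mean_baseline: float
    se_baseline: float
    em_mean_induced: float
    se_induced: float
    difference: float
    pct_difference: object  # float or "n/a" for signed asymmetry variables
    p_raw: float
    p_fdr: float = np.nan
    converged: bool = True


def _fit_mixed(df: pd.DataFrame, speed_correction: bool):
    """Fit value ~ condition with subject random intercept (optionally a
    per-subject random slope on speed); fall back to paired subject means."""
    import statsmodels.formula.api as smf

    data = df.rename(columns={"condition": "cond"}).copy()
    data["induced"] = (data["cond"] != "baseline").astype(float)
    try:
        if data["subject"].nunique() < 3:
            # the fixed intercept is not identifiable against the random
            # intercepts with so few groups; use the paired-means contrast
            raise RuntimeError("too few subjects for a mixed model")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            formula, kwargs = "value ~ induced", {}
            if speed_correction and data["stride_speed"].notna().all():
                # fixed speed effect (a mean-zero random slope alone cannot
                # absorb a condition-correlated speed shift) plus the
                # per-subject random slope; centred so the intercept is the
                # EM mean at the average speed
                data["speed_c"] = data["stride_speed"] - data["stride_speed"].mean()
                formula += " + speed_c"
                kwargs["re_formula"] = "~speed_c"
            model = smf.mixedlm(formula, data, groups=data["subject"],
                                **kwargs)
            fit = model.fit(reml=True, method="lbfgs")
            if not fit.converged:
                raise RuntimeError("mixed model did not converge")
            b0, b1 = fit.params["Intercept"], fit.params["induced"]
            cov = fit.cov_params().loc[["Intercept", "induced"],
                                       ["Intercept", "induced"]]
            se0 = float(np.sqrt(cov.iloc[0, 0]))
            se1 = float(np.sqrt(cov.iloc[0, 0] + cov.iloc[1, 1] + 2 * cov.iloc[0, 1]))
            p = float(fit.pvalues["induced"])
        if not all(np.isfinite(v) for v in (b0, b1, se0, se1, p)):
            raise RuntimeError("non-finite mixed-model estimates")
        return float(b0), se0, float(b0 + b1), se1, float(b1), p, True
    except Exception:
        # fallback: paired t on per-subject means
        from scipy import stats as sps
        means = data.groupby(["subject", "induced"])["value"].mean().unstack()
        base, ind = means[0.0], means[1.0]
        diff = ind - base
        n = len(diff)
        if n >= 2:
            _, p = sps.ttest_rel(ind, base)
            se_b = float(base.std(ddof=1) / np.sqrt(n))
            se_i = float(ind.std(ddof=1) / np.sqrt(n))
        else:  # a single subject: stride-level dispersion, no exact p
            p = np.nan
            se_b = float(data.loc[data.induced == 0, "value"].std(ddof=1))
            se_i = float(data.loc[data.induced == 1, "value"].std(ddof=1))
        return (float(base.mean()), se_b, float(ind.mean()), se_i,
                float(diff.mean()), float(p), False)


def contrast_conditions(table: pd.DataFrame, speed_correction: bool = False,
                        fdr: bool = True) -> list:
    """Baseline-vs-induced contrast per variable.

    ``table`` needs columns subject, condition ('baseline' or 'induced'),
    variable, value and (if ``speed_correction``) stride_speed.  Percentage
    difference uses the baseline EM mean as denominator and is reported
    'n/a' for signed asymmetry variables (no meaningful baseline scale).
    """
    results = []
    for var, df in table.groupby("variable", sort=True):
        b0, se0, b1, se1, diff, p, conv = _fit_mixed(df, speed_correction)
        if var in SIGNED_ASYMMETRY_VARS:
            pct = "n/a"
        else:
            pct = 100.0 * abs(diff) / abs(b0) if b0 != 0 else "n/a"
        results.append(ConditionContrast(var, b0, se0, b1, se1, diff, pct, p,
                                         converged=conv))
    if fdr and results:
        adj = fdr_adjust([r.p_raw for r in results])
        for r, q in zip(results, adj):
            r.p_fdr = float(q)
    return results


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)  # NaN (e.g. undefined single-subject p) passes through
    q = p[ok]
    m = q.size
    if m:
        order = np.argsort(q, kind="stable")
        ranked = q[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.empty(m)
        adj[order] = np.minimum(ranked, 1.0)
        out[ok] = adj
    return out


def induction_sufficiency(baseline: pd.DataFrame, induced: pd.DataFrame) -> dict:
    """Classify whether an induction produced sufficient motion asymmetry.

    Forelimb induction is sufficient when the baseline-to-induced change in
    mean poll MinDiff or MaxDiff exceeds 13 mm in magnitude; hindlimb when
    pelvis MinDiff and/or MaxDiff change exceeds 5 mm -- in both cases
    provided the induced-condition standard deviation of the qualifying
    index is smaller than the magnitude of its induced mean (variability
    rule).  Thresholds are strict (">").  Missing indices give
    'indeterminate'.
    """
    def verdict(indices, threshold):
        any_present = False
        for col in indices:
            if col not in baseline.columns or col not in induced.columns:
                continue
            b = baseline[col].dropna()
            i = induced[col].dropna()
            if len(b) == 0 or len(i) == 0:
                continue
            any_present = True
            delta = i.mean() - b.mean()
            if abs(delta) > threshold and i.std(ddof=1) < abs(i.mean()):
                return "sufficient"
        return "insufficient" if any_present else "indeterminate"

    return {
        "forelimb": verdict(("min_diff_poll", "max_diff_poll"), POLL_THRESHOLD_MM),
        "hindlimb": verdict(("min_diff_pelvis", "max_diff_pelvis"), PELVIS_THRESHOLD_MM),
    }
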