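"""Inferential statistics for curve-parameter tables and PTH time courses.

* Dunnett's many-to-one comparison: one-way ANOVA followed by simultaneous
  two-sided comparisons of every treatment level against the control,
  with adjusted p-values from the equicorrelated multivariate-t
  distribution, evaluated by direct numerical integration (no lookup
  tables).
* Two-way repeated-measures ANOVA on PTH profiles (between factor:
  compound; within factor: time) with per-timepoint adjusted comparisons.
* Linear trapezoidal AUC over a sampled time course.
* Classical unpaired two-tailed t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, optimize, special, stats as sps

from .data import TimeCourse, timecourses_to_frame

__all__ = [
    "DunnettResult",
    "AUCResult",
    "TTestResult",
    "RMAnovaResult",
    "dunnett_vs_control",
    "dunnett_max_t_cdf",
    "dunnett_critical_value",
    "rm_two_way_anova",
    "trapezoid_auc",
    "unpaired_t",
]


# ---------------------------------------------------------------------------
# Dunnett's test
# ---------------------------------------------------------------------------

# Gauss-Hermite nodes for the standard-normal mixing variable shared by all
# comparisons (the control-group mean).  80 nodes give ~1e-10 accuracy here.
_GH_X, _GH_W = np.polynomial.hermite_e.hermegauss(80)
_GH_W = _GH_W / np.sqrt(2.0 * np.pi)


def dunnett_max_t_cdf(c: float, lambdas: np.ndarray, df: float) -> float:
    """P(max_i |T_i| <= c) for Dunnett's many-to-one statistics.

    The T_i are jointly multivariate t with df degrees of freedom and
    product correlation rho_ij = lambda_i * lambda_j, where
    lambda_i = 1 / sqrt(1 + n_0 / n_i) for group sizes n_i and control size
    n_0.  Conditioning on the control deviate z and the pooled scale u
    factorises the probability:

        P = E_u E_z  prod_i [ Phi((c u - l_i z)/s_i) - Phi((-c u - l_i z)/s_i) ]

    with s_i = sqrt(1 - lambda_i^2).  The z-expectation uses Gauss-Hermite
    quadrature; the scale expectation integrates over the chi distribution
    of u = s/sigma.
    """
    if c <= 0:
        return 0.0
    lam = np.asarray(lambdas, dtype=float)
    s = np.sqrt(1.0 - lam**2)

    def inner(u):
        # u may be a vector of scale values
        u = np.atleast_1d(u)[:, None, None]            # (nu, 1, 1)
        z = _GH_X[None, :, None]                       # (1, nz, 1)
        hi = (c * u - lam * z) / s
        lo = (-c * u - lam * z) / s
        prod = np.prod(sps.norm.cdf(hi) - sps.norm.cdf(lo), axis=2)
        return prod @ _GH_W

    # chi distribution of u = sqrt(chi2_df / df)
    ln_norm = (1.0 - df / 2.0) * np.log(2.0) - special.gammaln(df / 2.0) \
        + (df / 2.0) * np.log(df)

    def integrand(u):
        dens = np.exp(ln_norm + (df - 1.0) * np.log(u) - df * u**2 / 2.0)
        return float(dens * inner(u)[0])

    val, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
    return float(min(max(val, 0.0), 1.0))


def dunnett_critical_value(
    n_compare: int, df: float, n_per_group: Optional[Sequence[float]] = None,
    n_control: Optional[float] = None, alpha: float = 0.05,
) -> float:
    """Two-sided Dunnett critical value |T| for ``n_compare`` comparisons.

    With no group sizes given, the balanced case (correlation 0.5) is
    assumed.
    """
    if n_per_group is None:
        lam = np.full(n_compare, np.sqrt(0.5))
    else:
        n_per_group = np.asarray(n_per_group, dtype=float)
        n0 = float(n_control if n_control is not None else n_per_group[0])
        lam = 1.0 / np.sqrt(1.0 + n0 / n_per_group)
    return float(optimize.brentq(
        lambda c: dunnett_max_t_cdf(c, lam, df) - (1.0 - alpha),
        1e-3, 30.0, xtol=1e-8,
    ))


@dataclass
class DunnettResult:
    """Comparisons of every treatment level against the control level."""

    parameter: str
    control_level: object
    df: float
    comparisons: pd.DataFrame  # level, mean_difference, t, p_unadjusted,
    #                            adjusted_p, significant

    def significant_levels(self) -> list:
        return list(self.comparisons.loc[self.comparisons["significant"],
                                         "level"])


def dunnett_vs_control(
    groups: Mapping[object, Iterable[float]],
    control_level: object,
    alpha: float = 0.05,
    parameter: str = "",
) -> DunnettResult:
    """One-way-ANOVA-style simultaneous comparisons against a control.

    ``groups`` maps level labels to replicate values; the control level must
    be one of them and is never compared to itself.  Adjusted p-values are
    two-sided familywise probabilities from the multivariate-t distribution
    of the max-|T| statistic; with a single comparison this reduces exactly
    to the pooled-variance two-sample t-test.
    """
    if control_level not in groups:
        raise ValueError(f"control level {control_level!r} not in groups")
    levels = [k for k in groups if k != control_level]
    if not levels:
        raise ValueError("need at least one non-control level")
    arrays = {k: np.asarray(list(v), dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 2:
            raise ValueError(
                f"group {k!r} has {len(v)} replicate(s); >= 2 required for "
                "a pooled variance estimate"
            )
    n0 = len(arrays[control_level])
    N = sum(len(v) for v in arrays.values())
    k_groups = len(arrays)
    df = N - k_groups
    # pooled within-group variance (one-way ANOVA MSE)
    sse = sum(np.sum((v - v.mean()) ** 2) for v in arrays.values())
    mse = sse / df
    if mse <= 0:
        raise ValueError("zero within-group variance; t undefined")

    ns = np.array([len(arrays[k]) for k in levels], dtype=float)
    lam = 1.0 / np.sqrt(1.0 + n0 / ns)
    m0 = arrays[control_level].mean()
    rows = []
    for i, lev in enumerate(levels):
        v = arrays[lev]
        diff = v.mean() - m0
        se = np.sqrt(mse * (1.0 / len(v) + 1.0 / n0))
        t = diff / se
        p_un = 2.0 * sps.t.sf(abs(t), df)
        p_adj = 1.0 - dunnett_max_t_cdf(abs(t), lam, df)
        rows.append({
            "level": lev, "mean_difference": diff, "t": t,
            "p_unadjusted": p_un, "adjusted_p": p_adj,
            "significant": p_adj < alpha,
        })
    return DunnettResult(parameter, control_level, df, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Repeated-measures two-way ANOVA on time courses
# ---------------------------------------------------------------------------


@dataclass
class RMAnovaResult:
    """Mixed-design ANOVA (between: compound, within: time) plus
    per-timepoint adjusted comparisons between the two compounds."""

    anova: pd.DataFrame       # Source, F, p-unc, ... (one row per effect)
    timepoints: pd.DataFrame  # time_min, mean_a, mean_b, t, p_unadjusted,
    #                           adjusted_p, significant
    correction: str

    def effect_p(self, source: str) -> float:
        row = self.anova.loc[self.anova["Source"] == source]
        if len(row) == 0:
            raise KeyError(source)
        return float(row["p_unc"].iloc[0])


def rm_two_way_anova(
    profiles: Sequence[TimeCourse],
    correction: str = "bonferroni",
    alpha: float = 0.05,
) -> RMAnovaResult:
    """Two-way repeated-measures ANOVA across compounds and time.

    ``profiles`` must contain exactly two compound groups with >= 2 animals
    each, identical time grids, and disjoint animal identities.  Main
    effects come from a mixed-design ANOVA (compound as the between-subject
    factor, time as the within-subject factor); per-timepoint comparisons
    are unpaired t-tests with Bonferroni (default) or Sidak adjustment
    across the time grid.
    """
    if correction not in ("bonferroni", "sidak"):
        raise ValueError("correction must be 'bonferroni' or 'sidak'")
    compounds = sorted({tc.compound for tc in profiles})
    if len(compounds) != 2:
        raise ValueError(f"need exactly 2 compounds, got {compounds}")
    by = {c: [tc for tc in profiles if tc.compound == c] for c in compounds}
    for c, tcs in by.items():
        if len(tcs) < 2:
            raise ValueError(f"compound {c!r} has < 2 animals")
    ids_a = {tc.animal_id for tc in by[compounds[0]]}
    ids_b = {tc.animal_id for tc in by[compounds[1]]}
    if ids_a & ids_b:
        raise ValueError(
            f"animals {sorted(ids_a & ids_b)} appear in both arms; "
            "between-subject factor requires disjoint animals"
        )
    grid = profiles[0].times
    for tc in profiles:
        if tc.times.shape != grid.shape or not np.allclose(tc.times, grid):
            raise ValueError("mismatched time grids across animals")

    import pingouin as pg

    long = timecourses_to_frame(list(profiles))
    anova = pg.mixed_anova(
        data=long, dv="pth_pg_ml", within="time_min",
        subject="animal_id", between="compound",
    )
    anova = anova.rename(columns={"p-unc": "p_unc"})
    # name the effect rows consistently
    anova.loc[anova["Source"] == "Interaction", "Source"] = "compound * time"
    anova.loc[anova["Source"] == "time_min", "Source"] = "time"

    n_t = len(grid)
    rows = []
    for j, t in enumerate(grid):
        va = np.array([tc.pth[j] for tc in by[compounds[0]]])
        vb = np.array([tc.pth[j] for tc in by[compounds[1]]])
        res = unpaired_t(va, vb)
        p = res.p
        if correction == "bonferroni":
            p_adj = min(1.0, p * n_t) if np.isfinite(p) else p
        else:
            p_adj = 1.0 - (1.0 - p) ** n_t if np.isfinite(p) else p
        rows.append({
            "time_min": float(t),
            f"mean_{compounds[0]}": va.mean(),
            f"mean_{compounds[1]}": vb.mean(),
            "t": res.t, "p_unadjusted": p, "adjusted_p": p_adj,
            "significant": bool(np.isfinite(p_adj) and p_adj < alpha),
        })
    return RMAnovaResult(anova, pd.DataFrame(rows), correction)


# ---------------------------------------------------------------------------
# AUC and t-test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AUCResult:
    animal_id: str
    auc: float           # pg*min/mL
    interval: tuple      # (t_start, t_end) minutes


def trapezoid_auc(
    tc: TimeCourse,
    t_start: Optional[float] = None,
    t_end: Optional[float] = None,
    baseline: float = 0.0,
) -> AUCResult:
    """Linear trapezoidal area under the PTH-time linear interpolant.

    Defaults to the full sampled range.  ``baseline`` is subtracted before
    integration when a baseline-corrected AUC is wanted (negative segments
    are kept as-is, the classical net-area convention).
    """
    t0 = tc.times[0] if t_start is None else float(t_start)
    t1 = tc.times[-1] if t_end is None else float(t_end)
    if not (tc.times[0] <= t0 < t1 <= tc.times[-1]):
        raise ValueError(
            f"interval ({t0}, {t1}) outside sampled range "
            f"[{tc.times[0]}, {tc.times[-1]}]"
        )
    inside = tc.times[(tc.times > t0) & (tc.times < t1)]
    grid = np.concatenate(([t0], inside, [t1]))
    y = np.interp(grid, tc.times, tc.pth) - baseline
    auc = float(np.trapezoid(y, grid))
    return AUCResult(tc.animal_id, auc, (t0, t1))


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: float
    undefined: bool = False


def unpaired_t(group_a, group_b) -> TTestResult:
    """Classical pooled-variance unpaired two-tailed t-test."""
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    df = len(a) + len(b) - 2
    sp2 = (np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)) / df
    if sp2 == 0.0:
        # all values identical within groups: statistic is 0/0
        return TTestResult(np.nan, np.nan, df, undefined=True)
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return TTestResult(float(t), float(p), df)
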