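"""Nonlinear least-squares estimation for concentration-response data.

Two estimation routes are provided, mirroring standard allosteric-modulator
workflows:

* :func:`fit_global_operational` — a *global* fit of the operational model of
  cooperative agonism and allosterism across every modulator concentration
  simultaneously, with the pharmacological constraint set (transducer slope
  fixed to 1, binding cooperativity alpha fixed to 0, no allosteric agonism,
  log KB bounded in (-8, 0)) and all remaining parameters shared across
  curves.  This is the route that yields pKB and log(alpha*beta).

* :func:`fit_4pl` / :func:`build_curve_table` — independent four-parameter
  logistic fits of each curve, summarised per modulator concentration as
  mean +/- SEM across experiments (the "LogEC50 / Emax / Hill slope" table
  convention).

Both are ordinary (unweighted) least squares on normalized responses.
Standard errors for global fits are asymptotic, from the Jacobian at the
optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import lmfit
import numpy as np
import pandas as pd

from .data import ConcentrationResponseDataset
from .models import (
    Concentrations,
    FourPLParams,
    OperationalModelParams,
    effect_4pl,
    effect_complete,
    effect_comparative,
)

__all__ = [
    "GlobalFitResult",
    "FourPLFit",
    "CurveFitTable",
    "fit_global_operational",
    "fit_4pl",
    "build_curve_table",
    "DEFAULT_CONSTRAINTS",
]

#: The default constraint set for global operational fits: transducer slope
#: at unity, no affinity-only cooperativity, no allosteric agonism
#: (log tauB = -1000 underflows tauB to exactly 0), and log KB bounded
#: between 10 nmol/L and 1 mol/L.
DEFAULT_CONSTRAINTS: dict = {
    "nT": {"value": 1.0, "vary": False},
    "alpha": {"value": 0.0, "vary": False},
    "log_tauB": {"value": -1000.0, "vary": False},
    "log_KB": {"min": -8.0, "max": 0.0},
}


class UnderDeterminedError(ValueError):
    """Raised when a fit has fewer distinct design points than parameters."""


class ConvergenceError(RuntimeError):
    """Raised when the optimizer fails to converge after multistart."""


@dataclass
class GlobalFitResult:
    """Outcome of a shared-parameter operational-model fit."""

    estimates: OperationalModelParams
    standard_errors: dict
    fixed_mask: dict
    rss: float
    n_obs: int
    converged: bool
    per_point_residuals: np.ndarray
    variant: str
    non_identifiable: list = field(default_factory=list)
    censored: list = field(default_factory=list)
    aic: float = np.nan
    n_free: int = 0

    @property
    def pKB(self) -> float:
        return -getattr(self.estimates, "log_KB")

    @property
    def pKB_sem(self) -> float:
        return self.standard_errors.get("log_KB", np.nan)

    @property
    def log_alphabeta(self) -> float:
        return self.estimates.log_alphabeta

    @property
    def log_alphabeta_sem(self) -> float:
        return self.standard_errors.get("log_alphabeta", np.nan)

    def summary(self) -> dict:
        """Report-ready scalars (KB in nmol/L, alphabeta linear)."""
        from .models import logab_to_ab, pk_to_k

        return {
            "variant": self.variant,
            "pKB": self.pKB,
            "pKB_sem": self.pKB_sem,
            "KB_nmol": pk_to_k(self.pKB),
            "log_alphabeta": self.log_alphabeta,
            "log_alphabeta_sem": self.log_alphabeta_sem,
            "alphabeta": logab_to_ab(self.log_alphabeta),
            "rss": self.rss,
            "aic": self.aic,
            "n_obs": self.n_obs,
            "converged": self.converged,
        }


# ---------------------------------------------------------------------------
# Global operational-model fit
# ---------------------------------------------------------------------------

_FREE_COMPLETE = ["Em", "log_tauA", "log_KA", "nB", "log_KB", "log_alphabeta"]
_FREE_COMPARATIVE = ["Em", "logEC50", "nB", "log_KB", "log_alphabeta"]


def _half_max_logA(A, resp):
    """Crude log10 concentration at half-maximal response, for starts."""
    order = np.argsort(A)
    A, resp = np.asarray(A)[order], np.asarray(resp)[order]
    pos = A > 0
    A, resp = A[pos], resp[pos]
    if len(A) == 0:
        return -3.0
    half = 0.5 * (resp.min() + resp.max())
    above = np.nonzero(resp >= half)[0]
    idx = above[0] if len(above) else len(A) - 1
    return float(np.log10(A[max(idx, 0)]))


def _build_params(variant, data, constraints):
    """lmfit.Parameters with the default starts, bounds and constraint set."""
    df = data.data
    obs_max = float(df["response"].max())
    veh = df.loc[df["nam_conc_molar"] == 0]
    src = veh if len(veh) else df
    log_half = _half_max_logA(
        src["agonist_conc_molar"].to_numpy() + data.ambient_C,
        src["response"].to_numpy(),
    )

    p = lmfit.Parameters()
    p.add("Em", value=max(obs_max, 1.0), min=1e-6, max=4.0 * max(obs_max, 1.0))
    if variant == "complete":
        p.add("log_tauA", value=0.5, min=-2.0, max=3.0)
        p.add("log_KA", value=log_half, min=log_half - 3.0, max=log_half + 3.0)
    elif variant == "comparative":
        p.add("log_tauA", value=0.0, vary=False)
        p.add("logEC50", value=log_half, min=log_half - 3.0, max=log_half + 3.0)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    p.add("nB", value=2.0, min=0.3, max=6.0)
    p.add("log_KB", value=-6.5, min=-8.0, max=0.0)
    p.add("log_alphabeta", value=-1.0, min=-4.0, max=1.0)
    p.add("nT", value=1.0, vary=False)
    p.add("alpha", value=0.0, vary=False)
    p.add("log_tauB", value=-1000.0, vary=False)

    merged = dict(DEFAULT_CONSTRAINTS)
    if constraints:
        for k, v in constraints.items():
            merged[k] = {**merged.get(k, {}), **v}
    for name, spec in merged.items():
        if name not in p:
            raise ValueError(f"unknown parameter {name!r} in constraints")
        if "value" in spec:
            p[name].set(value=spec["value"])
        if "vary" in spec:
            p[name].set(vary=spec["vary"])
        if "min" in spec:
            p[name].set(min=spec["min"])
        if "max" in spec:
            p[name].set(max=spec["max"])
    # keep starts inside bounds
    for par in p.values():
        if par.vary:
            par.value = float(np.clip(par.value, par.min + 1e-9, par.max - 1e-9))
    return p


def _params_to_model(p, variant, C=0.0) -> dict:
    kw = dict(
        C=C,
        Em=p["Em"].value,
        log_tauA=p["log_tauA"].value,
        log_KB=p["log_KB"].value,
        log_alphabeta=p["log_alphabeta"].value,
        log_tauB=p["log_tauB"].value,
        alpha=p["alpha"].value,
        nT=p["nT"].value,
        nB=p["nB"].value,
    )
    if variant == "complete":
        kw["log_KA"] = p["log_KA"].value
    else:
        kw["logEC50"] = p["logEC50"].value
    return kw


def fit_global_operational(
    data: ConcentrationResponseDataset,
    variant: str = "complete",
    constraints: Optional[dict] = None,
    n_multistart: int = 10,
    seed: int = 0,
    jitter: float = 0.5,
) -> GlobalFitResult:
    """Fit the operational allosteric model globally across all curves.

    Parameters
    ----------
    data : ConcentrationResponseDataset
        Normalized responses spanning >= 3 modulator concentrations
        including vehicle (B = 0).
    variant : {"complete", "comparative"}
        Whether the agonist is parameterised by (log KA, log tauA) or by its
        observed logEC50.
    constraints : dict, optional
        Per-parameter overrides merged over :data:`DEFAULT_CONSTRAINTS`,
        e.g. ``{"nB": {"value": 2.0, "vary": False}}``.
    n_multistart : int
        Number of jittered restarts (+/- ``jitter`` log units on the free
        log-scale parameters) around the default start; the best
        residual-sum-of-squares solution wins.  Deterministic for a fixed
        ``seed``.

    Returns
    -------
    GlobalFitResult
        Shared-parameter estimates with asymptotic SEMs, residuals, and
        flags for non-identifiable or bound-censored parameters.
    """
    df = data.data
    A = df["agonist_conc_molar"].to_numpy(dtype=float)
    B = df["nam_conc_molar"].to_numpy(dtype=float)
    y = df["response"].to_numpy(dtype=float)
    C = data.ambient_C
    effect = effect_complete if variant == "complete" else effect_comparative

    params = _build_params(variant, data, constraints)

    non_identifiable = []
    if not np.any(B > 0):
        # KB cancels from the vehicle-only likelihood and alphabeta only
        # multiplies B: both are structurally absent.  Fix and flag them.
        for name in ("log_KB", "log_alphabeta"):
            if params[name].vary:
                params[name].set(vary=False)
                non_identifiable.append(name)

    free = [name for name in params if params[name].vary]
    design = {(a, b) for a, b in zip(A, B)}
    if len(design) < len(free) + 1:
        raise UnderDeterminedError(
            f"{len(design)} distinct design points for {len(free)} free "
            "parameters"
        )

    def residual(p):
        m = OperationalModelParams(**_params_to_model(p, variant, C))
        return effect(m, Concentrations(A, B)) - y

    rng = np.random.default_rng(seed)
    starts = [params]
    log_scale = [n for n in free if n.startswith("log") or n == "nB"]
    for _ in range(max(n_multistart - 1, 0)):
        q = params.copy()
        for name in log_scale:
            lo, hi = q[name].min, q[name].max
            q[name].value = float(
                np.clip(q[name].value + rng.uniform(-jitter, jitter),
                        lo + 1e-9, hi - 1e-9)
            )
        starts.append(q)

    best = None
    for start in starts:
        try:
            res = lmfit.minimize(residual, start, method="least_squares")
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr - 1e-12:
            best = res
    if best is None or not best.success:
        raise ConvergenceError(
            "operational-model fit failed to converge after "
            f"{len(starts)} starts"
        )

    p = best.params
    sems = {}
    for i, name in enumerate(best.var_names):
        if p[name].stderr is not None:
            sems[name] = float(p[name].stderr)
        else:
            sems[name] = np.nan
    censored = [
        name
        for name in best.var_names
        if np.isfinite(p[name].min)
        and (abs(p[name].value - p[name].min) < 1e-6
             or abs(p[name].value - p[name].max) < 1e-6)
    ]

    est = OperationalModelParams(**_params_to_model(p, variant, C))
    resid = np.asarray(best.residual, dtype=float)
    return GlobalFitResult(
        estimates=est,
        standard_errors=sems,
        fixed_mask={name: (not params[name].vary) for name in params},
        rss=float(np.sum(resid**2)),
        n_obs=len(y),
        converged=bool(best.success),
        per_point_residuals=resid,
        variant=variant,
        non_identifiable=non_identifiable,
        censored=censored,
        aic=float(best.aic),
        n_free=len(best.var_names),
    )


# ---------------------------------------------------------------------------
# Per-curve 4PL fits
# ---------------------------------------------------------------------------


@dataclass
class FourPLFit:
    """A single-curve four-parameter logistic fit."""

    params: FourPLParams
    standard_errors: dict
    rss: float
    n_obs: int
    converged: bool
    flat: bool = False  # response range indistinguishable from noise


def _fit_4pl_arrays(logA: np.ndarray, y: np.ndarray) -> FourPLFit:
    if len(np.unique(logA)) < 4:
        raise UnderDeterminedError(
            "4PL fit needs >= 4 distinct agonist concentrations, got "
            f"{len(np.unique(logA))}"
        )
    span = float(y.max() - y.min())
    flat = span < 1e-9 * max(abs(float(y.max())), 1.0)
    if flat:
        # Hill slope and LogEC50 are unidentifiable on a flat curve; return
        # the degenerate constant fit, flagged, rather than raising.
        params = FourPLParams(float(y.mean()), float(y.mean()),
                              float(np.median(logA)), 1.0)
        return FourPLFit(params, {k: np.inf for k in
                                  ("Bottom", "Top", "LogEC50", "HillSlope")},
                         rss=float(np.sum((y - y.mean()) ** 2)),
                         n_obs=len(y), converged=True, flat=True)

    p = lmfit.Parameters()
    pad = 0.1 * span
    p.add("Bottom", value=float(y.min()), min=float(y.min()) - 5 * span - pad,
          max=float(y.max()) + pad)
    p.add("Top", value=float(y.max()), min=float(y.min()) - pad,
          max=float(y.max()) + 5 * span + pad)
    half = 0.5 * (y.min() + y.max())
    order = np.argsort(logA)
    xs, ys = logA[order], y[order]
    above = np.nonzero(ys >= half)[0]
    x_half = xs[above[0]] if len(above) else float(np.median(xs))
    p.add("LogEC50", value=float(x_half), min=float(xs.min()) - 3.0,
          max=float(xs.max()) + 3.0)
    p.add("HillSlope", value=1.5, min=0.05, max=15.0)

    def residual(q):
        m = FourPLParams(q["Bottom"].value, q["Top"].value,
                         q["LogEC50"].value, q["HillSlope"].value)
        return effect_4pl(m, logA) - y

    best = None
    for hill0 in (1.5, 3.0, 0.7):
        q = p.copy()
        q["HillSlope"].value = hill0
        try:
            res = lmfit.minimize(residual, q, method="least_squares")
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr - 1e-12:
            best = res
    if best is None:
        raise ConvergenceError("4PL fit failed to converge")

    q = best.params
    sems = {n: (float(q[n].stderr) if q[n].stderr is not None else np.nan)
            for n in best.var_names}
    params = FourPLParams(q["Bottom"].value, q["Top"].value,
                          q["LogEC50"].value, q["HillSlope"].value)
    resid = np.asarray(best.residual)
    return FourPLFit(params, sems, rss=float(np.sum(resid**2)),
                     n_obs=len(y), converged=bool(best.success))


def fit_4pl(curve, response=None) -> FourPLFit:
    """Fit a four-parameter logistic to a single concentration-response curve.

    ``curve`` may be a :class:`ConcentrationResponseDataset` restricted to a
    single modulator concentration (agonist concentrations are taken from
    ``agonist_conc_molar`` plus the ambient agonist level), or an array of
    log10 molar agonist concentrations with ``response`` given separately.

    A flat curve (response range indistinguishable from zero) yields a
    flagged degenerate fit with infinite standard errors, not an exception.
    """
    if isinstance(curve, ConcentrationResponseDataset):
        df = curve.data
        A = df["agonist_conc_molar"].to_numpy(dtype=float) + curve.ambient_C
        if np.any(A <= 0):
            raise ValueError("4PL needs positive total agonist concentrations")
        logA = np.log10(A)
        y = df["response"].to_numpy(dtype=float)
    else:
        logA = np.asarray(curve, dtype=float)
        y = np.asarray(response, dtype=float)
        if logA.shape != y.shape:
            raise ValueError("logA and response must have the same shape")
    return _fit_4pl_arrays(logA, y)


@dataclass
class CurveFitTable:
    """Per-modulator-concentration 4PL summary (mean +/- SEM across
    experiments), plus the underlying per-experiment fits for inference."""

    table: pd.DataFrame              # b_molar, logec50, logec50_sem, emax, ...
    per_experiment: pd.DataFrame     # b_molar, experiment_id, logec50, emax, hill

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def build_curve_table(data: ConcentrationResponseDataset) -> CurveFitTable:
    """Independent 4PL fits per (modulator concentration, experiment),
    summarised as mean +/- SEM across experiments with n = experiment count.

    The Hill-slope column of such tables is the usual diagnostic for
    allosteric modulation of cooperative agonist binding: a NAM with
    alpha*beta < 1 progressively flattens the curves.
    """
    rows, per_exp = [], []
    for b in data.nam_concs:
        sub = data.subset_nam(float(b))
        fits = []
        for exp in sub.experiments:
            one = ConcentrationResponseDataset(
                sub.data.loc[sub.data["experiment_id"] == exp].reset_index(drop=True),
                sub.ambient_C, sub.normalization,
            )
            fit = fit_4pl(one)
            fits.append(fit)
            per_exp.append({
                "b_molar": float(b), "experiment_id": exp,
                "logec50": fit.params.LogEC50, "emax": fit.params.Top,
                "hill": fit.params.HillSlope, "flat": fit.flat,
            })
        n = len(fits)
        vals = {
            "logec50": np.array([f.params.LogEC50 for f in fits]),
            "emax": np.array([f.params.Top for f in fits]),
            "hill": np.array([f.params.HillSlope for f in fits]),
        }
        row = {"b_molar": float(b)}
        for name, v in vals.items():
            row[name] = float(np.mean(v))
            row[f"{name}_sem"] = (float(np.std(v, ddof=1) / np.sqrt(n))
                                  if n > 1 else np.nan)
        row["n"] = n
        rows.append(row)
    cols = ["b_molar", "logec50", "logec50_sem", "emax", "emax_sem",
            "hill", "hill_sem", "n"]
    return CurveFitTable(pd.DataFrame(rows)[cols], pd.DataFrame(per_exp))
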