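"""End-to-end orchestration: normalization, fitting, inference, reports.

The pipeline mirrors the full analysis workflow of a NAM characterization
study: raw plate records are normalized to the ionomycin reference, fitted
globally with the operational allosteric model (affinity pKB and composite
cooperativity alpha*beta) and per-curve with the 4PL (LogEC50 / Emax / Hill
slope table with Dunnett annotations); washout experiments are reduced to a
reversibility verdict; in vivo PTH time courses are summarised by trapezoid
AUCs with the associated tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import (
    ConcentrationResponseDataset,
    TimeCourse,
    RAW_PLATE_COLUMNS,
)
from .fitting import (
    CurveFitTable,
    GlobalFitResult,
    build_curve_table,
    fit_4pl,
    fit_global_operational,
)
from .models import logab_to_ab, pk_to_k
from .stats import (
    dunnett_vs_control,
    rm_two_way_anova,
    trapezoid_auc,
    unpaired_t,
)
from .synthetic import WASHOUT_ARMS

__all__ = [
    "RunConfig",
    "ReportBundle",
    "normalize_responses",
    "run_crc_analysis",
    "run_washout_analysis",
    "run_pth_analysis",
    "format_affinity_table",
]


class NormalizationError(ValueError):
    pass


@dataclass
class RunConfig:
    """Configuration of a pipeline run; defaults reproduce the standard
    constraint set of the global operational fit."""

    variant: str = "complete"
    normalization: str = "ionomycin"
    ambient_C: float = 1e-4
    constraints: Optional[dict] = None
    seed: int = 0
    n_multistart: int = 10
    alpha: float = 0.05
    out_dir: Optional[str] = None

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Read a flat ``key = value`` text config."""
        kw = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"bad config line: {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key in ("seed", "n_multistart"):
                kw[key] = int(val)
            elif key in ("ambient_C", "alpha"):
                kw[key] = float(val)
            elif key in ("variant", "normalization", "out_dir"):
                kw[key] = val
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cls(**kw)


def normalize_responses(
    raw: pd.DataFrame,
    mode: str = "ionomycin",
    ambient_C: float = 1e-4,
) -> ConcentrationResponseDataset:
    """Normalize raw plate fluorescence to the ionomycin reference.

    ``response = 100 * raw_peak / ionomycin_peak`` per record.  Under mode
    ``"percent-max"`` responses are additionally rescaled so the vehicle
    curve's maximum (mean across replicates per agonist concentration) maps
    to 100 — the convention used for washout comparisons.
    """
    missing = [c for c in RAW_PLATE_COLUMNS if c not in raw.columns]
    if missing:
        raise NormalizationError(f"raw plate records missing columns: {missing}")
    if len(raw) == 0:
        raise NormalizationError("empty plate records")
    iono = raw["ionomycin_peak"].to_numpy(dtype=float)
    if np.any(~np.isfinite(iono)):
        raise NormalizationError("missing ionomycin reference wells")
    if np.any(iono <= 0):
        raise NormalizationError("zero or negative ionomycin reference")
    df = raw.copy()
    df["response"] = 100.0 * df["raw_peak"].to_numpy(dtype=float) / iono
    if mode == "percent-max":
        veh = df.loc[df["nam_conc_molar"] == 0]
        if len(veh) == 0:
            raise NormalizationError("percent-max mode needs a vehicle curve")
        veh_max = veh.groupby("agonist_conc_molar")["response"].mean().max()
        if veh_max <= 0:
            raise NormalizationError("non-positive vehicle maximum")
        df["response"] = 100.0 * df["response"] / veh_max
    elif mode != "ionomycin":
        raise ValueError(f"unknown normalization mode {mode!r}")
    keep = [c for c in df.columns if c != "raw_peak" and c != "ionomycin_peak"]
    return ConcentrationResponseDataset(
        df[keep], ambient_C=ambient_C, normalization=mode
    )


@dataclass
class ReportBundle:
    """Structured outputs of the pipeline stages (any subset populated)."""

    table1_like: Optional[pd.DataFrame] = None   # pKB / KB / Logab / ab row
    table2_like: Optional[pd.DataFrame] = None   # per-[NAM] 4PL with stars
    global_fit: Optional[GlobalFitResult] = None
    curve_table: Optional[CurveFitTable] = None
    washout_summary: Optional[dict] = None
    pth_summary: Optional[dict] = None

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if self.table1_like is not None:
            self.table1_like.to_csv(out / "affinity_table.csv", index=False)
        if self.table2_like is not None:
            self.table2_like.to_csv(out / "curve_table.csv", index=False)
        if self.global_fit is not None:
            (out / "global_fit.json").write_text(
                json.dumps(_jsonable(self.global_fit.summary()), indent=2))
        if self.washout_summary is not None:
            (out / "washout_summary.json").write_text(
                json.dumps(_jsonable(self.washout_summary), indent=2))
        if self.pth_summary is not None:
            (out / "pth_summary.json").write_text(
                json.dumps(_jsonable(self.pth_summary), indent=2))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def format_affinity_table(fit: GlobalFitResult, nam_id: str = "NAM") -> pd.DataFrame:
    """One report row per modulator: pKB +/- SEM, KB (nmol/L, nearest
    integer), Logab +/- SEM and alpha*beta (3 significant figures).

    KB and alpha*beta are deterministic transforms of the pKB and Logab
    columns; the rounding matches the usual display precision of such
    tables.
    """
    pKB = fit.pKB
    logab = fit.log_alphabeta
    kb = pk_to_k(pKB)
    ab = logab_to_ab(logab)
    row = {
        "nam_id": nam_id,
        "pKB": round(pKB, 2),
        "pKB_sem": round(fit.pKB_sem, 2) if np.isfinite(fit.pKB_sem) else np.nan,
        "KB_nmol": round(kb),
        "log_alphabeta": round(logab, 2),
        "log_alphabeta_sem": (round(fit.log_alphabeta_sem, 2)
                              if np.isfinite(fit.log_alphabeta_sem) else np.nan),
        "alphabeta": float(f"{ab:.3g}"),
        "variant": fit.variant,
    }
    return pd.DataFrame([row])


def run_crc_analysis(
    data: ConcentrationResponseDataset, config: RunConfig = RunConfig()
) -> ReportBundle:
    """Global operational fit + per-concentration 4PL table with Dunnett
    annotations against the vehicle row."""
    if not data.has_vehicle():
        raise ValueError("dataset has no vehicle (B = 0) curve")
    fit = fit_global_operational(
        data, variant=config.variant, constraints=config.constraints,
        n_multistart=config.n_multistart, seed=config.seed,
    )
    curve = build_curve_table(data)
    table2 = curve.table.copy()

    # Dunnett stars per parameter when >= 2 experiments per level
    per = curve.per_experiment
    counts = per.groupby("b_molar")["experiment_id"].nunique()
    stars = {}
    if (counts >= 2).all() and len(counts) >= 2 and 0.0 in counts.index:
        for param in ("logec50", "emax", "hill"):
            groups = {
                b: per.loc[per["b_molar"] == b, param].to_numpy()
                for b in counts.index
            }
            res = dunnett_vs_control(groups, 0.0, alpha=config.alpha,
                                     parameter=param)
            sig = dict(zip(res.comparisons["level"],
                           res.comparisons["significant"]))
            stars[param] = {0.0: False, **sig}
    for param in ("logec50", "emax", "hill"):
        if param in stars:
            table2[f"{param}_sig"] = [
                bool(stars[param].get(b, False)) for b in table2["b_molar"]
            ]
    return ReportBundle(
        table1_like=format_affinity_table(fit),
        table2_like=table2,
        global_fit=fit,
        curve_table=curve,
    )


# ---------------------------------------------------------------------------
# Washout
# ---------------------------------------------------------------------------


def _arms_equivalent(per_a: pd.DataFrame, per_b: pd.DataFrame,
                     alpha: float, atol: dict) -> bool:
    """Are two arms statistically indistinguishable in LogEC50 and Emax?

    Uses unpaired t-tests on the per-experiment fit values; when both arms
    have zero variance (noise-free data) the comparison falls back to an
    absolute-difference tolerance.
    """
    for param, tol in atol.items():
        a = per_a[param].to_numpy()
        b = per_b[param].to_numpy()
        res = unpaired_t(a, b) if len(a) >= 2 and len(b) >= 2 else None
        if res is None or res.undefined:
            if abs(a.mean() - b.mean()) > tol:
                return False
        elif res.p < alpha:
            return False
    return True


def run_washout_analysis(
    data: ConcentrationResponseDataset, config: RunConfig = RunConfig()
) -> ReportBundle:
    """Per-arm 4PL fits and a reversibility verdict.

    Verdict: ``washed-out`` if the washout arm is statistically
    indistinguishable from vehicle in both Emax and LogEC50 (full reversal),
    ``retained`` if indistinguishable from the modulator arm (irreversible
    or very slowly dissociating), else ``partial``.
    """
    if "arm" not in data.data.columns:
        raise ValueError("washout dataset needs an 'arm' column")
    arms = set(data.data["arm"].unique())
    missing = set(WASHOUT_ARMS) - arms
    if missing:
        raise ValueError(f"missing washout arm(s): {sorted(missing)}")

    per_arm_fits, per_arm_rows = {}, {}
    for arm in WASHOUT_ARMS:
        sub = data.subset_arm(arm)
        rows = []
        for exp in sub.experiments:
            one = ConcentrationResponseDataset(
                sub.data.loc[sub.data["experiment_id"] == exp]
                .reset_index(drop=True),
                sub.ambient_C, sub.normalization,
            )
            f = fit_4pl(one)
            rows.append({"experiment_id": exp, "logec50": f.params.LogEC50,
                         "emax": f.params.Top, "hill": f.params.HillSlope})
        per_arm_rows[arm] = pd.DataFrame(rows)
        per_arm_fits[arm] = {
            "logec50": float(per_arm_rows[arm]["logec50"].mean()),
            "emax": float(per_arm_rows[arm]["emax"].mean()),
            "hill": float(per_arm_rows[arm]["hill"].mean()),
            "n": len(rows),
        }

    # exact-equality tolerances used only in the zero-variance fallback
    atol = {"logec50": 1e-4, "emax": 1e-2}
    if _arms_equivalent(per_arm_rows["washout"], per_arm_rows["vehicle"],
                        config.alpha, atol):
        verdict = "washed-out"
    elif _arms_equivalent(per_arm_rows["washout"], per_arm_rows["nam"],
                          config.alpha, atol):
        verdict = "retained"
    else:
        verdict = "partial"

    summary = {"verdict": verdict, "arms": per_arm_fits}
    return ReportBundle(washout_summary=summary)


# ---------------------------------------------------------------------------
# PTH time courses
# ---------------------------------------------------------------------------


def run_pth_analysis(
    profiles: Sequence[TimeCourse], config: RunConfig = RunConfig()
) -> ReportBundle:
    """Per-animal trapezoid AUCs, group means, unpaired t-test between the
    two compounds, and the repeated-measures ANOVA per-timepoint table."""
    compounds = sorted({tc.compound for tc in profiles})
    if len(compounds) != 2:
        raise ValueError(f"need exactly 2 compounds, got {compounds}")
    by = {c: [tc for tc in profiles if tc.compound == c] for c in compounds}
    for c, tcs in by.items():
        if len(tcs) < 2:
            raise ValueError(f"compound {c!r} has < 2 animals; "
                             "no degrees of freedom for the t-test")

    aucs = {c: [trapezoid_auc(tc) for tc in tcs] for c, tcs in by.items()}
    vals = {c: np.array([a.auc for a in lst]) for c, lst in aucs.items()}
    ttest = unpaired_t(vals[compounds[0]], vals[compounds[1]])
    rm = rm_two_way_anova(list(profiles), alpha=config.alpha)

    summary = {
        "compounds": compounds,
        "auc_per_animal": {
            c: [{"animal_id": a.animal_id, "auc": a.auc} for a in lst]
            for c, lst in aucs.items()
        },
        "auc_mean": {c: float(v.mean()) for c, v in vals.items()},
        "auc_sem": {c: float(v.std(ddof=1) / np.sqrt(len(v)))
                    for c, v in vals.items()},
        "auc_ratio": float(vals[compounds[1]].mean()
                           / vals[compounds[0]].mean()),
        "t_test": {"t": ttest.t, "p": ttest.p, "df": ttest.df,
                   "undefined": ttest.undefined},
        "rm_anova": {
            "effects": rm.anova[["Source", "F", "p_unc"]],
            "timepoints": rm.timepoints,
            "correction": rm.correction,
        },
    }
    return ReportBundle(pth_summary=summary)
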