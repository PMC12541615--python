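"""Seeded generators emulating the three experiment types.

Three designs are generated with known ground truth so that every analysis
stage can be exercised and recovered at desk scale:

1. Intracellular-calcium mobilization plates: full concentration-response
   surfaces produced by the operational allosteric model over a grid of
   agonist and modulator concentrations, with additive Gaussian noise.
2. Washout plates: three arms (vehicle / modulator / modulator + washout),
   where the washout arm carries an effective modulator concentration equal
   to ``residual_fraction`` of the preincubation concentration — 0 for a
   fully reversible ligand, 1 for an irreversible one.
3. PTH time courses after a 10-min intravenous infusion: a baseline plus a
   phenomenological surge term with a controllable peak time and decay
   half-life, sampled on the in vivo protocol grid.  Two presets encode the
   fast-reversible (peak during the infusion, gone by ~30 min) and
   slow-irreversible (peak ~15 min, decaying to baseline over ~6 h)
   phenotypes.

All generators are deterministic for a fixed seed and embed their ground
truth in the returned object's metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .data import ConcentrationResponseDataset, TimeCourse
from .models import Concentrations, OperationalModelParams, effect_complete, effect_comparative

__all__ = [
    "AssayDesign",
    "WashoutDesign",
    "PTHProfileDesign",
    "default_truth",
    "hill_trend_truth",
    "HILL_TREND_AGONIST_CONCS",
    "simulate_crc",
    "simulate_washout",
    "simulate_pth",
    "FAST_PRESET",
    "SLOW_PRESET",
    "surge_shape",
    "amplitude_for_auc_ratio",
]

#: Default modulator concentrations: 0 (vehicle) plus 0.1-10 umol/L.
DEFAULT_NAM_CONCS = (0.0, 0.1e-6, 0.3e-6, 1e-6, 3e-6, 10e-6)

#: Default agonist (Ca2+) grid: 10 half-log points from 0.1 to 30 mmol/L,
#: bracketing a control LogEC50 near -2.94 so both plateaus are sampled.
DEFAULT_AGONIST_CONCS = tuple(10 ** np.linspace(-4, -4 + 0.5 * 9, 10))


@dataclass(frozen=True)
class AssayDesign:
    """Plate design for the calcium-mobilization concentration-response assay."""

    agonist_concs: tuple = DEFAULT_AGONIST_CONCS
    nam_concs: tuple = DEFAULT_NAM_CONCS
    n_experiments: int = 4
    n_replicates_per_experiment: int = 1
    ambient_C: float = 1e-4
    noise_sd_pct_Em: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.agonist_concs) == 0 or len(self.nam_concs) == 0:
            raise ValueError("empty concentration list in design")
        if self.n_experiments < 1 or self.n_replicates_per_experiment < 1:
            raise ValueError("need >= 1 experiment and replicate")
        if self.noise_sd_pct_Em < 0 or self.ambient_C < 0:
            raise ValueError("negative noise SD or ambient concentration")


def default_truth(
    pKB: float = 7.06,
    log_alphabeta: float = -1.87,
    Em: float = 193.56,
    log_tauA: float = np.log10(5.0),
    nB: float = 2.91,
    control_logec50: float = -2.94,
    C: float = 1e-4,
) -> OperationalModelParams:
    """Ground-truth parameter set whose vehicle curve matches the reference
    control curve (LogEC50 -2.94, Emax = Em*tauA/(1+tauA) = 161.3 %
    ionomycin, Hill slope = nB).

    The vehicle curve of the complete model is an exact Hill curve with
    EC50^nB = KA^nB / (1 + tauA), which fixes log KA given the target
    control LogEC50.
    """
    tauA = 10.0 ** log_tauA
    log_KA = control_logec50 + np.log10(1.0 + tauA) / nB
    return OperationalModelParams(
        Em=Em, log_tauA=log_tauA, log_KA=log_KA, nB=nB,
        log_KB=-pKB, log_alphabeta=log_alphabeta, C=C,
    )


#: Agonist grid for the Hill-slope-trend demonstration: 12 points,
#: ~0.03-100 mmol/L, wide enough that every shifted curve's sigmoid is
#: covered at both ends.
HILL_TREND_AGONIST_CONCS = tuple(10 ** np.linspace(-4.5, -1.0, 12))


def hill_trend_truth() -> OperationalModelParams:
    """Ground truth whose per-curve 4PL Hill slope declines monotonically
    with modulator concentration.

    With the transducer slope at unity the model's fixed-B curves are exact
    Hill curves of slope nB, so the apparent Hill slope cannot vary with
    modulator concentration.  A sub-linear transducer (nT < 1) breaks that
    exactness: the modulator raises the effective operational efficacy
    through the alphabeta*B numerator term, and under a saturating
    transducer higher efficacy flattens the apparent curve — reproducing
    the progressive Hill-slope decline seen with NAMs on cooperative
    receptors.  A high-affinity, modest-cooperativity NAM makes the effect
    visible across the standard 0.1-10 umol/L range.
    """
    return OperationalModelParams(
        Em=200.0, log_tauA=np.log10(5.0), log_KA=-2.6,
        log_KB=-8.0, log_alphabeta=-1.0, nB=4.4, nT=0.5, C=1e-4,
    )


def _forward(truth: OperationalModelParams, A, B):
    effect = effect_complete if truth.log_KA is not None else effect_comparative
    return effect(truth, Concentrations(A, B))


def simulate_crc(
    design: AssayDesign, truth: OperationalModelParams
) -> ConcentrationResponseDataset:
    """Simulate a full concentration-response surface from the operational
    model plus additive Gaussian noise (SD = ``noise_sd_pct_Em`` % of Em),
    truncated at zero.  Deterministic for a fixed ``design.seed``."""
    rng = np.random.default_rng(design.seed)
    sd = design.noise_sd_pct_Em * truth.Em / 100.0
    rows = []
    for e in range(design.n_experiments):
        for r in range(design.n_replicates_per_experiment):
            for b in design.nam_concs:
                for a in design.agonist_concs:
                    mu = _forward(truth, a, b)
                    resp = mu + (rng.normal(0.0, sd) if sd > 0 else 0.0)
                    rows.append({
                        "experiment_id": f"exp{e + 1}",
                        "replicate": r + 1,
                        "nam_id": "NAM",
                        "nam_conc_molar": b,
                        "agonist_conc_molar": a,
                        "response": max(resp, 0.0),
                    })
    df = pd.DataFrame(rows)
    meta = {k: (float(v) if isinstance(v, (int, float)) else v)
            for k, v in asdict(truth).items() if v is not None}
    meta["seed"] = design.seed
    return ConcentrationResponseDataset(
        df, ambient_C=design.ambient_C, normalization="ionomycin", truth=meta
    )


@dataclass(frozen=True)
class WashoutDesign:
    """Three-arm washout experiment design.

    ``residual_fraction`` is the fraction of modulator occupancy surviving
    the wash series: 0 reproduces full washout (reversible ligand), 1 no
    washout (irreversible ligand).
    """

    residual_fraction: float
    preincubation_nam: float = 10e-6
    agonist_concs: tuple = DEFAULT_AGONIST_CONCS
    n_experiments: int = 4
    ambient_C: float = 1e-4
    noise_sd_pct_Em: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.residual_fraction <= 1.0:
            raise ValueError("residual_fraction must be in [0, 1]")
        if self.preincubation_nam < 0:
            raise ValueError("negative preincubation concentration")


#: Arm labels and their effective modulator concentration rule.
WASHOUT_ARMS = ("vehicle", "nam", "washout")


def simulate_washout(
    design: WashoutDesign, truth: OperationalModelParams
) -> ConcentrationResponseDataset:
    """Simulate vehicle / modulator / modulator+washout arms.

    The washout arm experiences an effective modulator concentration of
    ``residual_fraction * preincubation_nam``; the vehicle arm B = 0."""
    rng = np.random.default_rng(design.seed)
    sd = design.noise_sd_pct_Em * truth.Em / 100.0
    b_eff = {
        "vehicle": 0.0,
        "nam": design.preincubation_nam,
        "washout": design.residual_fraction * design.preincubation_nam,
    }
    rows = []
    for e in range(design.n_experiments):
        for arm in WASHOUT_ARMS:
            for a in design.agonist_concs:
                mu = _forward(truth, a, b_eff[arm])
                resp = mu + (rng.normal(0.0, sd) if sd > 0 else 0.0)
                rows.append({
                    "experiment_id": f"exp{e + 1}",
                    "replicate": 1,
                    "nam_id": "NAM",
                    "arm": arm,
                    "nam_conc_molar": b_eff[arm],
                    "agonist_conc_molar": a,
                    "response": max(resp, 0.0),
                })
    meta = {k: (float(v) if isinstance(v, (int, float)) else v)
            for k, v in asdict(truth).items() if v is not None}
    meta.update(seed=design.seed, residual_fraction=design.residual_fraction,
                preincubation_nam=design.preincubation_nam)
    return ConcentrationResponseDataset(
        pd.DataFrame(rows), ambient_C=design.ambient_C,
        normalization="ionomycin", truth=meta,
    )


# ---------------------------------------------------------------------------
# PTH time courses
# ---------------------------------------------------------------------------

#: Blood-sampling grid of the 10-min-infusion protocol (minutes).
PROTOCOL_TIMES = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 40.0, 70.0, 160.0, 240.0, 370.0)


@dataclass(frozen=True)
class PTHProfileDesign:
    """Design of a simulated PTH release profile after a 10-min infusion.

    The surge term is phenomenological: s(t) = (t/tp)^a * exp(-lambda (t-tp))
    with lambda = ln2 / decay_halflife and a = lambda * tp, which has its
    mode exactly at ``peak_time`` and an asymptotically exponential tail with
    the given half-life.  Multiplicative log-normal noise with coefficient
    of variation ``noise_cv`` is applied per sample.
    """

    compound: str = "compound"
    sample_times: tuple = PROTOCOL_TIMES
    baseline_pth: float = 30.0
    amplitude: float = 300.0
    peak_time: float = 5.0
    decay_halflife: float = 4.0
    n_animals: int = 3
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.sample_times) or len(self.sample_times) == 0:
            raise ValueError("sample times must be positive")
        if list(self.sample_times) != sorted(self.sample_times):
            raise ValueError("sample times must be increasing")
        for name in ("baseline_pth", "amplitude", "peak_time",
                     "decay_halflife", "noise_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative {name}")
        if self.n_animals < 1:
            raise ValueError("need >= 1 animal")


#: Rapid-onset, rapidly reversible phenotype: PTH peaks mid-infusion (5 min)
#: and is back near baseline within ~30 min.
FAST_PRESET = dict(peak_time=5.0, decay_halflife=4.0)

#: Slow-onset, sustained phenotype: PTH peaks at ~15 min and decays to
#: baseline over ~6 h.
SLOW_PRESET = dict(peak_time=15.0, decay_halflife=70.0)


def surge_shape(t, peak_time: float, decay_halflife: float):
    """Unit-peak surge shape with mode at ``peak_time`` (min)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative times")
    lam = np.log(2.0) / decay_halflife
    a = lam * peak_time
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(t > 0, (t / peak_time) ** a * np.exp(-lam * (t - peak_time)), 0.0)
    return s


def amplitude_for_auc_ratio(
    reference: PTHProfileDesign, target: PTHProfileDesign, ratio: float
) -> float:
    """Surge amplitude for ``target`` so that its noise-free trapezoid AUC
    over its sampling grid equals ``ratio`` times the reference design's.

    Useful for closure tests: e.g. tuning the slow preset's amplitude to
    exactly double the fast preset's total PTH exposure.
    """
    def parts(d: PTHProfileDesign):
        t = np.asarray(d.sample_times, dtype=float)
        s = surge_shape(t, d.peak_time, d.decay_halflife)
        base = d.baseline_pth * (t[-1] - t[0])
        return base, float(np.trapezoid(s, t))

    base_ref, s_ref = parts(reference)
    base_tgt, s_tgt = parts(target)
    amp = (ratio * (base_ref + reference.amplitude * s_ref) - base_tgt) / s_tgt
    if amp < 0:
        raise ValueError("target baseline already exceeds the requested AUC")
    return float(amp)


def simulate_pth(design: PTHProfileDesign) -> list[TimeCourse]:
    """Simulate per-animal PTH time courses for one compound arm."""
    rng = np.random.default_rng(design.seed)
    t = np.asarray(design.sample_times, dtype=float)
    mean = design.baseline_pth + design.amplitude * surge_shape(
        t, design.peak_time, design.decay_halflife
    )
    out = []
    for i in range(design.n_animals):
        if design.noise_cv > 0:
            sigma = np.sqrt(np.log1p(design.noise_cv**2))
            noise = rng.lognormal(-0.5 * sigma**2, sigma, size=t.shape)
        else:
            noise = 1.0
        out.append(TimeCourse(
            animal_id=f"{design.compound}-{i + 1}",
            compound=design.compound,
            times=t,
            pth=mean * noise,
        ))
    return out
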