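"""Simulate-and-recover and calibration studies.

These are the package's own quality-control experiments: they generate data
with the synthetic module, analyse it with the fitting/stats modules, and
summarise how well the known ground truth is recovered.  They are what the
test suite and the reproduction script run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import fit_global_operational
from .models import OperationalModelParams
from .stats import dunnett_critical_value
from .synthetic import AssayDesign, simulate_crc

__all__ = ["RecoveryStudy", "recovery_study", "dunnett_fwer"]


@dataclass
class RecoveryStudy:
    """Outcome of a repeated simulate -> fit -> compare experiment."""

    truth_pKB: float
    truth_log_alphabeta: float
    n_sims: int
    pkb_errors: np.ndarray
    logab_errors: np.ndarray
    pkb_tol: float
    logab_tol: float

    @property
    def joint_rate(self) -> float:
        """Fraction of runs with both parameters inside tolerance."""
        return float(np.mean((np.abs(self.pkb_errors) <= self.pkb_tol)
                             & (np.abs(self.logab_errors) <= self.logab_tol)))

    @property
    def pkb_rate(self) -> float:
        return float(np.mean(np.abs(self.pkb_errors) <= self.pkb_tol))

    @property
    def logab_rate(self) -> float:
        return float(np.mean(np.abs(self.logab_errors) <= self.logab_tol))


def recovery_study(
    truth: OperationalModelParams,
    n_sims: int = 100,
    seed: int = 0,
    design: AssayDesign | None = None,
    n_multistart: int = 10,
    pkb_tol: float = 0.2,
    logab_tol: float = 0.5,
) -> RecoveryStudy:
    """Monte-Carlo parameter recovery for the global operational fit.

    Each replicate simulates the default plate design (4 experiments, 5 %
    of Em additive noise) from ``truth`` and refits it with the standard
    constraint set; errors are fitted minus true values on the log scales.
    Deterministic for a fixed ``seed``.
    """
    base = design or AssayDesign()
    rng = np.random.default_rng(seed)
    sim_seeds = rng.integers(0, 2**31 - 1, size=n_sims)
    pkb_err, logab_err = [], []
    for i in range(n_sims):
        d = AssayDesign(
            agonist_concs=base.agonist_concs, nam_concs=base.nam_concs,
            n_experiments=base.n_experiments,
            n_replicates_per_experiment=base.n_replicates_per_experiment,
            ambient_C=base.ambient_C, noise_sd_pct_Em=base.noise_sd_pct_Em,
            seed=int(sim_seeds[i]),
        )
        data = simulate_crc(d, truth)
        fit = fit_global_operational(data, n_multistart=n_multistart,
                                     seed=int(sim_seeds[i]) % 10000)
        pkb_err.append(fit.pKB - truth.pKB)
        logab_err.append(fit.log_alphabeta - truth.log_alphabeta)
    return RecoveryStudy(
        truth_pKB=truth.pKB, truth_log_alphabeta=truth.log_alphabeta,
        n_sims=n_sims, pkb_errors=np.array(pkb_err),
        logab_errors=np.array(logab_err),
        pkb_tol=pkb_tol, logab_tol=logab_tol,
    )


def dunnett_fwer(
    k: int = 5, n_per_group: int = 5, n_sims: int = 10_000, seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Familywise type-I error of the Dunnett procedure under a global null.

    Simulates ``n_sims`` balanced one-way layouts of ``k`` treatment groups
    plus a control, all drawn from one normal distribution, and counts how
    often the max-|t| statistic exceeds the two-sided critical value.
    """
    df = (k + 1) * (n_per_group - 1)
    crit = dunnett_critical_value(k, df=df, alpha=alpha)
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n_sims, k + 1, n_per_group))
    m = x.mean(axis=2)
    mse = ((x - m[..., None]) ** 2).sum(axis=(1, 2)) / df
    t = (m[:, 1:] - m[:, :1]) / np.sqrt(mse[:, None] * 2.0 / n_per_group)
    return float((np.abs(t).max(axis=1) > crit).mean())
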