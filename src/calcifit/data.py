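"""Tidy data containers for concentration-response plates and in vivo
time courses, with the CSV dialects the pipeline reads and writes.

Concentrations are always molar inside files and DataFrames; reports
pretty-print them in umol/L or mmol/L.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ConcentrationResponseDataset",
    "TimeCourse",
    "RAW_PLATE_COLUMNS",
    "read_plate_csv",
    "read_timecourse_csv",
    "timecourses_to_frame",
    "frame_to_timecourses",
]

#: Required headers of a raw plate CSV (responses not yet normalized).
RAW_PLATE_COLUMNS = [
    "experiment_id",
    "replicate",
    "nam_id",
    "nam_conc_molar",
    "agonist_conc_molar",
    "raw_peak",
    "ionomycin_peak",
]

#: Columns of a normalized concentration-response table.
CRC_COLUMNS = [
    "experiment_id",
    "replicate",
    "nam_id",
    "nam_conc_molar",
    "agonist_conc_molar",
    "response",
]


@dataclass
class ConcentrationResponseDataset:
    """Normalized concentration-response records, the fitting substrate.

    ``data`` is a tidy DataFrame with :data:`CRC_COLUMNS` (``response`` in
    % ionomycin, or % of the vehicle maximum under the ``percent-max``
    normalization).  An optional ``arm`` column labels washout-assay arms
    (``vehicle`` / ``nam`` / ``washout``).

    Attributes
    ----------
    ambient_C : float
        Ambient agonist concentration in the assay buffer, mol/L.
    normalization : str
        ``"ionomycin"`` or ``"percent-max"``.
    truth : dict, optional
        Generating parameters when the dataset is synthetic.
    """

    data: pd.DataFrame
    ambient_C: float = 1e-4
    normalization: str = "ionomycin"
    truth: Optional[dict] = None

    def __post_init__(self) -> None:
        missing = [c for c in CRC_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")
        if len(self.data) == 0:
            raise ValueError("empty dataset")
        if not np.all(np.isfinite(self.data["response"])):
            raise ValueError("non-finite responses")
        if np.any(self.data["nam_conc_molar"] < 0) or np.any(
            self.data["agonist_conc_molar"] < 0
        ):
            raise ValueError("negative concentrations")

    @property
    def nam_concs(self) -> np.ndarray:
        """Sorted unique modulator concentrations (mol/L)."""
        return np.sort(self.data["nam_conc_molar"].unique())

    @property
    def agonist_concs(self) -> np.ndarray:
        return np.sort(self.data["agonist_conc_molar"].unique())

    @property
    def experiments(self) -> list:
        return sorted(self.data["experiment_id"].unique())

    def has_vehicle(self) -> bool:
        return bool((self.data["nam_conc_molar"] == 0).any())

    def subset_nam(self, b: float, rtol: float = 1e-9) -> "ConcentrationResponseDataset":
        """Records at a single modulator concentration ``b`` (mol/L)."""
        col = self.data["nam_conc_molar"]
        mask = np.isclose(col, b, rtol=rtol, atol=0.0) if b > 0 else (col == 0)
        sub = self.data.loc[mask]
        if len(sub) == 0:
            raise ValueError(f"no records at nam_conc_molar={b!r}")
        return ConcentrationResponseDataset(
            sub.reset_index(drop=True), self.ambient_C, self.normalization, self.truth
        )

    def subset_arm(self, arm: str) -> "ConcentrationResponseDataset":
        if "arm" not in self.data.columns:
            raise ValueError("dataset has no 'arm' column")
        sub = self.data.loc[self.data["arm"] == arm]
        if len(sub) == 0:
            raise ValueError(f"no records in arm {arm!r}")
        return ConcentrationResponseDataset(
            sub.reset_index(drop=True), self.ambient_C, self.normalization, self.truth
        )

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)
        if self.truth is not None:
            Path(path).with_suffix(".truth.json").write_text(
                json.dumps(self.truth, indent=2, sort_keys=True)
            )


@dataclass
class TimeCourse:
    """Per-animal sampled plasma PTH (and optionally drug) concentrations.

    ``times`` in minutes, strictly increasing; ``pth`` in pg/mL.
    """

    animal_id: str
    compound: str
    times: np.ndarray
    pth: np.ndarray
    drug_conc: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.pth = np.asarray(self.pth, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.pth.shape:
            raise ValueError("times and pth must be 1-D and the same length")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.pth < 0) or not np.all(np.isfinite(self.pth)):
            raise ValueError("pth must be finite and non-negative")
        if self.drug_conc is not None:
            self.drug_conc = np.asarray(self.drug_conc, dtype=float)
            if self.drug_conc.shape != self.times.shape:
                raise ValueError("drug_conc length mismatch")


def read_plate_csv(path) -> pd.DataFrame:
    """Read a raw plate CSV and validate its headers."""
    df = pd.read_csv(path)
    missing = [c for c in RAW_PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate CSV {path} missing columns: {missing}")
    return df


def read_timecourse_csv(path) -> list[TimeCourse]:
    """Read a tidy time-course CSV (animal_id, compound, time_min,
    pth_pg_ml[, drug_conc]) into per-animal :class:`TimeCourse` objects."""
    df = pd.read_csv(path)
    required = ["animal_id", "compound", "time_min", "pth_pg_ml"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"time-course CSV {path} missing columns: {missing}")
    return frame_to_timecourses(df)


def frame_to_timecourses(df: pd.DataFrame) -> list[TimeCourse]:
    out = []
    for (animal, compound), g in df.groupby(["animal_id", "compound"], sort=True):
        g = g.sort_values("time_min")
        drug = g["drug_conc"].to_numpy() if "drug_conc" in g.columns else None
        out.append(
            TimeCourse(
                animal_id=str(animal),
                compound=str(compound),
                times=g["time_min"].to_numpy(),
                pth=g["pth_pg_ml"].to_numpy(),
                drug_conc=drug,
            )
        )
    return out


def timecourses_to_frame(tcs: list[TimeCourse]) -> pd.DataFrame:
    rows = []
    for tc in tcs:
        for i, t in enumerate(tc.times):
            row = {
                "animal_id": tc.animal_id,
                "compound": tc.compound,
                "time_min": t,
                "pth_pg_ml": tc.pth[i],
            }
            if tc.drug_conc is not None:
                row["drug_conc"] = tc.drug_conc[i]
            rows.append(row)
    return pd.DataFrame(rows)
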