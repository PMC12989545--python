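"""Amplicon melt prediction, derivative melt-curve simulation and the
Ct/Tm positivity rule for SYBR-green qPCR assays.

The decision rule mirrors real-time PCR practice for presence/absence
biomonitoring: a well is positive when amplification crossed threshold
by cycle 30 (Ct <= 30) AND its melt peak lies within 0.5 degC of the
positive control's — both boundaries inclusive, 0.5 degC being the melt
program's step size and hence the measurement uncertainty.

Predicted melt temperatures use the empirical long-duplex formula
Tm = 81.5 + 16.6 log10[Na+] + 0.41 GC% - 675/N. Predicted values are
never compared with an instrument's absolute peak positions (dye
chemistry shifts those systematically); assays compare ampicon peaks via
the difference to a positive control measured on the same instrument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .primers import gc_content


@dataclass
class MeltConfig:
    """Melt program: 72 -> 95 degC in 0.5 degC increments, 50 mM Na+."""

    temp_start_c: float = 72.0
    temp_end_c: float = 95.0
    temp_step_c: float = 0.5
    na_mM: float = 50.0

    def __post_init__(self) -> None:
        if self.temp_start_c >= self.temp_end_c:
            raise ValueError("temp_start_c must be < temp_end_c")
        if self.temp_step_c <= 0:
            raise ValueError("temp_step_c must be positive")

    def grid(self) -> np.ndarray:
        n = int(math.floor((self.temp_end_c - self.temp_start_c) / self.temp_step_c))
        pts = self.temp_start_c + self.temp_step_c * np.arange(n + 1)
        if pts[-1] < self.temp_end_c - 1e-9:
            # step does not divide the range: clamp the final point at the end
            pts = np.append(pts, self.temp_end_c)
        return pts


@dataclass(frozen=True)
class QpcrObservation:
    """One well's measurement. ct/tm_c are None when nothing amplified."""

    sample_id: str
    assay_id: str
    ct: float | None = None
    tm_c: float | None = None
    crop: str = ""
    timepoint_days: int = 0
    group: str = "treated"


@dataclass(frozen=True)
class QpcrCall:
    observation: QpcrObservation
    positive: bool
    reasons: tuple[str, ...]


def amplicon_melt_tm(seq: str, na_mM: float = 50.0) -> float:
    """Empirical melt temperature of a long duplex (length >= 50 bp)."""
    if len(seq) < 50:
        raise ValueError(f"amplicon_melt_tm requires length >= 50, got {len(seq)}")
    gc = gc_content(seq)
    return 81.5 + 16.6 * math.log10(na_mM / 1000.0) + 0.41 * gc - 675.0 / len(seq)


def simulate_melt_curve(
    amplicons: Sequence[tuple[str, float]],
    config: MeltConfig | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    width_c: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Simulate a derivative melt curve (-dF/dT) on the instrument grid.

    Fluorescence is the sum over (sequence, abundance) amplicons of
    abundance * sigmoid((Tm - T)/w) with transition width w = 1 degC;
    the analytic derivative is evaluated on the grid and optional
    Gaussian noise added. Returns (grid, -dF/dT, peak temperatures),
    peaks being per-connected-component argmaxes above half the global
    maximum.
    """
    if not amplicons:
        raise ValueError("simulate_melt_curve requires at least one amplicon")
    config = config or MeltConfig()
    grid = config.grid()
    deriv = np.zeros_like(grid)
    for seq, abundance in amplicons:
        tm = amplicon_melt_tm(seq, config.na_mM)
        x = (tm - grid) / width_c
        sig = 1.0 / (1.0 + np.exp(-x))
        deriv += abundance / width_c * sig * (1.0 - sig)  # -dF/dT
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        deriv = deriv + rng.normal(0.0, noise_sd, size=grid.shape)
    peaks = _find_peaks(grid, deriv)
    return grid, deriv, peaks


def _find_peaks(grid: np.ndarray, deriv: np.ndarray) -> list[float]:
    half_max = deriv.max() / 2.0
    if deriv.max() <= 0:
        return []
    above = deriv > half_max
    peaks: list[float] = []
    i = 0
    n = len(grid)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            seg = slice(i, j)
            peaks.append(float(grid[seg][np.argmax(deriv[seg])]))
            i = j
        else:
            i += 1
    return peaks


def call_sample(
    obs: QpcrObservation,
    control_tm_c: float,
    ct_max: float = 30.0,
    tm_tol_c: float = 0.5,
) -> QpcrCall:
    """Positive iff Ct present and <= ct_max AND |Tm - control| <= tm_tol_c.

    Both thresholds are inclusive. Reason codes explain every negative:
    no_amplification (no Ct), ct_above_threshold, tm_mismatch (Tm absent
    or outside tolerance).
    """
    reasons: list[str] = []
    if obs.ct is None:
        reasons.append("no_amplification")
    elif obs.ct > ct_max:
        reasons.append("ct_above_threshold")
    if obs.ct is not None:
        if obs.tm_c is None or abs(obs.tm_c - control_tm_c) > tm_tol_c:
            reasons.append("tm_mismatch")
    return QpcrCall(observation=obs, positive=not reasons, reasons=tuple(reasons))


def sample_verdicts(calls: Iterable[QpcrCall]) -> dict[str, bool]:
    """Sample-level 'colonized' verdict: positive with >= 1 assay."""
    out: dict[str, bool] = {}
    for c in calls:
        sid = c.observation.sample_id
        out[sid] = out.get(sid, False) or c.positive
    return out


def detection_rates(
    calls: Sequence[QpcrCall],
    expected_groups: Sequence[tuple[str, int, str]] | None = None,
) -> pd.DataFrame:
    """Percent positive per (crop, timepoint, assay) group, 1 decimal.

    Groups listed in expected_groups but absent from the data are
    reported with rate "ND" (no data). Rates are plain floats otherwise.
    """
    if not calls:
        raise ValueError("detection_rates requires at least one call")
    df = pd.DataFrame(
        {
            "crop": [c.observation.crop for c in calls],
            "timepoint_days": [c.observation.timepoint_days for c in calls],
            "assay": [c.observation.assay_id for c in calls],
            "positive": [c.positive for c in calls],
        }
    )
    grouped = (
        df.groupby(["crop", "timepoint_days", "assay"], sort=True)["positive"]
        .agg(n_positive="sum", n_total="count")
        .reset_index()
    )
    grouped["rate_pct"] = (100.0 * grouped["n_positive"] / grouped["n_total"]).round(1)
    if expected_groups:
        have = set(zip(grouped["crop"], grouped["timepoint_days"], grouped["assay"]))
        missing = [g for g in expected_groups if g not in have]
        if missing:
            extra = pd.DataFrame(
                [
                    {"crop": c, "timepoint_days": t, "assay": a,
                     "n_positive": 0, "n_total": 0, "rate_pct": "ND"}
                    for c, t, a in missing
                ]
            )
            grouped = pd.concat([grouped, extra], ignore_index=True)
            grouped = grouped.sort_values(["crop", "timepoint_days", "assay"]).reset_index(drop=True)
    return grouped


def read_qpcr_csv(path) -> list[QpcrObservation]:
    """Read qPCR observations from CSV with columns sample,assay,crop,
    timepoint_days,group,ct,tm_c (ct/tm_c blank = no amplification)."""
    df = pd.read_csv(path)
    obs = []
    for row in df.itertuples(index=False):
        ct = None if pd.isna(row.ct) else float(row.ct)
        tm = None if pd.isna(row.tm_c) else float(row.tm_c)
        obs.append(
            QpcrObservation(
                sample_id=str(row.sample),
                assay_id=str(row.assay),
                ct=ct,
                tm_c=tm,
                crop=str(getattr(row, "crop", "")),
                timepoint_days=int(getattr(row, "timepoint_days", 0)),
                group=str(getattr(row, "group", "treated")),
            )
        )
    return obs
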