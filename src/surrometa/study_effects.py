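"""Treatment-effect estimates and within-study variances from arm-level data.

Each trial contributes up to three outcome blocks: a continuous surrogate
reported as arm means with standard errors (here the mean number of
active MRI lesions, analysed on the log rate-ratio scale), an event-rate
surrogate reported as event counts with patient denominators (annualised
relapse rate, log rate-ratio scale) and a binary final outcome reported
as 2x2 counts (disability progression, log odds-ratio scale).  The SEs
of the log ratios come from the delta method (for the mean and Poisson
rate ratios) and the standard ``sqrt(sum of reciprocal cells)`` formula
for the log odds ratio.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StudyArmRecord",
    "EffectRow",
    "OUTCOME_NAMES",
    "log_odds_ratio",
    "log_rate_ratio_from_means",
    "log_annualised_rate_ratio",
    "build_dataset",
    "read_studies_csv",
    "write_effects_csv",
    "effects_frame",
]

#: fixed outcome order: continuous (MRI-type), rate (relapse-type), binary final
OUTCOME_NAMES = ("mri", "relapse", "progression")

# CSV column names follow the abbreviations of the source table legend:
# Nd/Rd = patients/events for disability progression, Nr/ARr = patients/relapses
# per year, Nm/Rm(SE) = patients/mean lesion count, suffix E/C = arm.
STUDY_CSV_COLUMNS = [
    "study_id",
    "followup_months",
    "NmE", "RmE", "SEmE", "NmC", "RmC", "SEmC",
    "NrE", "ARrE", "NrC", "ARrC",
    "NdE", "RdE", "NdC", "RdC",
]


@dataclass
class StudyArmRecord:
    """Arm-level summary data for one study; any outcome block may be absent."""

    study_id: str
    followup_months: float = 24.0
    # binary final outcome (events / n per arm)
    final_events_trt: int | None = None
    final_n_trt: int | None = None
    final_events_ctl: int | None = None
    final_n_ctl: int | None = None
    # rate outcome (event counts with patient denominators)
    rate_events_trt: int | None = None
    rate_n_trt: int | None = None
    rate_events_ctl: int | None = None
    rate_n_ctl: int | None = None
    # continuous outcome (arm means with SEs)
    cont_mean_trt: float | None = None
    cont_se_trt: float | None = None
    cont_mean_ctl: float | None = None
    cont_se_ctl: float | None = None

    def __post_init__(self) -> None:
        if self.followup_months <= 0:
            raise ValueError("followup_months must be positive")
        for ev, n, arm in [
            (self.final_events_trt, self.final_n_trt, "trt"),
            (self.final_events_ctl, self.final_n_ctl, "ctl"),
        ]:
            if ev is not None and n is not None and not 0 <= ev <= n:
                raise ValueError(
                    f"{self.study_id}: final events must satisfy 0 <= events <= n ({arm})"
                )
        if self.has_continuous:
            if self.cont_se_trt <= 0 or self.cont_se_ctl <= 0:
                raise ValueError(f"{self.study_id}: SEs must be positive")

    @property
    def has_final(self) -> bool:
        return None not in (
            self.final_events_trt, self.final_n_trt,
            self.final_events_ctl, self.final_n_ctl,
        )

    @property
    def has_rate(self) -> bool:
        return None not in (
            self.rate_events_trt, self.rate_n_trt,
            self.rate_events_ctl, self.rate_n_ctl,
        )

    @property
    def has_continuous(self) -> bool:
        return None not in (
            self.cont_mean_trt, self.cont_se_trt,
            self.cont_mean_ctl, self.cont_se_ctl,
        )


@dataclass
class EffectRow:
    """Per-study effect estimates on up to N outcomes with within-study SDs.

    ``y`` and ``sigma`` are length-N vectors with ``nan`` marking missing
    entries; ``within_corr`` is the (shared or per-study) within-study
    correlation matrix between the effect estimates.
    """

    study_id: str
    y: np.ndarray
    sigma: np.ndarray
    within_corr: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.within_corr = np.asarray(self.within_corr, dtype=float)
        n = self.y.size
        if self.sigma.size != n or self.within_corr.shape != (n, n):
            raise ValueError("y, sigma and within_corr dimensions disagree")
        if not np.allclose(self.within_corr, self.within_corr.T) or not np.allclose(
            np.diag(self.within_corr), 1.0
        ):
            raise ValueError("within_corr must be symmetric with unit diagonal")
        off = self.within_corr[~np.eye(n, dtype=bool)]
        if np.any(np.abs(off) >= 1):
            raise ValueError("within-study correlations must lie in (-1, 1)")
        if np.any(self.sigma[np.isfinite(self.sigma)] <= 0):
            raise ValueError("within-study SDs must be positive")
        if np.any(np.isfinite(self.y) & ~np.isfinite(self.sigma)):
            raise ValueError("sigma may be missing only where y is missing")

    @property
    def n_outcomes(self) -> int:
        return self.y.size

    def observed(self) -> np.ndarray:
        """Boolean mask of outcomes with an observed estimate."""
        return np.isfinite(self.y)

    def covariance(self) -> np.ndarray:
        """Within-study covariance matrix (nan rows/cols where sigma missing)."""
        return np.outer(self.sigma, self.sigma) * self.within_corr

    def subset(self, idx) -> "EffectRow":
        idx = np.asarray(idx, dtype=int)
        return EffectRow(
            study_id=self.study_id,
            y=self.y[idx],
            sigma=self.sigma[idx],
            within_corr=self.within_corr[np.ix_(idx, idx)],
        )

    def mask_outcome(self, j: int) -> "EffectRow":
        """Copy with outcome ``j``'s estimate *and* SD marked missing."""
        y = self.y.copy()
        sigma = self.sigma.copy()
        y[j] = np.nan
        sigma[j] = np.nan
        return EffectRow(self.study_id, y, sigma, self.within_corr.copy())


def _check_continuity(cells: list[float], continuity: bool, label: str) -> list[float]:
    if any(c == 0 for c in cells):
        if not continuity:
            raise ValueError(
                f"zero cell in {label}; pass continuity=True to add 0.5 to all cells"
            )
        warnings.warn(
            f"zero cell in {label}: adding 0.5 continuity correction to all cells",
            stacklevel=3,
        )
        return [c + 0.5 for c in cells]
    return cells


def log_odds_ratio(
    events_trt: int,
    n_trt: int,
    events_ctl: int,
    n_ctl: int,
    continuity: bool = False,
) -> tuple[float, float]:
    """Log odds ratio and its SE from 2x2 counts.

    SE is the usual ``sqrt(1/a + 1/b + 1/c + 1/d)`` over the four cells.
    Zero cells raise unless ``continuity`` adds 0.5 to every cell.
    """
    if n_trt <= 0 or n_ctl <= 0:
        raise ValueError("arm sizes must be positive")
    if not (0 <= events_trt <= n_trt and 0 <= events_ctl <= n_ctl):
        raise ValueError("events must satisfy 0 <= events <= n")
    a, b = events_trt, n_trt - events_trt
    c, d = events_ctl, n_ctl - events_ctl
    a, b, c, d = _check_continuity([a, b, c, d], continuity, "2x2 table")
    est = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return est, se


def log_rate_ratio_from_means(
    mean_trt: float, se_trt: float, mean_ctl: float, se_ctl: float
) -> tuple[float, float]:
    """Log ratio of two arm means with a delta-method SE.

    ``se^2 = (se_t/m_t)^2 + (se_c/m_c)^2`` — first-order propagation of
    the arm-mean SEs through the log.
    """
    if mean_trt <= 0 or mean_ctl <= 0:
        raise ValueError("means must be positive for a log ratio")
    if se_trt <= 0 or se_ctl <= 0:
        raise ValueError("SEs must be positive")
    est = math.log(mean_trt / mean_ctl)
    se = math.sqrt((se_trt / mean_trt) ** 2 + (se_ctl / mean_ctl) ** 2)
    return est, se


def log_annualised_rate_ratio(
    count_trt: int,
    n_trt: int,
    count_ctl: int,
    n_ctl: int,
    continuity: bool = False,
) -> tuple[float, float]:
    """Log ratio of two event rates (counts over patient-denominators).

    Counts are treated as Poisson with the denominators as fixed
    exposure, giving the delta-method SE ``sqrt(1/count_t + 1/count_c)``.
    """
    if n_trt <= 0 or n_ctl <= 0:
        raise ValueError("denominators must be positive")
    if count_trt < 0 or count_ctl < 0:
        raise ValueError("counts must be non-negative")
    count_trt, count_ctl = _check_continuity(
        [count_trt, count_ctl], continuity, "rate counts"
    )
    est = math.log((count_trt / n_trt) / (count_ctl / n_ctl))
    se = math.sqrt(1 / count_trt + 1 / count_ctl)
    return est, se


def build_dataset(
    records: list[StudyArmRecord],
    within_corr: np.ndarray,
    continuity: bool = False,
) -> list[EffectRow]:
    """Assemble arm-level records into model-ready effect rows.

    Outcome order is fixed as (continuous MRI-type, rate, binary final);
    absent blocks propagate as missing entries.
    """
    within_corr = np.asarray(within_corr, dtype=float)
    seen: set[str] = set()
    rows: list[EffectRow] = []
    for r in records:
        if r.study_id in seen:
            raise ValueError(f"duplicate study_id {r.study_id!r}")
        seen.add(r.study_id)
        y = np.full(3, np.nan)
        s = np.full(3, np.nan)
        if r.has_continuous:
            y[0], s[0] = log_rate_ratio_from_means(
                r.cont_mean_trt, r.cont_se_trt, r.cont_mean_ctl, r.cont_se_ctl
            )
        if r.has_rate:
            # the rate column is annualised; the Poisson count behind the SE
            # is the total number of events over the whole follow-up
            yrs = r.followup_months / 12.0
            y[1], s[1] = log_annualised_rate_ratio(
                r.rate_events_trt * yrs, r.rate_n_trt,
                r.rate_events_ctl * yrs, r.rate_n_ctl,
                continuity=continuity,
            )
        if r.has_final:
            y[2], s[2] = log_odds_ratio(
                r.final_events_trt, r.final_n_trt,
                r.final_events_ctl, r.final_n_ctl,
                continuity=continuity,
            )
        rows.append(EffectRow(r.study_id, y, s, within_corr))
    return rows


def _opt_int(v) -> int | None:
    return None if pd.isna(v) else int(v)


def _opt_float(v) -> float | None:
    return None if pd.isna(v) else float(v)


def read_studies_csv(path) -> list[StudyArmRecord]:
    """Read the study-level CSV (one row per study; empty fields = missing)."""
    df = pd.read_csv(path)
    missing = set(STUDY_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"studies CSV is missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            StudyArmRecord(
                study_id=str(row["study_id"]),
                followup_months=float(row["followup_months"]),
                final_events_trt=_opt_int(row["RdE"]),
                final_n_trt=_opt_int(row["NdE"]),
                final_events_ctl=_opt_int(row["RdC"]),
                final_n_ctl=_opt_int(row["NdC"]),
                rate_events_trt=_opt_int(row["ARrE"]),
                rate_n_trt=_opt_int(row["NrE"]),
                rate_events_ctl=_opt_int(row["ARrC"]),
                rate_n_ctl=_opt_int(row["NrC"]),
                cont_mean_trt=_opt_float(row["RmE"]),
                cont_se_trt=_opt_float(row["SEmE"]),
                cont_mean_ctl=_opt_float(row["RmC"]),
                cont_se_ctl=_opt_float(row["SEmC"]),
            )
        )
    return records


def effects_frame(rows: list[EffectRow]) -> pd.DataFrame:
    """Tabulate effect rows as study_id, y1..yN, se1..seN."""
    n = rows[0].n_outcomes if rows else 3
    data = {"study_id": [r.study_id for r in rows]}
    for j in range(n):
        data[f"y{j + 1}"] = [r.y[j] for r in rows]
    for j in range(n):
        data[f"se{j + 1}"] = [r.sigma[j] for r in rows]
    return pd.DataFrame(data)


def write_effects_csv(rows: list[EffectRow], path) -> None:
    effects_frame(rows).to_csv(path, index=False)


def write_effects_json(rows: list[EffectRow], path) -> None:
    payload = [
        {
            "study_id": r.study_id,
            "y": [None if not np.isfinite(v) else v for v in r.y],
            "sigma": [None if not np.isfinite(v) else v for v in r.sigma],
            "within_corr": r.within_corr.tolist(),
        }
        for r in rows
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
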