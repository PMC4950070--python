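"""Take-one-out cross-validation of final-outcome predictions.

For each study in turn, the final-outcome estimate *and its SD* are
masked, every candidate model is refitted to the masked data (the
held-out study still contributes its surrogate estimates), the final
outcome is predicted, and the observed estimate is checked against the
95% predicted interval.  Models are compared by the percentage
reduction in predicted-interval width relative to a reference model;
widths are compared on the log-effect scale (symmetric and invariant to
exponentiation of the endpoints), with widths on the exponentiated
scale also reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .bayes_fit import ModelSpec, fit_model, predict_final_outcome
from .study_effects import EffectRow

__all__ = ["CrossvalResult", "cross_validate", "coverage_and_width"]


def coverage_and_width(
    true_values: np.ndarray, intervals: list[tuple[float, float]]
) -> tuple[float, np.ndarray]:
    """Fraction of values inside their intervals, and interval widths."""
    true_values = np.asarray(true_values, dtype=float)
    lo = np.array([iv[0] for iv in intervals], dtype=float)
    hi = np.array([iv[1] for iv in intervals], dtype=float)
    if true_values.size != lo.size:
        raise ValueError("true_values and intervals must have equal length")
    if np.any(lo > hi):
        raise ValueError("interval with lo > hi")
    inside = (lo <= true_values) & (true_values <= hi)
    return float(inside.mean()), hi - lo


@dataclass
class CrossvalResult:
    """Per-study predictions and interval-width comparisons.

    ``folds`` holds one row per (study, model) with the predicted mean /
    median / 95% interval on the log and exponentiated scales, the
    inside-interval flag and the percent width reduction vs the
    reference model (log-scale widths); ``summary`` aggregates the mean
    percent reduction and coverage count per model.
    """

    folds: pd.DataFrame
    summary: pd.DataFrame
    reference: str

    def mean_reduction(self, model: str) -> float:
        return float(self.summary.loc[model, "mean_pct_reduction"])

    def n_covered(self, model: str) -> int:
        return int(self.summary.loc[model, "n_covered"])


def cross_validate(
    data: list[EffectRow],
    specs: list[ModelSpec],
    reference: str,
    final_outcome: int | None = None,
    seed: int | None = None,
) -> CrossvalResult:
    """Run the take-one-out validation over all studies and models.

    Every study must report the final outcome.  Per-fold seeds derive
    deterministically from ``seed`` and the study index, so folds are
    order-independent and reproducible.  The input rows are never
    modified.
    """
    if len(data) < 4:
        raise ValueError("need at least 4 studies for cross-validation")
    names = [s.name for s in specs]
    if reference not in names:
        raise ValueError(f"reference {reference!r} not among models {names}")
    j_final = data[0].n_outcomes - 1 if final_outcome is None else final_outcome
    for row in data:
        if not np.isfinite(row.y[j_final]):
            raise ValueError(
                f"study {row.study_id!r} does not report the final outcome"
            )

    records = []
    failed: list[tuple[str, str]] = []
    master = np.random.SeedSequence(seed)
    for i, row in enumerate(data):
        fold_seed = np.random.SeedSequence(entropy=master.entropy or 0, spawn_key=(i,))
        masked = [r if k != i else r.mask_outcome(j_final) for k, r in enumerate(data)]
        sigma_obs = float(row.sigma[j_final])
        for s_idx, spec in enumerate(specs):
            sub_seed = np.random.default_rng(fold_seed.spawn(1)[0]).integers(0, 2**31 - 1)
            spec_i = replace(spec, seed=int(sub_seed) + s_idx)
            try:
                with warnings.catch_warnings(record=True) as caught:
                    warnings.simplefilter("always")
                    fit = fit_model(masked, spec_i)
                nonconv = any("scale-reduction" in str(w.message) for w in caught)
                pred = predict_final_outcome(
                    fit,
                    masked[i],
                    sigma_final=sigma_obs,
                    rng=np.random.default_rng(int(sub_seed) + 7919 + s_idx),
                )
            except Exception as exc:  # noqa: BLE001 - fold robustness
                warnings.warn(
                    f"fold {row.study_id!r}, model {spec.name!r} failed: {exc}",
                    stacklevel=2,
                )
                failed.append((row.study_id, spec.name))
                continue
            est = pred.estimate
            records.append(
                {
                    "study_id": row.study_id,
                    "model": spec.name,
                    "observed": row.y[j_final],
                    "observed_se": sigma_obs,
                    "pred_mean": est["mean"],
                    "pred_median": est["median"],
                    "pred_lo": est["lo"],
                    "pred_hi": est["hi"],
                    "exp_pred_mean": pred.exp_estimate["mean"],
                    "exp_pred_median": pred.exp_estimate["median"],
                    "exp_pred_lo": pred.exp_estimate["lo"],
                    "exp_pred_hi": pred.exp_estimate["hi"],
                    "true_lo": pred.true_effect["lo"],
                    "true_hi": pred.true_effect["hi"],
                    "inside": bool(est["lo"] <= row.y[j_final] <= est["hi"]),
                    "width": est["hi"] - est["lo"],
                    "exp_width": pred.exp_estimate["hi"] - pred.exp_estimate["lo"],
                    "nonconverged": nonconv,
                }
            )
    folds = pd.DataFrame(records)
    if folds.empty:
        raise RuntimeError("all cross-validation folds failed")

    ref_w = folds[folds.model == reference].set_index("study_id")["width"]
    folds["pct_reduction"] = folds.apply(
        lambda r: 100.0 * (1.0 - r["width"] / ref_w[r["study_id"]])
        if r["study_id"] in ref_w.index
        else np.nan,
        axis=1,
    )
    summ = []
    for name in names:
        sub = folds[folds.model == name]
        summ.append(
            {
                "model": name,
                "n_folds": len(sub),
                "n_covered": int(sub["inside"].sum()),
                "mean_pct_reduction": float(sub["pct_reduction"].mean()),
                "n_failed": sum(1 for s, m in failed if m == name),
            }
        )
    summary = pd.DataFrame(summ).set_index("model")
    return CrossvalResult(folds=folds, summary=summary, reference=reference)
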