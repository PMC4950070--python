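"""Individual-level surrogacy (Prentice criteria) and within-study correlations.

For a surrogate response ``S``, final response ``F`` and randomised
treatment indicator ``Z``, the first two Prentice criteria fit the pair
of regressions ``S = mu_S + alpha*Z + e_S`` and ``F = mu_F + beta*Z + e_F``
with correlated residuals ``Omega``; the fourth criterion fits
``F = mu~ + beta_S*Z + gamma_Z*S + e~`` and requires ``beta_S = 0`` for
full mediation.  The residual correlation after adjusting for treatment
("adjusted association") is

    rho_Z = omega_SF / sqrt(omega_SS * omega_FF)
          = (beta - beta_S)/alpha * sqrt(omega_SS/omega_FF),

and the second form lets published regression coefficients stand in for
unavailable patient data.  Because ``rho_Z`` equals the correlation
between the arm-level mean responses, it converts into the correlation
between two treatment-effect *estimates* (each a difference of arm
effects) through the arm-level variances:

    rho_w = [sqrt(Ve_j Ve_k) + sqrt(Vc_j Vc_k)] * rho_Z / (sigma_j sigma_k).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "PrenticeSet",
    "IpdRecord",
    "adjusted_association",
    "within_correlation",
    "fit_prentice_ipd",
    "read_prentice_csv",
]


@dataclass
class PrenticeSet:
    """Published (or fitted) Prentice-criteria coefficients for one outcome pair."""

    surrogate_label: str
    final_label: str
    alpha: float
    se_alpha: float
    beta: float
    se_beta: float
    beta_S: float
    se_beta_S: float
    omega_SS: float | None = None
    omega_FF: float | None = None
    gamma: float | None = None
    se_gamma: float | None = None
    gamma_Z: float | None = None

    def __post_init__(self) -> None:
        for se in (self.se_alpha, self.se_beta, self.se_beta_S):
            if se <= 0:
                raise ValueError("standard errors must be positive")
        for om in (self.omega_SS, self.omega_FF):
            if om is not None and om <= 0:
                raise ValueError("residual variances must be positive")


@dataclass
class IpdRecord:
    """One patient's surrogate response, final response and treatment arm."""

    S: float
    F: float
    Z: int


def adjusted_association(
    p: PrenticeSet, var_ratio_override: float | None = None
) -> float:
    """Correlation between S and F after adjusting for treatment.

    Evaluates ``(beta - beta_S)/alpha * sqrt(omega_SS/omega_FF)``.  The
    residual-variance ratio is taken from ``p`` when present, else from
    ``var_ratio_override``, else defaults to 1 with a prominent warning
    (published criteria often omit the residual variances, in which case
    the user-supplied within-study correlation is the authoritative
    route).
    """
    if p.alpha == 0:
        raise ValueError("alpha = 0: adjusted association undefined (division by zero)")
    if p.omega_SS is not None and p.omega_FF is not None:
        ratio = p.omega_SS / p.omega_FF
    elif var_ratio_override is not None:
        if var_ratio_override <= 0:
            raise ValueError("variance ratio must be positive")
        ratio = var_ratio_override
    else:
        warnings.warn(
            "residual variances omega_SS/omega_FF unavailable: defaulting the "
            "variance ratio to 1; supply var_ratio_override or user-specified "
            "within-study correlations if available",
            stacklevel=2,
        )
        ratio = 1.0
    rho = (p.beta - p.beta_S) / p.alpha * np.sqrt(ratio)
    if abs(rho) >= 1:
        raise ValueError(
            f"adjusted association {rho:.4f} outside (-1, 1); the supplied "
            "coefficients/variance ratio are mutually inconsistent"
        )
    return float(rho)


def within_correlation(
    var_e_j: float,
    var_e_k: float,
    var_c_j: float,
    var_c_k: float,
    rho_star: float,
    sigma_j: float,
    sigma_k: float,
) -> float:
    """Within-study correlation between two treatment-effect estimates.

    ``var_a_j`` are the variances of the arm-level effects (a = e, c:
    experimental/control) on each outcome, ``rho_star`` the arm-level
    correlation between outcomes (= the adjusted association), and
    ``sigma_j``/``sigma_k`` the SEs of the two treatment-effect estimates.
    """
    for v in (var_e_j, var_e_k, var_c_j, var_c_k):
        if v < 0:
            raise ValueError("arm-level variances must be non-negative")
    if sigma_j <= 0 or sigma_k <= 0:
        raise ValueError("effect-estimate SDs must be positive")
    if not -1 < rho_star < 1:
        raise ValueError("rho_star must lie in (-1, 1)")
    cov = (np.sqrt(var_e_j * var_e_k) + np.sqrt(var_c_j * var_c_k)) * rho_star
    rho_w = cov / (sigma_j * sigma_k)
    if abs(rho_w) >= 1:
        raise ValueError(
            f"within-study correlation {rho_w:.4f} outside (-1, 1): arm "
            f"variances ({var_e_j}, {var_e_k}, {var_c_j}, {var_c_k}) are "
            f"inconsistent with effect SDs ({sigma_j}, {sigma_k})"
        )
    return float(rho_w)


def fit_prentice_ipd(data: list[IpdRecord]) -> PrenticeSet:
    """Fit the Prentice-criteria regressions to patient-level data.

    ``alpha``/``beta`` come from per-equation OLS of S and F on Z (the
    equations share the single regressor Z, so seemingly-unrelated
    estimation coincides with OLS); ``Omega`` from the residual
    cross-moments; ``beta_S``/``gamma_Z`` from the regression of F on
    (Z, S); and ``gamma`` from F on S.  The closed-form identities
    ``beta_S = beta - alpha * omega_FS / omega_SS`` and
    ``gamma_Z = omega_FS / omega_SS`` hold for the fitted values.
    """
    if len(data) < 4:
        raise ValueError("need at least 4 records")
    S = np.array([r.S for r in data], dtype=float)
    F = np.array([r.F for r in data], dtype=float)
    Z = np.array([r.Z for r in data], dtype=float)
    if np.unique(Z).size < 2:
        raise ValueError("treatment indicator Z is constant")
    X = sm.add_constant(Z)
    fit_S = sm.OLS(S, X).fit()
    fit_F = sm.OLS(F, X).fit()
    res_S, res_F = fit_S.resid, fit_F.resid
    dof = len(data) - 2
    omega_SS = float(res_S @ res_S / dof)
    omega_FF = float(res_F @ res_F / dof)
    omega_SF = float(res_S @ res_F / dof)

    XZS = sm.add_constant(np.column_stack([Z, S]))
    fit_med = sm.OLS(F, XZS).fit()
    fit_three = sm.OLS(F, sm.add_constant(S)).fit()

    return PrenticeSet(
        surrogate_label="S",
        final_label="F",
        alpha=float(fit_S.params[1]),
        se_alpha=float(fit_S.bse[1]),
        beta=float(fit_F.params[1]),
        se_beta=float(fit_F.bse[1]),
        beta_S=float(fit_med.params[1]),
        se_beta_S=float(fit_med.bse[1]),
        omega_SS=omega_SS,
        omega_FF=omega_FF,
        gamma=float(fit_three.params[1]),
        se_gamma=float(fit_three.bse[1]),
        gamma_Z=float(fit_med.params[2]),
    )


def read_prentice_csv(path) -> list[PrenticeSet]:
    """Read Prentice-criteria coefficients (one outcome pair per row)."""
    df = pd.read_csv(path)
    required = {
        "surrogate", "final",
        "alpha", "se_alpha", "beta", "se_beta", "beta_S", "se_beta_S",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"prentice CSV is missing columns: {sorted(missing)}")
    out = []
    for _, r in df.iterrows():
        def opt(col):
            if col not in df.columns or pd.isna(r[col]):
                return None
            return float(r[col])

        out.append(
            PrenticeSet(
                surrogate_label=str(r["surrogate"]),
                final_label=str(r["final"]),
                alpha=float(r["alpha"]),
                se_alpha=float(r["se_alpha"]),
                beta=float(r["beta"]),
                se_beta=float(r["se_beta"]),
                beta_S=float(r["beta_S"]),
                se_beta_S=float(r["se_beta_S"]),
                omega_SS=opt("omega_SS"),
                omega_FF=opt("omega_FF"),
            )
        )
    return out
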