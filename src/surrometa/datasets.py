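"""Packaged relapsing-remitting multiple sclerosis (RRMS) example data.

Thirteen randomised trials reporting treatment effects on three outcomes:
mean number of active MRI lesions (continuous surrogate), annualised
relapse rate (rate surrogate) and disability progression (binary final
outcome).  The individual-level surrogacy coefficients (Prentice-criteria
fits on the log scales) come from published IPD analyses of one of the
trials and are used to fix the within-study correlations between the
effect estimates; the published analysis reports the resulting
correlations as (0.25, 0.09, 0.09) for the (MRI-relapse, MRI-progression,
relapse-progression) pairs, constant across studies.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .prentice_within import PrenticeSet
from .study_effects import EffectRow, StudyArmRecord, build_dataset, read_studies_csv

__all__ = [
    "load_rrms_studies",
    "load_rrms_prentice",
    "rrms_within_correlations",
    "rrms_effects",
]

#: Within-study correlations between effect estimates for the outcome pairs
#: (MRI, relapse), (MRI, progression), (relapse, progression); derived from
#: the Prentice-criteria coefficients of a single study and applied to all.
RRMS_WITHIN_CORR_PAIRS = (0.25, 0.09, 0.09)


def _data_path(name: str):
    return resources.files("surrometa.data") / name


def load_rrms_studies() -> list[StudyArmRecord]:
    """Arm-level summary data for the 13 RRMS trials."""
    with resources.as_file(_data_path("rrms_table1.csv")) as p:
        return read_studies_csv(p)


def load_rrms_prentice() -> list[PrenticeSet]:
    """Published individual-level surrogacy coefficients (three outcome pairs)."""
    with resources.as_file(_data_path("rrms_prentice.csv")) as p:
        df = pd.read_csv(p)
    out = []
    for _, r in df.iterrows():
        out.append(
            PrenticeSet(
                surrogate_label=r["surrogate"],
                final_label=r["final"],
                alpha=float(r["alpha"]),
                se_alpha=float(r["se_alpha"]),
                beta=float(r["beta"]),
                se_beta=float(r["se_beta"]),
                beta_S=float(r["beta_S"]),
                se_beta_S=float(r["se_beta_S"]),
                omega_SS=None if pd.isna(r["omega_SS"]) else float(r["omega_SS"]),
                omega_FF=None if pd.isna(r["omega_FF"]) else float(r["omega_FF"]),
            )
        )
    return out


def rrms_within_correlations() -> np.ndarray:
    """The 3x3 within-study correlation matrix used for the RRMS analysis."""
    r12, r13, r23 = RRMS_WITHIN_CORR_PAIRS
    return np.array([[1.0, r12, r13], [r12, 1.0, r23], [r13, r23, 1.0]])


def rrms_effects() -> list[EffectRow]:
    """Model-ready effect rows for the 13 RRMS trials.

    Effects on the log MRI rate-ratio, log annualised relapse-rate-ratio
    and log odds-ratio (progression) scales, with the constant
    within-study correlation matrix.
    """
    return build_dataset(load_rrms_studies(), rrms_within_correlations())
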