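"""The input/output flow (IOF) imbalance statistic for CSF spaces.

For every CSF space (region) and disease stage (e.g. control, mild,
severe), the mean filtration rate ``k_in'`` and mean evacuation rate
``k_out'`` over subjects are normalized against the same-region control
means, and their ratio

    IOF = mean(k_in') / control-normalized mean(k_out')

quantifies which flow mechanism is disturbed: the input mechanism
predominates if IOF > 1, the output mechanism if IOF < 1, and the control
stage has IOF = 1 by construction.  When IOF < 1 the reciprocal 1/IOF is
reported alongside, the conventional presentation for output-predominant
disturbances.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["RATE_COLUMNS", "stage_means", "normalize_to_control", "compute_iof"]

RATE_COLUMNS = ["subject", "region", "stage", "k_in_prime", "k_out_prime"]


def _validate_rates(rates: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RATE_COLUMNS if c not in rates.columns]
    if missing:
        raise ValueError(f"rates table is missing columns {missing}")
    if len(rates) == 0:
        raise ValueError("rates table is empty")
    for col in ("k_in_prime", "k_out_prime"):
        vals = pd.to_numeric(rates[col], errors="coerce")
        if vals.isna().any():
            bad = rates.index[vals.isna()].tolist()[:5]
            raise ValueError(f"non-numeric {col} values at rows {bad}")
        if (vals < 0).any():
            raise ValueError(f"{col} must be >= 0")
    return rates


def stage_means(rates: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean rates per (region, stage) group.

    Parameters
    ----------
    rates
        Long-format table with columns ``subject, region, stage,
        k_in_prime, k_out_prime`` (one row per subject and CSF space).

    Returns
    -------
    DataFrame with columns ``region, stage, k_in_prime, k_out_prime,
    n_subjects``, sorted by region then stage.
    """
    _validate_rates(rates)
    grouped = (
        rates.groupby(["region", "stage"], sort=True)
        .agg(
            k_in_prime=("k_in_prime", "mean"),
            k_out_prime=("k_out_prime", "mean"),
            n_subjects=("subject", "size"),
        )
        .reset_index()
    )
    empty = grouped[grouped["n_subjects"] == 0]
    if len(empty):
        raise ValueError(f"empty (region, stage) groups: {empty}")
    return grouped


def normalize_to_control(means: pd.DataFrame, control_stage: str) -> pd.DataFrame:
    """Divide each stage mean by the same-region control mean, per rate.

    Raises if a region lacks the control stage or a control mean is zero
    (normalization undefined).
    """
    out = means.copy()
    ctrl = means[means["stage"] == control_stage].set_index("region")
    for region in means["region"].unique():
        if region not in ctrl.index:
            raise ValueError(
                f"region {region!r} has no control stage {control_stage!r}"
            )
    for col in ("k_in_prime", "k_out_prime"):
        ref = ctrl[col]
        if (ref == 0).any():
            zero_regions = ref.index[ref == 0].tolist()
            raise ZeroDivisionError(
                f"control mean {col} is zero in regions {zero_regions}; "
                "normalization is undefined"
            )
    out["normalized_in"] = (
        out["k_in_prime"].to_numpy()
        / ctrl["k_in_prime"].reindex(out["region"]).to_numpy()
    )
    out["normalized_out"] = (
        out["k_out_prime"].to_numpy()
        / ctrl["k_out_prime"].reindex(out["region"]).to_numpy()
    )
    return out


def compute_iof(
    rates: pd.DataFrame, control_stage: str, tol: float = 1e-9
) -> pd.DataFrame:
    """Full IOF pipeline: group means → control normalization → ratio.

    Parameters
    ----------
    rates
        Per-subject rate table (see :func:`stage_means`).
    control_stage
        Stage label of the normal-brain group; must exist in every region.
    tol
        Half-width of the "balanced" band around IOF = 1.  At ``tol=0``
        the binary input/output rule is recovered exactly.

    Returns
    -------
    DataFrame with one row per (region, stage): ``region, stage,
    normalized_in, normalized_out, iof, iof_reciprocal, predominance,
    n_subjects``.  ``iof_reciprocal`` is 1/IOF where IOF < 1 and NaN
    otherwise; the control stage has ``iof == 1.0`` exactly.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    norm = normalize_to_control(stage_means(rates), control_stage)
    n_out = norm["normalized_out"].to_numpy()
    if np.any(n_out <= 0):
        raise ValueError("normalized output rate must be > 0 to form IOF")
    iof = norm["normalized_in"].to_numpy() / n_out
    predominance = np.where(
        iof > 1.0 + tol, "input", np.where(iof < 1.0 - tol, "output", "balanced")
    )
    out = norm[
        ["region", "stage", "normalized_in", "normalized_out", "n_subjects"]
    ].copy()
    out["iof"] = iof
    out["iof_reciprocal"] = np.where(iof < 1.0, 1.0 / iof, np.nan)
    out["predominance"] = predominance
    return out[
        [
            "region",
            "stage",
            "normalized_in",
            "normalized_out",
            "iof",
            "iof_reciprocal",
            "predominance",
            "n_subjects",
        ]
    ]
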