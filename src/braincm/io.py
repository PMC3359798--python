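"""Tabular and image IO: curve tables, rate tables, results, phantoms.

Curves travel as long-format delimited text (TSV by default, CSV by file
extension) with columns ``subject, region, time_min, conc_mM``; fitted
parameters and IOF results are written as TSV or JSON with numbers at 10
significant digits and a deterministic column order; phantoms go to
NIfTI-1 with the frame period stored in the header's temporal zoom.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .fitting import FitResult
from .models import BloodParams, CSFParams, ConcentrationCurve, TissueParams

__all__ = [
    "read_curves",
    "write_curves",
    "read_rates",
    "write_results",
    "write_phantom",
    "read_phantom",
    "write_manifest",
]

log = logging.getLogger("braincm")

CURVE_COLUMNS = ["subject", "region", "time_min", "conc_mM"]
FLOAT_FMT = "%.10g"


class ParseError(ValueError):
    """Malformed input table; the message carries the offending row(s)."""


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_curves(path) -> list[tuple[str, str, ConcentrationCurve]]:
    """Read a long-format curve table into per-(subject, region) curves.

    Rows are grouped by ``(subject, region)`` and sorted by time within
    each group.  Duplicated times inside a group, missing columns or
    non-numeric cells raise :class:`ParseError` naming the 1-based data
    row involved.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    for col in ("time_min", "conc_mM"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()] + 2  # header + 1-based
        nan_rows = df.index[df[col].isna()] + 2
        bad = sorted(set(bad.tolist()) | set(nan_rows.tolist()))
        if bad:
            raise ParseError(f"{path}: non-numeric {col} at file row(s) {bad[:10]}")
        df[col] = vals
    out = []
    for (subject, region), grp in df.groupby(["subject", "region"], sort=True):
        grp = grp.sort_values("time_min")
        times = grp["time_min"].to_numpy()
        if np.any(np.diff(times) <= 0):
            dup_at = grp.index[1:][np.diff(times) <= 0] + 2
            raise ParseError(
                f"{path}: duplicated/non-increasing time for subject "
                f"{subject!r} region {region!r} at file row(s) {dup_at.tolist()}"
            )
        out.append(
            (str(subject), str(region),
             ConcentrationCurve(times, grp["conc_mM"].to_numpy()))
        )
    if not out:
        raise ParseError(f"{path}: no curves found")
    return out


def write_curves(records, path) -> None:
    """Write ``(subject, region, curve)`` records as a long-format table."""
    path = Path(path)
    frames = [
        pd.DataFrame(
            {"subject": subject, "region": region,
             "time_min": curve.times, "conc_mM": curve.values}
        )
        for subject, region, curve in records
    ]
    df = pd.concat(frames, ignore_index=True)[CURVE_COLUMNS]
    df.to_csv(path, sep=_sep_for(path), index=False, float_format=FLOAT_FMT)


def read_rates(path) -> pd.DataFrame:
    """Read a per-subject CSF rate table (input to the IOF statistic)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    required = ["subject", "region", "stage", "k_in_prime", "k_out_prime"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return df


_PARAM_ORDER = {
    BloodParams: ["c_in", "k_out", "hct"],
    TissueParams: ["k_trans", "k_ep", "k_pi", "k_ip",
                   "v_blood", "v_ees", "v_ies", "v_now"],
    CSFParams: ["k_in_prime", "k_out_prime", "v_blood", "v_csf"],
}


def fit_results_frame(results) -> pd.DataFrame:
    """Flatten ``(subject, region, FitResult)`` records into a table."""
    rows = []
    for subject, region, res in results:
        row = {"subject": subject, "region": region}
        order = _PARAM_ORDER[type(res.params)]
        for name in order:
            row[name] = getattr(res.params, name)
        row.update(
            rss=res.rss,
            converged=res.converged,
            n_iter=res.n_iter,
            bounds_hit=";".join(res.bounds_hit),
            blood_only=res.blood_only,
        )
        rows.append(row)
    if not rows:
        raise ValueError("no fit results to write")
    return pd.DataFrame(rows)


def write_results(results, path, fmt: str = "tsv") -> None:
    """Write fit results or an IOF table as TSV or JSON.

    ``results`` is either a DataFrame (e.g. from
    :func:`braincm.iof.compute_iof`) or a list of
    ``(subject, region, FitResult)`` records.  Numbers are rendered with
    10 significant digits; column order is fixed by construction.
    """
    if fmt not in ("tsv", "json"):
        raise ValueError(f"format must be 'tsv' or 'json', got {fmt!r}")
    df = results if isinstance(results, pd.DataFrame) else fit_results_frame(results)
    if len(df) == 0:
        raise ValueError("no results to write")
    path = Path(path)
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    else:
        records = json.loads(df.to_json(orient="records"))
        path.write_text(json.dumps(records, indent=1, allow_nan=True) + "\n")


def write_phantom(
    image4d: np.ndarray,
    path,
    t_step_min: float,
    truth: dict[str, np.ndarray] | None = None,
    truth_dir=None,
) -> None:
    """Write a 4D phantom as NIfTI-1, frame period in the temporal zoom.

    Truth maps, if given, are written as 3D NIfTI files
    ``<name>.nii`` under ``truth_dir``.
    """
    img = nib.Nifti1Image(np.asarray(image4d, dtype=np.float64), np.eye(4))
    zooms = list(img.header.get_zooms())
    zooms[3] = t_step_min
    img.header.set_zooms(zooms)
    nib.save(img, str(path))
    if truth:
        truth_dir = Path(truth_dir if truth_dir is not None else Path(path).parent)
        truth_dir.mkdir(parents=True, exist_ok=True)
        for name, arr in truth.items():
            nib.save(
                nib.Nifti1Image(np.asarray(arr, dtype=np.float64), np.eye(4)),
                str(truth_dir / f"{name}.nii"),
            )


def read_phantom(path) -> tuple[np.ndarray, float]:
    """Read a 4D phantom NIfTI; returns (array, frame period in minutes)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ParseError(f"{path}: expected a 4D image, got shape {data.shape}")
    return data, float(img.header.get_zooms()[3])


def write_manifest(path, seed, config_hash: str, **extra) -> None:
    """Record run provenance: seed, config hash, package version."""
    from . import __version__

    manifest = {
        "package": "braincm",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash,
        **extra,
    }
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    log.info("run manifest: seed=%s config_hash=%s", seed, config_hash)
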