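"""Reading trial tables, writing result records, and the estimate report."""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .estimators import AteEstimate, TrialData, estimate
from .inference import z_test

__all__ = [
    "TrialParseError",
    "read_trial_csv",
    "write_trial_csv",
    "run_estimate",
    "write_results",
]

DEFAULT_COLUMNS = {"y": "y", "t": "t", "f": "f"}


class TrialParseError(ValueError):
    """A trial table failed validation; the message names row/column."""


def read_trial_csv(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    delimiter: str | None = None,
) -> TrialData:
    """Read a delimited trial table into a validated :class:`TrialData`.

    Expects header columns ``y`` (outcome), ``t`` (arm, 0/1) and ``f``
    (prognostic score); other names can be mapped via ``column_map``,
    e.g. ``{"y": "adas13_change"}``.  The delimiter is sniffed unless
    given explicitly.
    """
    cols = {**DEFAULT_COLUMNS, **(column_map or {})}
    try:
        df = pd.read_csv(path, sep=delimiter, engine="python")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed file
        raise TrialParseError(f"cannot parse {path}: {exc}") from exc
    for key in ("y", "t", "f"):
        if cols[key] not in df.columns:
            raise TrialParseError(
                f"missing column {cols[key]!r} (for {key}) in {path}; "
                f"found {list(df.columns)}"
            )
    for key in ("y", "t", "f"):
        col = df[cols[key]]
        if col.isna().any():
            row = int(col.isna().idxmax())
            raise TrialParseError(
                f"missing value in column {cols[key]!r} at row {row}"
            )
    t_raw = df[cols["t"]]
    bad = ~t_raw.isin([0, 1])
    if bad.any():
        row = int(bad.idxmax())
        val = t_raw.iloc[row]
        val = val.item() if hasattr(val, "item") else val
        raise TrialParseError(
            f"arm indicator {cols['t']!r} must be 0/1; found {val} at row {row}"
        )
    try:
        return TrialData(
            y=df[cols["y"]].to_numpy(dtype=float),
            t=t_raw.to_numpy(dtype=int),
            f=df[cols["f"]].to_numpy(dtype=float),
        )
    except ValueError as exc:
        raise TrialParseError(str(exc)) from exc


def write_trial_csv(data: TrialData, path: str | Path) -> None:
    pd.DataFrame({"y": data.y, "t": data.t, "f": data.f}).to_csv(path, index=False)


def run_estimate(
    data: TrialData,
    methods: tuple[str, ...] = ("reference", "ppi", "ppct", "ppct2", "ancova"),
    alpha: float = 0.05,
    lam: float | None = None,
) -> pd.DataFrame:
    """Compare estimators on one dataset.

    One row per requested method: point estimate, standard error,
    normal confidence interval, the weight used, and the relative sample
    size of an equally powered trial (reference = 100; proportional to
    the variance estimate).  A method that fails contributes a row with
    its error message rather than aborting the report.
    """
    records = []
    v_ref = None
    ests: dict[str, AteEstimate | str] = {}
    for meth in dict.fromkeys(["reference", *methods]):
        try:
            ests[meth] = estimate(data, meth, lam=lam)
        except Exception as exc:
            ests[meth] = f"{type(exc).__name__}: {exc}"
    ref = ests["reference"]
    if isinstance(ref, AteEstimate) and ref.variance > 0:
        v_ref = ref.variance
    for meth in methods:
        est = ests[meth]
        if isinstance(est, str):
            records.append({"method": meth, "error": est})
            continue
        test = z_test(est, alpha=alpha)
        records.append(
            {
                "method": meth,
                "ate": est.ate,
                "se": est.se,
                "ci_low": test.ci_low,
                "ci_high": test.ci_high,
                "lambda": est.lam,
                "rel_sample_size": (
                    100.0 * est.variance / v_ref if v_ref else float("nan")
                ),
                "warnings": ";".join(est.warnings),
            }
        )
    return pd.DataFrame(records)


def _round_floats(obj, sig: int = 12):
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, (np.floating,)):
        return float(f"{float(obj):.{sig}g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def write_results(
    obj,
    path: str | Path,
    format: str = "json",
    seed: int | None = None,
) -> None:
    """Serialize a result object (records, dict or DataFrame) to disk.

    JSON output wraps the payload with the package version, the seed
    used and a UTC timestamp; floats are written at 12 significant
    digits so round-trips are stable across platforms.
    """
    from . import __version__

    path = Path(path)
    if isinstance(obj, pd.DataFrame):
        payload = obj.to_dict(orient="records")
    elif hasattr(obj, "to_dict"):
        payload = obj.to_dict()
    else:
        payload = obj
    if format == "json":
        doc = {
            "version": __version__,
            "seed": seed,
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "results": _round_floats(payload),
        }
        path.write_text(json.dumps(doc, indent=2) + "\n")
    elif format == "csv":
        df = obj if isinstance(obj, pd.DataFrame) else pd.DataFrame(payload or [])
        df.to_csv(path, index=False, float_format="%.12g")
    else:
        raise ValueError(f"unknown format {format!r}")
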