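"""Machine-readable reports with reproducibility provenance.

Every report carries a provenance block (package version, configuration,
seed) sufficient to reproduce deterministic outputs bit-for-bit.  Values are
emitted at full precision with display-rounded companions where the field's
reporting convention rounds (percentages to one decimal).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping, Optional

import pandas as pd

from . import __version__
from .extrapolation import ErrorModel, extrapolated_metrics, normalized_mae
from .metrics import summarize


def provenance(config: Mapping[str, Any], seed: Optional[int] = None) -> dict[str, Any]:
    """Provenance block for a report: version + full configuration + seed."""
    return {"package": "berrymetrics", "version": __version__, "seed": seed, "config": dict(config)}


def counting_report(est, ref, label: str = "counting") -> dict[str, Any]:
    """Paired-series validation report: ME, sigma_E, MPE (+sd), MAE, RMSE."""
    stats = summarize(est, ref)
    stats["k"] = len(est)
    stats["mpe_pct_rounded"] = round(stats["mpe_pct"])
    return {"metric_set": label, **stats}


def extrapolation_report(
    model: ErrorModel, b: int, berries_per_cluster: float
) -> dict[str, Any]:
    """One multi-bunch extrapolation row: ME^B, MAE^B, MAE_norm, RMSE^B."""
    m = extrapolated_metrics(model, b)
    mae_norm = normalized_mae(m, berries_per_cluster)
    return {
        "b": m.b,
        "me": model.me,
        "sigma_e": model.sigma_e,
        "berries_per_cluster": berries_per_cluster,
        "me_b": m.me_b,
        "mae_b": m.mae_b,
        "mae_norm_pct": mae_norm,
        "mae_norm_pct_rounded": round(mae_norm, 1),
        "rmse_b": m.rmse_b,
    }


def write_report(payload: dict[str, Any] | pd.DataFrame, path: str | Path) -> None:
    """Write a report as JSON or CSV depending on the path extension."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        if isinstance(payload, pd.DataFrame):
            payload = payload.to_dict(orient="records")
        path.write_text(json.dumps(payload, indent=1, default=float) + "\n")
    elif path.suffix.lower() == ".csv":
        df = payload if isinstance(payload, pd.DataFrame) else pd.DataFrame([payload])
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported report format {path.suffix!r} (use .json or .csv)")
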