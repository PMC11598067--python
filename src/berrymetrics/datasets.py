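"""Validation-dataset records, packaged reference tables, and annotation I/O.

The package ships the published validation measurements of ten Flame-variety
grape bunches as machine-readable CSV fixtures: per-bunch ground truth
(total berry count, caliper-measured mean radius in mm) with three annotated
views per bunch at 0/120/240 degree rotations (visible count, mean visible
radius in px), plus the detector's estimated counts for the same thirty views.

The estimate table stores the raw printed count *and* the signed difference
against ground truth.  The difference column is authoritative: the published
aggregate statistics are computed from the errors, and one cell (Bunch_06,
view 3) has a raw count inconsistent with its difference.  Loaders
reconstruct ``n_est = n_visible + diff`` and flag any inconsistent row
instead of silently passing it through.

User annotation/prediction files are read and written in the same schema,
as CSV or JSON (JSON additionally carries optional per-berry radius lists).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

VIEW_ANGLES_DEG = {1: 0.0, 2: 120.0, 3: 240.0}


class SchemaError(ValueError):
    """An annotation file violates the documented column schema."""


class FixtureIntegrityError(RuntimeError):
    """A packaged fixture failed its integrity check."""


@dataclass(frozen=True)
class BunchRecord:
    """Ground truth for one grape bunch.

    ``n_total`` is the caliper-verified number of berries in the whole bunch;
    ``r_mean_total_mm``/``r_sd_total_mm`` the mean and sd of their radii in mm.
    ``per_berry_radii_mm`` is optional because the published table prints only
    per-bunch summaries.
    """

    bunch_id: str
    n_total: int
    r_mean_total_mm: float
    r_sd_total_mm: float
    per_berry_radii_mm: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValueError(f"{self.bunch_id}: n_total must be >= 1, got {self.n_total}")
        if self.r_mean_total_mm <= 0:
            raise ValueError(f"{self.bunch_id}: mean radius must be > 0 mm")
        if self.r_sd_total_mm < 0:
            raise ValueError(f"{self.bunch_id}: radius sd must be >= 0 mm")
        if self.per_berry_radii_mm is not None:
            if len(self.per_berry_radii_mm) != self.n_total:
                raise ValueError(
                    f"{self.bunch_id}: {len(self.per_berry_radii_mm)} per-berry radii "
                    f"for n_total={self.n_total}"
                )


@dataclass(frozen=True)
class ViewAnnotation:
    """Manual annotation of one view (image) of a bunch: visible berries only."""

    bunch_id: str
    view_index: int
    n_visible: int
    r_mean_px: float
    per_berry_radii_px: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.view_index not in VIEW_ANGLES_DEG:
            raise SchemaError(f"{self.bunch_id}: view_index must be in {{1,2,3}}, got {self.view_index}")
        if self.n_visible < 0:
            raise SchemaError(f"{self.bunch_id}: n_visible must be >= 0, got {self.n_visible}")
        if self.r_mean_px <= 0:
            raise ValueError(f"{self.bunch_id}: mean radius must be > 0 px")
        if self.per_berry_radii_px is not None and len(self.per_berry_radii_px) != self.n_visible:
            raise ValueError(f"{self.bunch_id} view {self.view_index}: radius list length mismatch")


@dataclass(frozen=True)
class ViewEstimate:
    """Detector output for one view: estimated count and mean radius.

    ``n_est_printed`` preserves the raw published count where it differs from
    the difference-reconstructed ``n_est`` (provenance); ``inconsistent``
    marks that disagreement.
    """

    bunch_id: str
    view_index: int
    n_est: int
    r_mean_est_px: Optional[float] = None
    n_est_printed: Optional[int] = None
    inconsistent: bool = False

    def __post_init__(self) -> None:
        if self.view_index not in VIEW_ANGLES_DEG:
            raise SchemaError(f"{self.bunch_id}: view_index must be in {{1,2,3}}, got {self.view_index}")
        if self.n_est < 0:
            raise SchemaError(f"{self.bunch_id}: n_est must be >= 0, got {self.n_est}")
        if self.r_mean_est_px is not None and self.r_mean_est_px <= 0:
            raise ValueError(f"{self.bunch_id}: estimated mean radius must be > 0 px")


def _fixture_path(name: str):
    return resources.files("berrymetrics").joinpath("data", name)


def load_flame_reference() -> list[tuple[BunchRecord, list[ViewAnnotation]]]:
    """Load the packaged ground-truth table: 10 bunches x 3 annotated views.

    Returns
    -------
    list of (BunchRecord, [ViewAnnotation, ViewAnnotation, ViewAnnotation])
        Views ordered by view_index (rotations 0/120/240 degrees).
    """
    with resources.as_file(_fixture_path("flame_reference.csv")) as p:
        df = pd.read_csv(p)
    out: list[tuple[BunchRecord, list[ViewAnnotation]]] = []
    for bunch_id, grp in df.groupby("bunch_id", sort=True):
        if len(grp) != 3 or sorted(grp["view_index"]) != [1, 2, 3]:
            raise FixtureIntegrityError(f"{bunch_id}: expected exactly views 1,2,3")
        head = grp.iloc[0]
        rec = BunchRecord(
            bunch_id=str(bunch_id),
            n_total=int(head["n_total"]),
            r_mean_total_mm=float(head["r_mean_total_mm"]),
            r_sd_total_mm=float(head["r_sd_total_mm"]),
        )
        views = []
        for _, row in grp.sort_values("view_index").iterrows():
            ann = ViewAnnotation(
                bunch_id=str(bunch_id),
                view_index=int(row["view_index"]),
                n_visible=int(row["n_visible"]),
                r_mean_px=float(row["r_mean_px"]),
            )
            if ann.n_visible > rec.n_total:
                raise FixtureIntegrityError(f"{bunch_id}: visible count exceeds total")
            views.append(ann)
        out.append((rec, views))
    if len(out) != 10:
        raise FixtureIntegrityError(f"expected 10 bunches, got {len(out)}")
    return out


def load_flame_estimates() -> list[ViewEstimate]:
    """Load the packaged detector estimates for the 30 validation views.

    The estimated count is reconstructed as ground truth + printed difference;
    rows whose raw printed count disagrees with that reconstruction are
    flagged ``inconsistent`` (the difference stays authoritative).
    """
    reference = {
        (rec.bunch_id, ann.view_index): ann.n_visible
        for rec, views in load_flame_reference()
        for ann in views
    }
    with resources.as_file(_fixture_path("flame_estimates.csv")) as p:
        df = pd.read_csv(p)
    estimates: list[ViewEstimate] = []
    for _, row in df.iterrows():
        key = (str(row["bunch_id"]), int(row["view_index"]))
        if key not in reference:
            raise FixtureIntegrityError(f"estimate row {key} has no reference")
        gt = reference[key]
        printed = int(row["n_est_printed"])
        diff = int(row["diff_printed"])
        n_est = gt + diff
        estimates.append(
            ViewEstimate(
                bunch_id=key[0],
                view_index=key[1],
                n_est=n_est,
                n_est_printed=printed,
                inconsistent=(printed != n_est),
            )
        )
    if len(estimates) != 30:
        raise FixtureIntegrityError(f"expected 30 estimates, got {len(estimates)}")
    return estimates


def paired_counts() -> tuple[np.ndarray, np.ndarray]:
    """(estimated, reference) visible-berry counts for the 30 packaged views."""
    ref = {
        (rec.bunch_id, ann.view_index): ann.n_visible
        for rec, views in load_flame_reference()
        for ann in views
    }
    ests = load_flame_estimates()
    est = np.array([e.n_est for e in ests], dtype=float)
    refv = np.array([ref[(e.bunch_id, e.view_index)] for e in ests], dtype=float)
    return est, refv


# ---------------------------------------------------------------------------
# user annotation / prediction files
# ---------------------------------------------------------------------------

_ANNOTATION_COLUMNS = ["bunch_id", "view_index", "n_visible", "r_mean_px"]
_ESTIMATE_COLUMNS = ["bunch_id", "view_index", "n_est", "r_mean_est_px"]


def write_annotations(records: Sequence[ViewAnnotation | ViewEstimate], path: str | Path) -> None:
    """Write annotation or estimate records to CSV or JSON (by extension).

    CSV carries one row per (bunch, view); JSON additionally serializes
    optional per-berry radius lists.  An empty record list produces a valid
    empty file with a header.
    """
    path = Path(path)
    kinds = {type(r) for r in records}
    if len(kinds) > 1:
        raise SchemaError("cannot mix ViewAnnotation and ViewEstimate in one file")
    is_estimate = kinds == {ViewEstimate}
    if path.suffix.lower() == ".json":
        payload = [asdict(r) for r in records]
        path.write_text(json.dumps(payload, indent=1))
        return
    cols = _ESTIMATE_COLUMNS if is_estimate else _ANNOTATION_COLUMNS
    rows = []
    for r in records:
        d = asdict(r)
        rows.append({c: d.get(c) for c in cols})
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_annotations(path: str | Path, kind: str = "annotation") -> list[ViewAnnotation] | list[ViewEstimate]:
    """Read a user annotation (``kind='annotation'``) or estimate (``'estimate'``) file.

    Accepts the documented CSV and JSON schemas; raises :class:`SchemaError`
    on missing required columns, negative counts or unknown view indices.
    """
    path = Path(path)
    if kind not in ("annotation", "estimate"):
        raise ValueError(f"kind must be 'annotation' or 'estimate', got {kind!r}")
    cls = ViewAnnotation if kind == "annotation" else ViewEstimate
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text())
        out = []
        for d in raw:
            d = dict(d)
            for key in ("per_berry_radii_mm", "per_berry_radii_px"):
                if d.get(key) is not None:
                    d[key] = tuple(d[key])
            try:
                out.append(cls(**d))
            except TypeError as exc:
                raise SchemaError(f"{path}: bad record {d}: {exc}") from exc
        return out
    df = pd.read_csv(path)
    required = _ANNOTATION_COLUMNS if kind == "annotation" else ["bunch_id", "view_index", "n_est"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    out = []
    for _, row in df.iterrows():
        if kind == "annotation":
            out.append(
                ViewAnnotation(
                    bunch_id=str(row["bunch_id"]),
                    view_index=int(row["view_index"]),
                    n_visible=int(row["n_visible"]),
                    r_mean_px=float(row["r_mean_px"]),
                )
            )
        else:
            r = row.get("r_mean_est_px")
            out.append(
                ViewEstimate(
                    bunch_id=str(row["bunch_id"]),
                    view_index=int(row["view_index"]),
                    n_est=int(row["n_est"]),
                    r_mean_est_px=None if r is None or pd.isna(r) else float(r),
                )
            )
    return out
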