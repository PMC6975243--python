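"""Cohort measurement tables and report rendering.

``measure_cohort`` walks a manifest of facet meshes, runs the appropriate
analysis per anatomical role and collects one row per facet;
``summarize`` reduces each numeric column to the ``mean (min-max)`` form
used in the published tables; ``render_report`` produces the
human-readable table (2 decimals) while the JSON keeps full precision.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import geom_core, morphometry
from .errors import SchemaError, ValidationError
from .mesh_io import OrientationSpec, TriangleMesh, read_mesh, read_orientation

log = logging.getLogger(__name__)

MEASURE_SCHEMA = "facetmorph-measure-1"

#: roles analysed with the two-sphere (bicondylar) decomposition
BICONDYLAR_ROLES = {"hamate5", "mc5"}
#: roles additionally measured by the 3-point mid-axial radius
THREE_POINT_ROLES = {"imf4", "imf5"}
#: roles screened for dorsal flattening (fourth carpometacarpal joint)
FLATTENING_ROLES = {"hamate4", "mc4"}

SUMMARY_COLUMNS = [
    "surface_area", "mid_sagittal_length", "mid_coronal_width",
    "roc", "mean_abs_error", "three_point_roc",
    "radial_roc", "ulnar_roc", "radial_area_pct", "ulnar_area_pct",
    "divergence",
]


def measure_one(
    mesh: TriangleMesh,
    role: str,
    orientation: OrientationSpec | None = None,
    flattening_threshold: float = morphometry.FLATTENING_THRESHOLD_MM,
) -> dict:
    """Measure a single facet according to its anatomical role."""
    frame = geom_core.build_frame(mesh, orientation)
    row: dict = {"role": role, "name": mesh.name}
    rep = morphometry.measure_facet(
        mesh, frame,
        flattening=role in FLATTENING_ROLES,
        flattening_threshold=flattening_threshold,
    )
    row.update(
        surface_area=rep.surface_area,
        mid_sagittal_length=rep.mid_sagittal_length,
        mid_coronal_width=rep.mid_coronal_width,
        roc=rep.roc,
        mean_abs_error=rep.mean_abs_error,
        mean_error_pct=rep.mean_error_pct,
        curvature_sense=rep.curvature_sense,
        flattened_dorsal=rep.flattened_dorsal,
    )
    if role in THREE_POINT_ROLES:
        tp, _ = morphometry.three_point_roc_of_facet(mesh, frame)
        row["three_point_roc"] = tp
    if role in BICONDYLAR_ROLES:
        bic = morphometry.partition_bicondylar(mesh, frame)
        row.update(
            radial_roc=bic.radial_fit.radius,
            ulnar_roc=bic.ulnar_fit.radius,
            radial_area_pct=bic.radial_area_fraction,
            ulnar_area_pct=bic.ulnar_area_fraction,
            divergence=bic.divergence_angle,
            bicondylar_converged=bic.converged,
        )
    return row


def measure_cohort(
    manifest: pd.DataFrame,
    base_dir: Path | str = ".",
    orientation: OrientationSpec | None = None,
    units: str = "mm",
) -> pd.DataFrame:
    """Measure every facet listed in a manifest (specimen_id, path, role).

    A failing facet is recorded as a row with an ``error`` message and the
    run continues; the caller decides whether an all-failed table is fatal.
    """
    required = {"specimen_id", "path", "role"}
    if not required.issubset(manifest.columns):
        raise SchemaError(f"manifest needs columns {sorted(required)}")
    base = Path(base_dir)
    rows = []
    for rec in manifest.to_dict("records"):
        row = {"specimen_id": rec["specimen_id"], "role": rec["role"],
               "path": str(rec["path"])}
        try:
            mesh = read_mesh(base / rec["path"], units=units)
            row.update(measure_one(mesh, rec["role"], orientation))
            row.pop("name", None)
        except Exception as exc:  # row-level failure, keep going
            log.warning("facet %s failed: %s", rec["path"], exc)
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def format_mean_range(values) -> str:
    """``mean (min-max)`` to two decimals, the published table style."""
    arr = np.asarray([v for v in values if v is not None and np.isfinite(v)],
                     dtype=float)
    if arr.size == 0:
        return ""
    return f"{arr.mean():.2f} ({arr.min():.2f}–{arr.max():.2f})"


def summarize(table: pd.DataFrame) -> dict:
    """Per-role column summaries: full-precision stats + formatted string."""
    out: dict = {}
    for role, group in table.groupby("role"):
        cols = {}
        for col in SUMMARY_COLUMNS:
            if col not in group.columns:
                continue
            vals = pd.to_numeric(group[col], errors="coerce").dropna()
            if vals.empty:
                continue
            cols[col] = {
                "mean": float(vals.mean()),
                "min": float(vals.min()),
                "max": float(vals.max()),
                "n": int(vals.size),
                "formatted": format_mean_range(vals),
            }
        if "flattened_dorsal" in group.columns:
            flags = group["flattened_dorsal"].dropna()
            if not flags.empty:
                cols["flattened_dorsal"] = {
                    "n_flagged": int(flags.astype(bool).sum()),
                    "n": int(flags.size),
                }
        out[str(role)] = cols
    return out


def measurement_payload(table: pd.DataFrame) -> dict:
    """Machine-readable measurement bundle (schema-versioned)."""
    clean = table.replace({np.nan: None})
    return {
        "schema": MEASURE_SCHEMA,
        "rows": clean.to_dict("records"),
        "summary": summarize(table),
    }


def write_measurements(table: pd.DataFrame, out_dir: Path | str) -> tuple[Path, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / "measurements.csv"
    json_path = out / "measurements.json"
    table.to_csv(csv_path, index=False)
    json_path.write_text(json.dumps(measurement_payload(table), indent=2,
                                    sort_keys=True))
    return csv_path, json_path


def render_report(payload: dict) -> str:
    """Human-readable per-role summary table from a measurement payload."""
    if payload.get("schema") != MEASURE_SCHEMA:
        raise SchemaError(
            f"expected schema {MEASURE_SCHEMA!r}, got {payload.get('schema')!r}"
        )
    if "summary" not in payload or "rows" not in payload:
        raise SchemaError("measurement payload lacks 'summary'/'rows'")
    lines = []
    n_rows = len(payload["rows"])
    lines.append(f"Facet morphometry summary ({n_rows} facets)")
    lines.append("=" * 60)
    for role in sorted(payload["summary"]):
        cols = payload["summary"][role]
        lines.append(f"\n[{role}]  (n per measure varies)")
        for col in SUMMARY_COLUMNS:
            if col in cols:
                lines.append(f"  {col:<22} {cols[col]['formatted']}"
                             f"   n={cols[col]['n']}")
        if "flattened_dorsal" in cols:
            f = cols["flattened_dorsal"]
            lines.append(f"  {'flattened_dorsal':<22} {f['n_flagged']} of {f['n']}")
    return "\n".join(lines) + "\n"


def load_measurements(path: Path | str) -> dict:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise SchemaError(f"cannot read measurement JSON {path}: {exc}") from exc
    if not isinstance(payload, dict):
        raise SchemaError(f"{path} is not a measurement payload")
    return payload
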