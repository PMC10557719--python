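"""Readers/writers for the formats the pipeline touches, plus configuration.

CSV is the interchange format for traces, points and series; TIFF for
rasters; JSON for structured results; YAML for configuration.  All readers
validate and reject malformed input rather than silently coercing it.

CSV schemas (headers case-insensitive):

* FRAP trace:      ``time_s, roi_mean, ref_mean``
  (scalar ``background`` and ``n_prebleach`` via sidecar/flags)
* follicle series: ``movie_id, t_min, hf_mean, ife_mean_1, ife_mean_2,
  depth_um`` (``ife_mean_2`` may be empty for single-ROI timepoints)
* division points: ``cell_id, phase, role, x_px, y_px, frame`` with role
  in {A, B1, B2, V1, V2}; in sagittal images +y is basal (downward).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ArgumentError, FormatError, SchemaError
from .types import DivisionGeometry, FollicleSeries, FrapTrace

__all__ = [
    "RunConfig",
    "read_tiff_stack",
    "write_tiff_stack",
    "read_trace_csv",
    "read_points_csv",
    "read_series_csv",
    "write_trace_csv",
    "write_points_csv",
    "write_series_csv",
    "write_results",
]


_CONFIG_DEFAULTS = {
    "seed": 0,
    "costes": {"n_rand": 100, "block": 5, "overlap_dialect": "and"},
    "frap": {"r2_gate": 0.9, "interval_s": 10.0, "n_prebleach": 3},
    "morpho": {"angle_dialect": "difference", "stats_adjustment": "bonferroni"},
    "io": {"tiff_axes": "TCYX", "pixel_size_um": 0.09},
}


@dataclasses.dataclass
class RunConfig:
    """Validated run configuration with experiment-derived defaults.

    Defaults: FRAP acceptance gate r² > 0.9 with 10-s frame interval and 3
    pre-bleach frames; 100 Costes randomizations with 5-px blocks; 0.09
    um/px pixel size.
    """

    seed: int = 0
    costes: dict = None  # type: ignore[assignment]
    frap: dict = None  # type: ignore[assignment]
    morpho: dict = None  # type: ignore[assignment]
    io: dict = None  # type: ignore[assignment]

    def __post_init__(self):
        for section in ("costes", "frap", "morpho", "io"):
            merged = dict(_CONFIG_DEFAULTS[section])
            given = getattr(self, section) or {}
            unknown = set(given) - set(merged)
            if unknown:
                raise ArgumentError(
                    f"unknown config keys in [{section}]: {sorted(unknown)}"
                )
            merged.update(given)
            setattr(self, section, merged)
        if not 0 < self.frap["r2_gate"] <= 1:
            raise ArgumentError("frap.r2_gate must lie in (0, 1]")
        if self.costes["n_rand"] < 1 or self.costes["block"] < 1:
            raise ArgumentError("costes.n_rand and costes.block must be >= 1")
        if self.io["pixel_size_um"] <= 0:
            raise ArgumentError("io.pixel_size_um must be positive")
        if self.costes["overlap_dialect"] not in ("and", "product"):
            raise ArgumentError("costes.overlap_dialect must be 'and' or 'product'")
        if self.morpho["angle_dialect"] not in ("difference", "ratio"):
            raise ArgumentError("morpho.angle_dialect must be 'difference' or 'ratio'")

    @classmethod
    def from_yaml(cls, path):
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ArgumentError(f"unknown top-level config keys: {sorted(unknown)}")
        return cls(**raw)

    def snapshot(self) -> dict:
        return dataclasses.asdict(self)


def read_tiff_stack(path, axes="CYX"):
    """Read a TIFF into a (T, C, Y, X) float array per the declared axes.

    ``axes`` is one of ``YX``, ``CYX``, ``TYX``, ``TCYX`` describing the
    page layout; missing leading axes are inserted with length 1.
    """
    axes = axes.upper()
    if axes not in ("YX", "CYX", "TYX", "TCYX"):
        raise ArgumentError(f"unsupported axes flag {axes!r}")
    try:
        arr = tifffile.imread(str(path))
    except Exception as exc:  # tifffile raises several types for bad files
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    arr = np.asarray(arr, dtype=float)
    expected_ndim = len(axes)
    if arr.ndim != expected_ndim:
        raise FormatError(
            f"{path}: declared axes {axes} imply {expected_ndim} dims "
            f"but file has {arr.ndim}"
        )
    while arr.ndim < 4:
        arr = arr[None]
    return arr  # (T, C, Y, X)


def write_tiff_stack(path, arr, axes="TCYX"):
    """Write a (T, C, Y, X) array as a multi-page TIFF with an axes tag."""
    arr = np.asarray(arr, dtype=np.float32)
    if arr.ndim != 4:
        raise ArgumentError("expected a (T, C, Y, X) array")
    tifffile.imwrite(str(path), arr, metadata={"axes": axes})


def _load_csv(path, required, optional=()):
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise SchemaError(f"cannot parse CSV {path}: {exc}") from exc
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    return df


def _numeric(df, col, path, allow_nan=False):
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & ~df[col].isna() if allow_nan else vals.isna()
    if bad.any():
        row = int(bad.idxmax())
        raise SchemaError(
            f"{path}: non-numeric value in column '{col}' at row {row}"
        )
    return vals.to_numpy()


def read_trace_csv(path, background=0.0, n_prebleach=3, trace_id=None) -> FrapTrace:
    """Read one FRAP trace (columns ``time_s, roi_mean, ref_mean``)."""
    df = _load_csv(path, ["time_s", "roi_mean", "ref_mean"])
    t = _numeric(df, "time_s", path)
    roi = _numeric(df, "roi_mean", path)
    ref = _numeric(df, "ref_mean", path)
    return FrapTrace(
        t=t, roi=roi, ref=ref, background=float(background),
        n_prebleach=int(n_prebleach),
        trace_id=trace_id or Path(path).stem,
    )


def write_trace_csv(path, trace: FrapTrace):
    pd.DataFrame(
        {"time_s": trace.t, "roi_mean": trace.roi, "ref_mean": trace.ref}
    ).to_csv(path, index=False)


def read_series_csv(path):
    """Read follicle series; returns a list of :class:`FollicleSeries` per movie."""
    cols = ["movie_id", "t_min", "hf_mean", "ife_mean_1", "ife_mean_2", "depth_um"]
    df = _load_csv(path, cols[:4] + [cols[5]])
    has_second = "ife_mean_2" in df.columns
    t = _numeric(df, "t_min", path)
    hf = _numeric(df, "hf_mean", path)
    ife1 = _numeric(df, "ife_mean_1", path)
    ife2 = _numeric(df, "ife_mean_2", path, allow_nan=True) if has_second else None
    depth = _numeric(df, "depth_um", path)
    out = []
    for movie in df["movie_id"].astype(str).unique():
        sel = (df["movie_id"].astype(str) == movie).to_numpy()
        ife = []
        for i in np.nonzero(sel)[0]:
            vals = [float(ife1[i])]
            if ife2 is not None and not np.isnan(ife2[i]):
                vals.append(float(ife2[i]))
            ife.append(vals)
        out.append(FollicleSeries(
            t=t[sel], hf_intensity=hf[sel], ife_intensities=ife,
            depth=depth[sel], movie_id=movie,
        ))
    return out


def write_series_csv(path, series_list):
    rows = []
    for s in series_list:
        for i in range(len(s.t)):
            vals = s.ife_intensities[i]
            rows.append({
                "movie_id": s.movie_id, "t_min": s.t[i],
                "hf_mean": s.hf_intensity[i],
                "ife_mean_1": vals[0],
                "ife_mean_2": vals[1] if len(vals) > 1 else np.nan,
                "depth_um": s.depth[i],
            })
    pd.DataFrame(rows).to_csv(path, index=False)


_ROLES = ("A", "B1", "B2", "V1", "V2")


def read_points_csv(path):
    """Read division-geometry points; returns {(cell_id, phase): DivisionGeometry}."""
    df = _load_csv(path, ["cell_id", "phase", "role", "x_px", "y_px"])
    x = _numeric(df, "x_px", path)
    y = _numeric(df, "y_px", path)
    out = {}
    grouped = df.assign(_x=x, _y=y).groupby(
        [df["cell_id"].astype(str), df["phase"].astype(str)], sort=False
    )
    for (cell, phase), sub in grouped:
        pts = {}
        for _, row in sub.iterrows():
            role = str(row["role"]).strip().upper()
            if role not in _ROLES:
                raise SchemaError(f"{path}: unknown role {role!r} for cell {cell}")
            pts[role] = np.array([row["_x"], row["_y"]], dtype=float)
        missing = [r for r in _ROLES if r not in pts]
        if missing:
            raise SchemaError(
                f"{path}: cell {cell} phase {phase} missing role(s) {missing}"
            )
        out[(cell, phase)] = DivisionGeometry(
            cell_id=cell, phase=phase,
            A=pts["A"], B1=pts["B1"], B2=pts["B2"], V1=pts["V1"], V2=pts["V2"],
        )
    return out


def write_points_csv(path, geoms):
    """Write DivisionGeometry objects (iterable) to the points CSV schema."""
    rows = []
    for g in geoms:
        for role in _ROLES:
            p = getattr(g, role)
            rows.append({
                "cell_id": g.cell_id, "phase": g.phase, "role": role,
                "x_px": p[0], "y_px": p[1], "frame": 0,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return super().default(o)


def write_results(results, path, fmt="json", config=None, seed=None):
    """Write structured results with config snapshot, version and seed.

    ``fmt="json"`` writes one JSON document; ``fmt="csv"`` expects
    ``results`` to be a list of flat dicts (one row each).
    """
    from . import __version__

    path = Path(path)
    if fmt == "json":
        doc = {
            "bmquant_version": __version__,
            "seed": seed,
            "config": config.snapshot() if config is not None else None,
            "results": results,
        }
        path.write_text(json.dumps(doc, indent=2, cls=_NumpyEncoder) + "\n")
    elif fmt == "csv":
        pd.DataFrame(results).to_csv(path, index=False)
    else:
        raise ArgumentError(f"unknown results format {fmt!r}")
    return path
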