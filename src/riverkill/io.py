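"""Readers and writers for the package's file formats.

All tabular inputs are plain CSV with the long-format schemas below;
photo annotations are one JSON file per photo; river geometry comes from
a YAML config block.  Readers validate row by row and collect errors
with line numbers instead of silently dropping records.

CSV schemas
-----------
flux sessions       start_time, session_minutes, count
shore transects     site_id, river_km, bank, length_m, taxon, count
density samples     site_id, period, method, sampled_area_m2, taxon, count
vertebrate records  transect_id, river_km, habitat, taxon, count, lengths
                    (lengths as semicolon-separated cm values)
coefficients        taxon, a, b, source
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError
from .river_frame import RiverFrame
from .flux import FluxSession
from .shore import ShoreTransect, IDWSurface
from .population import DensitySample
from .photos import PhotoGrid
from .vertebrates import VertebrateRecord, LengthWeightCoeff


def ensure_dir(path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    return path


def _read_csv(path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")
    return df


def _raise_row_errors(path, errors: list[str]) -> None:
    if errors:
        raise SchemaError(
            f"{Path(path).name}: {len(errors)} invalid row(s):\n  "
            + "\n  ".join(errors)
        )


def read_flux_sessions(path) -> list[FluxSession]:
    df = _read_csv(path, ["session_minutes", "count"])
    sessions, errors = [], []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            sessions.append(
                FluxSession(
                    count_x=int(row["count"]),
                    session_minutes=float(row["session_minutes"]),
                    start_time=(
                        str(row["start_time"])
                        if "start_time" in df.columns and pd.notna(row.get("start_time"))
                        else None
                    ),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"line {line}: {exc}")
    _raise_row_errors(path, errors)
    return sessions


def write_flux_sessions(path, sessions: Sequence[FluxSession]) -> None:
    pd.DataFrame(
        {
            "start_time": [s.start_time or "" for s in sessions],
            "session_minutes": [s.session_minutes for s in sessions],
            "count": [s.count_x for s in sessions],
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_shore_transects(path) -> list[ShoreTransect]:
    df = _read_csv(path, ["site_id", "river_km", "bank", "taxon", "count"])
    if "length_m" not in df.columns:
        df["length_m"] = 10.0
    transects, errors = [], []
    keys = ["site_id", "river_km", "bank", "length_m"]
    for key, grp in df.groupby(keys, sort=False):
        site_id, river_km, bank, length_m = key
        counts: dict[str, int] = {}
        ok = True
        for i, row in grp.iterrows():
            line = i + 2
            try:
                c = int(row["count"])
                if c < 0:
                    raise ValueError(f"negative count {c}")
                counts[str(row["taxon"])] = counts.get(str(row["taxon"]), 0) + c
            except (ValueError, TypeError) as exc:
                errors.append(f"line {line}: {exc}")
                ok = False
        if not ok:
            continue
        try:
            transects.append(
                ShoreTransect(
                    site_id=str(site_id),
                    river_km=float(river_km),
                    bank=str(bank),
                    counts=counts,
                    length_m=float(length_m),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"site {site_id}: {exc}")
    _raise_row_errors(path, errors)
    return transects


def write_shore_transects(path, transects: Sequence[ShoreTransect]) -> None:
    rows = []
    for t in transects:
        for taxon, c in sorted(t.counts.items()):
            rows.append(
                {
                    "site_id": t.site_id,
                    "river_km": t.river_km,
                    "bank": t.bank,
                    "length_m": t.length_m,
                    "taxon": taxon,
                    "count": c,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_density_samples(path) -> list[DensitySample]:
    df = _read_csv(
        path, ["site_id", "period", "sampled_area_m2", "taxon", "count"]
    )
    if "method" not in df.columns:
        df["method"] = "net"
    samples, errors = [], []
    keys = ["site_id", "period", "method", "sampled_area_m2"]
    for key, grp in df.groupby(keys, sort=False):
        site_id, period, method, area = key
        counts: dict[str, int] = {}
        ok = True
        for i, row in grp.iterrows():
            line = i + 2
            try:
                c = int(row["count"])
                if c < 0:
                    raise ValueError(f"negative count {c}")
                counts[str(row["taxon"])] = counts.get(str(row["taxon"]), 0) + c
            except (ValueError, TypeError) as exc:
                errors.append(f"line {line}: {exc}")
                ok = False
        if not ok:
            continue
        try:
            samples.append(
                DensitySample(
                    site_id=str(site_id),
                    period=str(period),
                    sampled_area=float(area),
                    counts=counts,
                    method=str(method),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"sample {site_id}/{period}: {exc}")
    _raise_row_errors(path, errors)
    return samples


def write_density_samples(path, samples: Sequence[DensitySample]) -> None:
    rows = []
    for s in samples:
        for taxon, c in sorted(s.counts.items()):
            rows.append(
                {
                    "site_id": s.site_id,
                    "period": s.period,
                    "method": s.method,
                    "sampled_area_m2": s.sampled_area,
                    "taxon": taxon,
                    "count": c,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_vertebrate_records(path) -> list[VertebrateRecord]:
    df = _read_csv(
        path, ["transect_id", "river_km", "habitat", "taxon", "count"]
    )
    records, errors = [], []
    for i, row in df.iterrows():
        line = i + 2
        try:
            lengths: tuple[float, ...] = ()
            raw = row.get("lengths") if "lengths" in df.columns else None
            if pd.notna(raw) and str(raw).strip():
                lengths = tuple(
                    float(x) for x in str(raw).split(";") if x.strip()
                )
            records.append(
                VertebrateRecord(
                    transect_id=str(row["transect_id"]),
                    river_km=float(row["river_km"]),
                    habitat=str(row["habitat"]),
                    taxon=str(row["taxon"]),
                    count=int(row["count"]),
                    lengths=lengths,
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"line {line}: {exc}")
    _raise_row_errors(path, errors)
    return records


def write_vertebrate_records(path, records: Sequence[VertebrateRecord]) -> None:
    pd.DataFrame(
        {
            "transect_id": [r.transect_id for r in records],
            "river_km": [r.river_km for r in records],
            "habitat": [r.habitat for r in records],
            "taxon": [r.taxon for r in records],
            "count": [r.count for r in records],
            "lengths": [";".join(f"{l:g}" for l in r.lengths) for r in records],
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_coeffs(path) -> dict[str, LengthWeightCoeff]:
    df = _read_csv(path, ["taxon", "a", "b"])
    coeffs, errors = {}, []
    for i, row in df.iterrows():
        line = i + 2
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                coeffs[str(row["taxon"])] = LengthWeightCoeff(
                    taxon=str(row["taxon"]),
                    a=float(row["a"]),
                    b=float(row["b"]),
                    source=str(row.get("source", "")) if "source" in df.columns else "",
                )
        except (ValueError, TypeError) as exc:
            errors.append(f"line {line}: {exc}")
    _raise_row_errors(path, errors)
    return coeffs


def write_coeffs(path, coeffs: dict[str, LengthWeightCoeff]) -> None:
    pd.DataFrame(
        {
            "taxon": [c.taxon for c in coeffs.values()],
            "a": [c.a for c in coeffs.values()],
            "b": [c.b for c in coeffs.values()],
            "source": [c.source for c in coeffs.values()],
        }
    ).to_csv(path, index=False, float_format="%.17g")


def demo_coefficients() -> dict[str, LengthWeightCoeff]:
    """Illustrative length-weight coefficients for the demo species.

    Synthetic round-number values for worked examples and simulations;
    real analyses should supply a coefficients CSV from an authoritative
    converter.
    """
    note = "synthetic illustrative value"
    return {
        "ruffe": LengthWeightCoeff("ruffe", a=0.012, b=3.05, source=note),
        "bream": LengthWeightCoeff("bream", a=0.009, b=3.10, source=note),
        "perch": LengthWeightCoeff("perch", a=0.011, b=3.00, source=note),
    }


def read_photo_annotation(path) -> PhotoGrid:
    with open(path) as fh:
        data = json.load(fh)
    cells = {
        (int(c["row"]), int(c["col"])): list(c["labels"])
        for c in data.get("cells", [])
    }
    return PhotoGrid(
        photo_id=str(data["photo_id"]),
        n_rows=int(data["n_rows"]),
        n_cols=int(data["n_cols"]),
        cells=cells,
        excluded=frozenset(
            (int(r), int(c)) for r, c in data.get("excluded", [])
        ),
    )


def write_photo_annotation(path, photo: PhotoGrid) -> None:
    data = {
        "photo_id": photo.photo_id,
        "n_rows": photo.n_rows,
        "n_cols": photo.n_cols,
        "cells": [
            {"row": r, "col": c, "labels": labels}
            for (r, c), labels in sorted(photo.cells.items())
        ],
        "excluded": [list(cell) for cell in sorted(photo.excluded)],
    }
    write_json(path, data)


def read_photo_dir(path) -> list[PhotoGrid]:
    files = sorted(Path(path).glob("*.json"))
    if not files:
        raise SchemaError(f"no annotation JSON files in {path}")
    return [read_photo_annotation(f) for f in files]


def read_river_config(path) -> RiverFrame:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if "river" in cfg:
        cfg = cfg["river"]
    return RiverFrame.from_dict(cfg)


def write_river_config(path, frame: RiverFrame) -> None:
    cfg = {
        "river": {
            "km_start": frame.km_start,
            "km_end": frame.km_end,
            "branches": [
                {"name": n, "length_km": l} for n, l in frame.extra_branches
            ],
            "strip_width_m": frame.strip_width_w,
            "n_banks": frame.n_banks,
        }
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def _round_sig(x: float, sig: int = 6) -> float:
    if x == 0 or not np.isfinite(x):
        return x
    return float(f"{x:.{sig}g}")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return _round_sig(float(obj))
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _round_floats(obj):
    """Round all floats to 6 significant digits for stable serialization."""
    if isinstance(obj, float):
        return _round_sig(obj)
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj


def write_json(path, data) -> None:
    with open(path, "w") as fh:
        json.dump(_round_floats(data), fh, indent=2, sort_keys=True,
                  default=_json_default)
        fh.write("\n")


def write_idw_geojson(path, surface: IDWSurface) -> None:
    """IDW lattice as a GeoJSON point collection (log10 + linear values)."""
    features = []
    for iy, y in enumerate(surface.grid_y):
        for ix, x in enumerate(surface.grid_x):
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
                    "properties": {
                        "log10_value": float(surface.log10_values[iy, ix]),
                        "value": float(surface.values[iy, ix]),
                    },
                }
            )
    write_json(path, {"type": "FeatureCollection", "features": features})


def write_esri_ascii(path, surface: IDWSurface) -> None:
    """IDW log10 surface as an ESRI ASCII raster (requires a uniform grid)."""
    gx, gy = surface.grid_x, surface.grid_y
    if gx.size > 1:
        dx = np.diff(gx)
        if not np.allclose(dx, dx[0]):
            raise ValueError("ESRI ASCII requires a uniform grid spacing")
        cell = float(dx[0])
    else:
        cell = 1.0
    if gy.size > 1:
        dy = np.diff(gy)
        if not (np.allclose(dy, dy[0]) and np.isclose(abs(dy[0]), cell)):
            raise ValueError("ESRI ASCII requires square, uniform cells")
    lines = [
        f"ncols {gx.size}",
        f"nrows {gy.size}",
        f"xllcorner {gx[0] - cell / 2:g}",
        f"yllcorner {gy[0] - cell / 2:g}",
        f"cellsize {cell:g}",
        "NODATA_value -9999",
    ]
    # ESRI ASCII rows run north to south: top row first
    for row in surface.log10_values[::-1]:
        lines.append(" ".join(f"{v:.6g}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")
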