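"""Readers and writers for the formats the pipeline touches.

Check-ins arrive as CSV with configurable column names; stay areas are
written as GeoJSON (RFC 7946) point features; the interaction graph and
the embedding table round-trip through TSV.  All writers/readers satisfy
read-after-write identity to 1e-9.
"""

from __future__ import annotations

import json
import math
import warnings
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .quadrants import validate_reading
from .types import (
    NOISE,
    CheckIn,
    EmbeddingTable,
    EmotionGraph,
    EmotionPoint,
    GraphVertex,
    Quadrant,
    StayArea,
)

#: Default column map mirroring the microblog table layout (time, y=lat,
#: x=lon, user id), with pre-extracted emotion readings instead of URLs.
DEFAULT_DIALECT = {"time": "post_time", "lat": "y", "lon": "x", "user": "id"}

_WEIBO_FORMAT = "%a %b %d %H:%M:%S %z %Y"


def parse_timestamp(raw: str) -> float:
    """Parse an ISO-8601 or microblog-dialect timestamp to UTC epoch seconds.

    The microblog dialect looks like ``Fri Jan 01 05:09:23 +0800 2021``
    (a spurious space after the sign is tolerated).  Naive ISO timestamps
    are taken as UTC.
    """
    s = str(raw).strip()
    # collapse "+ 0800" -> "+0800"
    for sign in ("+ ", "- "):
        if sign in s:
            s = s.replace(sign, sign[0])
    try:
        dt = datetime.strptime(s, _WEIBO_FORMAT)
        return dt.timestamp()
    except ValueError:
        pass
    ts = pd.Timestamp(s)
    if ts.tzinfo is None:
        ts = ts.tz_localize("UTC")
    return ts.timestamp()


def _reading_columns(columns: Sequence[str]) -> List[Tuple[str, str]]:
    """Pair up valence*/intensity* columns by shared suffix."""
    pairs = []
    for col in columns:
        if col.startswith("valence"):
            suffix = col[len("valence"):]
            partner = "intensity" + suffix
            if partner in columns:
                pairs.append((col, partner))
    return pairs


def read_checkins(
    path: "str | Path",
    dialect: Optional[Dict[str, str]] = None,
) -> List[CheckIn]:
    """Read a check-in CSV into CheckIn records, preserving file order.

    ``dialect`` maps the logical names time/lat/lon/user to the file's
    column names; emotion readings are taken from every
    ``valence<suffix>``/``intensity<suffix>`` column pair (blank cells
    mean "no further image").  Unparseable rows raise a ValueError naming
    the data row number (1-based, excluding the header).
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    df = pd.read_csv(path, dtype={dialect["user"]: str})
    if df.empty:
        warnings.warn(f"{path}: no check-in rows")
        return []
    for key in ("time", "lat", "lon", "user"):
        if dialect[key] not in df.columns:
            raise ValueError(f"{path}: missing column {dialect[key]!r} (for {key})")
    pairs = _reading_columns(list(df.columns))
    if not pairs:
        raise ValueError(f"{path}: no valence/intensity column pairs found")

    out: List[CheckIn] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rec = dict(zip(df.columns, row))
        try:
            t = parse_timestamp(rec[dialect["time"]])
            lat = float(rec[dialect["lat"]])
            lon = float(rec[dialect["lon"]])
            readings = []
            for vcol, icol in pairs:
                v, a = rec[vcol], rec[icol]
                if pd.isna(v) and pd.isna(a):
                    continue
                readings.append(validate_reading(float(v), float(a)))
            out.append(
                CheckIn(
                    user_id=str(rec[dialect["user"]]),
                    t=t,
                    lat=lat,
                    lon=lon,
                    readings=tuple(readings),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from exc
    return out


def write_checkins(checkins: Sequence[CheckIn], path: "str | Path") -> None:
    """Write check-ins in the default CSV dialect (ISO-8601 timestamps)."""
    max_readings = max(len(c.readings) for c in checkins)
    cols = ["post_time", "y", "x", "id"]
    for k in range(1, max_readings + 1):
        cols += [f"valence_{k}", f"intensity_{k}"]
    rows = []
    for c in checkins:
        iso = datetime.fromtimestamp(c.t, tz=timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")
        row: List[object] = [iso, repr(c.lat), repr(c.lon), c.user_id]
        for k in range(max_readings):
            if k < len(c.readings):
                row += [repr(c.readings[k].x), repr(c.readings[k].y)]
            else:
                row += ["", ""]
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# stay areas <-> GeoJSON


def write_stay_areas(
    areas: Sequence[StayArea],
    assignments: Sequence[int],
    path: "str | Path",
) -> None:
    """Write stay-area centers as a GeoJSON FeatureCollection.

    ``assignments`` (check-in index -> area id or NOISE) is recorded in
    the collection's foreign ``assignments`` member so a single file can
    reconstruct the clustering.
    """
    if not areas:
        raise ValueError("no stay areas to write")
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [a.center[0], a.center[1]]},
            "properties": {"area_id": a.area_id, "member_count": a.member_count},
        }
        for a in areas
    ]
    doc = {
        "type": "FeatureCollection",
        "features": features,
        "assignments": [int(x) for x in assignments],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_stay_areas(path: "str | Path") -> Tuple[List[StayArea], List[int]]:
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    areas = []
    for f in doc["features"]:
        lon, lat = f["geometry"]["coordinates"]
        p = f["properties"]
        areas.append(StayArea(area_id=int(p["area_id"]), center=(lon, lat),
                              member_count=int(p["member_count"])))
    return areas, [int(x) for x in doc.get("assignments", [])]


# ---------------------------------------------------------------------------
# interaction graph <-> TSV edge list

_EDGE_HEADER = "src_area\tsrc_quadrant\tdst_area\tdst_quadrant\tweight"


def write_edge_list(graph: EmotionGraph, path: "str | Path") -> None:
    lines = [_EDGE_HEADER]
    for (src, dst), w in sorted(
        graph.edges.items(),
        key=lambda kv: (kv[0][0].area_id, kv[0][0].quadrant.value,
                        kv[0][1].area_id, kv[0][1].quadrant.value),
    ):
        lines.append(f"{src.area_id}\t{src.quadrant.name}\t{dst.area_id}\t{dst.quadrant.name}\t{w!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_edge_list(path: "str | Path") -> EmotionGraph:
    graph = EmotionGraph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if lineno == 1 or not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}: line {lineno}: expected 5 fields, got {len(parts)}")
            try:
                src = GraphVertex(int(parts[0]), Quadrant[parts[1]])
                dst = GraphVertex(int(parts[2]), Quadrant[parts[3]])
                w = float(parts[4])
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            if w <= 0:
                raise ValueError(f"{path}: line {lineno}: non-positive weight {w}")
            graph.add_edge(src, dst, w)
    return graph


# ---------------------------------------------------------------------------
# embedding table <-> TSV


def write_embeddings(table: EmbeddingTable, path: "str | Path") -> None:
    lines = ["area\tquadrant\t" + "\t".join(f"v{i+1}" for i in range(table.dim))]
    for v in sorted(table.vectors, key=lambda v: (v.area_id, v.quadrant.value)):
        vec = "\t".join(repr(float(x)) for x in table.vectors[v])
        lines.append(f"{v.area_id}\t{v.quadrant.name}\t{vec}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_embeddings(path: "str | Path") -> EmbeddingTable:
    vectors: Dict[GraphVertex, np.ndarray] = {}
    dim = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if lineno == 1 or not line:
                continue
            parts = line.split("\t")
            try:
                v = GraphVertex(int(parts[0]), Quadrant[parts[1]])
                vec = np.array([float(x) for x in parts[2:]])
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            if dim is None:
                dim = len(vec)
            elif len(vec) != dim:
                raise ValueError(f"{path}: line {lineno}: inconsistent dimension")
            vectors[v] = vec
    if dim is None:
        raise ValueError(f"{path}: empty embedding table")
    return EmbeddingTable(dim=dim, vectors=vectors)


# ---------------------------------------------------------------------------
# misc small tables


def write_assignments(assignments: Sequence[int], path: "str | Path") -> None:
    lines = ["checkin_index\tarea_id"]
    lines += [f"{i}\t{int(a)}" for i, a in enumerate(assignments)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_assignments(path: "str | Path") -> List[int]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno == 1 or not line.strip():
                continue
            idx, area = line.split("\t")
            out.append(int(area))
    return out


def write_labels(labels: Sequence[Tuple[float, float, Quadrant]], path: "str | Path") -> None:
    """Write per-check-in aggregated emotion and quadrant as TSV."""
    lines = ["checkin_index\tx\ty\tquadrant"]
    lines += [f"{i}\t{x!r}\t{y!r}\t{q.name}" for i, (x, y, q) in enumerate(labels)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_labels(path: "str | Path") -> List[Tuple[float, float, Quadrant]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno == 1 or not line.strip():
                continue
            _, x, y, q = line.rstrip("\n").split("\t")
            out.append((float(x), float(y), Quadrant[q]))
    return out


def load_config(path: "str | Path") -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
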