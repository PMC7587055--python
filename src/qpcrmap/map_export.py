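"""GeoJSON and self-contained HTML map export of classified detections.

Each record becomes one RFC 7946 Point feature placed at its *display*
coordinate (cluster centroid + spiderfy offset for multi-member clusters);
the true sampling coordinates are kept in the feature properties together
with the information-bubble content: species, taxonID (+ NCBI Taxonomy
link), Ct, intensity label and color, platform, date, and collector when
available. Every multi-member cluster additionally contributes one summary
feature at its centroid.

Output is deterministic byte-for-byte for identical inputs: keys are sorted
and coordinates rounded to a fixed precision.
"""

from __future__ import annotations

import html
import json
from pathlib import Path
from typing import Sequence

from .core import NO_CROSSING
from .ct_engine import NONE_DETECTED, DetectionClass, IntensityScheme
from .geospatial import GeoCluster
from .metadata_schema import taxonomy_link
from .platform_io import MergedRecord

_COORD_DECIMALS = 8


def _round(x: float) -> float:
    return round(float(x), _COORD_DECIMALS)


def to_geojson(
    records: Sequence[MergedRecord],
    classes: Sequence[DetectionClass],
    clusters: Sequence[GeoCluster],
    scheme: IntensityScheme,
) -> dict:
    """Build a GeoJSON FeatureCollection of detections plus cluster summaries.

    ``records`` and ``classes`` must be parallel and ``clusters`` must
    partition the record indices. Feature count is
    ``len(records) + #multi-member clusters``.
    """
    if len(records) != len(classes):
        raise ValueError(
            f"records ({len(records)}) and classes ({len(classes)}) differ in length"
        )
    covered = sorted(i for c in clusters for i in c.members)
    if covered != list(range(len(records))):
        raise ValueError("clusters do not partition the record indices")

    display: dict[int, tuple[float, float]] = {}
    for cluster in clusters:
        multi = len(cluster.members) > 1
        for k, idx in enumerate(cluster.members):
            if multi:
                dlat, dlon = cluster.spider_offsets[k]
                display[idx] = (
                    cluster.centroid[0] + dlat,
                    cluster.centroid[1] + dlon,
                )
            else:
                m = records[idx].metadata
                display[idx] = (m.decimalLatitude, m.decimalLongitude)

    features = []
    for idx, (rec, cls) in enumerate(zip(records, classes)):
        m = rec.metadata
        lat, lon = display[idx]
        props = {
            "feature_type": "detection",
            "run_location": m.run_location,
            "species": m.species,
            "taxonID": str(m.taxonID),
            "taxonomy_url": taxonomy_link(m.taxonID),
            "ct": "none" if cls.ct is NO_CROSSING else float(cls.ct),
            "intensity_label": cls.label,
            "color": scheme.color_of(cls.label),
            "run_platform": m.run_platform,
            "eventDate": m.eventDate.isoformat(),
            "decimalLatitude": _round(m.decimalLatitude),
            "decimalLongitude": _round(m.decimalLongitude),
        }
        for optional in ("recordedBy", "vernacularName"):
            if optional in m.extras:
                props[optional] = m.extras[optional]
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": [_round(lon), _round(lat)],
                },
                "properties": props,
            }
        )

    for cluster in clusters:
        if len(cluster.members) < 2:
            continue
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": [
                        _round(cluster.centroid[1]),
                        _round(cluster.centroid[0]),
                    ],
                },
                "properties": {
                    "feature_type": "cluster",
                    "n_members": len(cluster.members),
                    "member_run_locations": [
                        records[i].metadata.run_location for i in cluster.members
                    ],
                },
            }
        )

    return {"type": "FeatureCollection", "features": features}


def dumps_geojson(document: dict) -> str:
    """Canonical serialization: sorted keys, compact separators, newline-terminated."""
    return json.dumps(document, sort_keys=True, separators=(",", ":")) + "\n"


def write_geojson(document: dict, path: str | Path) -> None:
    Path(path).write_text(dumps_geojson(document))


def legend_entries(scheme: IntensityScheme) -> list[tuple[str, str]]:
    """(label, color) pairs: intensity levels strongest-first, then none detected."""
    entries = [(lab, scheme.color_of(lab)) for lab in scheme.labels]
    entries.append((NONE_DETECTED, scheme.color_of(NONE_DETECTED)))
    return entries


def to_html_map(
    document: dict, scheme: IntensityScheme, path: str | Path | None = None
) -> str:
    """Render a self-contained HTML map (inline SVG, no external assets).

    Points are drawn in an equirectangular projection of the feature bounding
    box; the legend lists the intensity levels strongest-first plus
    "none detected". When ``path`` is given the page is also written there.
    """
    features = [
        f
        for f in document.get("features", [])
        if f["properties"].get("feature_type") == "detection"
    ]
    width, height, pad = 860, 560, 30

    if features:
        lons = [f["geometry"]["coordinates"][0] for f in features]
        lats = [f["geometry"]["coordinates"][1] for f in features]
        min_lon, max_lon = min(lons), max(lons)
        min_lat, max_lat = min(lats), max(lats)
        span_lon = max(max_lon - min_lon, 0.02)
        span_lat = max(max_lat - min_lat, 0.02)

        def sx(lon: float) -> float:
            return pad + (lon - min_lon) / span_lon * (width - 2 * pad)

        def sy(lat: float) -> float:
            return height - pad - (lat - min_lat) / span_lat * (height - 2 * pad)

        circles = []
        for f in features:
            lon, lat = f["geometry"]["coordinates"]
            p = f["properties"]
            tip = f"{p['species']} | well {p['run_location']} | Ct {p['ct']}"
            circles.append(
                f'<circle cx="{sx(lon):.1f}" cy="{sy(lat):.1f}" r="6" '
                f'fill="{p["color"]}" stroke="#333" stroke-width="1">'
                f"<title>{html.escape(tip)}</title></circle>"
            )
        svg_body = "\n".join(circles)
    else:
        svg_body = (
            f'<text x="{width / 2}" y="{height / 2}" text-anchor="middle" '
            f'fill="#666">no detections to display</text>'
        )

    legend_items = "\n".join(
        f'<li><span class="swatch" style="background:{color}"></span>'
        f"{html.escape(label)}</li>"
        for label, color in legend_entries(scheme)
    )
    page = f"""<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>qPCR detection map</title>
<style>
body {{ font-family: sans-serif; margin: 1em; }}
.legend ul {{ list-style: none; padding: 0; }}
.legend li {{ margin: 0.15em 0; }}
.swatch {{ display: inline-block; width: 1em; height: 1em;
           border: 1px solid #333; margin-right: 0.5em; vertical-align: -0.15em; }}
svg {{ border: 1px solid #999; background: #f4f8fb; }}
</style>
</head>
<body>
<h1>qPCR detection map</h1>
<svg width="{width}" height="{height}" viewBox="0 0 {width} {height}">
{svg_body}
</svg>
<div class="legend">
<h2>qPCR intensity</h2>
<ul>
{legend_items}
</ul>
</div>
</body>
</html>
"""
    if path is not None:
        Path(path).write_text(page)
    return page
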