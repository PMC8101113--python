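"""Choropleth rendering of risk summaries on areal geometry.

Joins per-area :class:`~bymmap.summaries.RiskSummary` values onto a GeoJSON
polygon collection and renders either a static figure (matplotlib; SVG or
PNG) or a single self-contained interactive HTML file with layer toggles and
per-area hover tooltips (inline SVG + a few lines of JavaScript — no
external tiles or network resources, so the file works offline).

Values are classed into bins by explicit break points; the highest
exceedance bin maps to the darkest red of the sequential palette, so
hotspots read as deep red.
"""

from __future__ import annotations

import html
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import matplotlib
import numpy as np
from shapely.geometry import shape

from .summaries import RiskSummary

__all__ = [
    "MapLayerSpec",
    "join_geometry",
    "assign_bins",
    "render_static",
    "render_interactive",
    "DEFAULT_RR_BREAKS",
    "DEFAULT_EXCEEDANCE_BREAKS",
]

logger = logging.getLogger(__name__)

DEFAULT_RR_BREAKS: tuple[float, ...] = (0.5, 0.75, 1.0, 1.25, 1.5, 2.0, 3.0)
DEFAULT_EXCEEDANCE_BREAKS: tuple[float, ...] = (0.2, 0.5, 0.8, 0.95)


class MappingError(ValueError):
    pass


@dataclass
class MapLayerSpec:
    """One choropleth layer: which value, how binned, how coloured."""

    value_key: str = "rr_mean"
    palette: str = "YlOrRd"
    breaks: Sequence[float] | None = None
    legend_title: str | None = None
    html_title: str | None = None

    def __post_init__(self) -> None:
        if self.breaks is None:
            self.breaks = (
                DEFAULT_EXCEEDANCE_BREAKS
                if self.value_key.startswith("exceedance@")
                else DEFAULT_RR_BREAKS
            )
        self.breaks = tuple(float(b) for b in self.breaks)
        if any(b2 <= b1 for b1, b2 in zip(self.breaks, self.breaks[1:])):
            raise MappingError("breaks must be strictly increasing")
        if self.legend_title is None:
            self.legend_title = self.value_key

    @property
    def n_bins(self) -> int:
        return len(self.breaks) + 1

    def colors(self) -> list[str]:
        cmap = matplotlib.colormaps[self.palette]
        return [
            matplotlib.colors.to_hex(cmap(x))
            for x in np.linspace(0.05, 0.95, self.n_bins)
        ]

    def bin_labels(self) -> list[str]:
        b = self.breaks
        labels = [f"< {b[0]:g}"]
        labels += [f"{lo:g} - {hi:g}" for lo, hi in zip(b, b[1:])]
        labels.append(f"> {b[-1]:g}")
        return labels


def _norm(name: str) -> str:
    return " ".join(str(name).split()).casefold()


def _value(summary: RiskSummary, key: str) -> float:
    if key == "rr_mean":
        return summary.rr_mean
    if key == "smr":
        if summary.smr is None:
            raise MappingError(f"{summary.area_id}: no SMR attached")
        return summary.smr
    if key.startswith("exceedance@"):
        c = float(key.split("@", 1)[1])
        try:
            return summary.exceedance[c]
        except KeyError:
            raise MappingError(f"threshold {c:g} absent for {summary.area_id}")
    raise MappingError(f"unknown value key {key!r}")


def join_geometry(
    summaries: Iterable[RiskSummary],
    geojson: dict | str | Path,
    id_property: str = "id",
    strict: bool = True,
) -> dict:
    """Annotate GeoJSON features with risk-summary properties.

    Areas match features by ``properties[id_property]`` (or the feature
    ``id``) after whitespace/case normalization.  Unmatched summaries raise
    (strict) or warn (lenient); unmatched features are always reported.
    """
    if not isinstance(geojson, dict):
        geojson = json.loads(Path(geojson).read_text(encoding="utf-8"))
    summaries = list(summaries)
    lookup = {_norm(s.area_id): s for s in summaries}
    out_features = []
    matched: set[str] = set()
    for feat in geojson.get("features", []):
        props = dict(feat.get("properties") or {})
        fid = props.get(id_property, feat.get("id"))
        s = lookup.get(_norm(fid)) if fid is not None else None
        if s is not None:
            matched.add(_norm(s.area_id))
            props.update(
                area_id=s.area_id,
                rr_mean=s.rr_mean,
                rr_lo=s.rr_lo,
                rr_hi=s.rr_hi,
                **{f"exceedance@{c:g}": p for c, p in s.exceedance.items()},
            )
            if s.smr is not None:
                props["smr"] = s.smr
        out_features.append({**feat, "properties": props})
    unmatched = [
        s.area_id for s in summaries if _norm(s.area_id) not in matched
    ]
    if unmatched:
        msg = f"summaries with no matching feature: {unmatched}"
        if strict:
            raise MappingError(msg)
        logger.warning(msg)
    return {"type": "FeatureCollection", "features": out_features}


def assign_bins(values: Sequence[float], breaks: Sequence[float]) -> np.ndarray:
    """Bin index per value: bin k holds values in (breaks[k-1], breaks[k]]."""
    return np.digitize(values, np.asarray(breaks), right=True)


def _annotated(features: list[dict], key: str) -> list[tuple[dict, float]]:
    pairs = []
    for feat in features:
        props = feat.get("properties") or {}
        if key in props:
            pairs.append((feat, float(props[key])))
    if not pairs:
        raise MappingError(
            f"no features annotated with {key!r}; run join_geometry first"
        )
    return pairs


def render_static(
    annotated: dict, layer: MapLayerSpec, out: str | Path
) -> Path:
    """Static choropleth (SVG/PNG by extension) with a binned legend.

    Deterministic: identical inputs yield byte-identical SVG output.
    """
    import matplotlib.pyplot as plt
    from matplotlib.patches import Patch
    from matplotlib.path import Path as MplPath
    from matplotlib.patches import PathPatch

    pairs = _annotated(annotated.get("features", []), layer.value_key)
    colors = layer.colors()
    bins = assign_bins([v for _, v in pairs], layer.breaks)
    with plt.rc_context({"svg.hashsalt": "bymmap"}):
        fig, ax = plt.subplots(figsize=(8, 8))
        for (feat, _val), b in zip(pairs, bins):
            path = _geom_path(MplPath, feat["geometry"])
            ax.add_patch(
                PathPatch(
                    path, facecolor=colors[b], edgecolor="#555555", lw=0.4
                )
            )
        ax.autoscale_view()
        ax.set_aspect("equal")
        ax.axis("off")
        handles = [
            Patch(facecolor=c, edgecolor="#555555", label=lab)
            for c, lab in zip(colors, layer.bin_labels())
        ]
        ax.legend(
            handles=handles,
            title=layer.legend_title,
            loc="lower left",
            fontsize=8,
            title_fontsize=9,
        )
        out = Path(out)
        fig.savefig(out, bbox_inches="tight", metadata=_no_date(out.suffix))
        plt.close(fig)
    return out


def _no_date(suffix: str) -> dict:
    return {"Date": None} if suffix.lower() == ".svg" else {}


def _geom_path(MplPath, geometry: dict):
    geom = shape(geometry)
    polys = [geom] if geom.geom_type == "Polygon" else list(geom.geoms)
    vertices: list = []
    codes: list = []
    for poly in polys:
        for ring in [poly.exterior, *poly.interiors]:
            pts = np.asarray(ring.coords)
            vertices.extend(pts)
            codes.extend(
                [MplPath.MOVETO] + [MplPath.LINETO] * (len(pts) - 2) + [MplPath.CLOSEPOLY]
            )
    return MplPath(np.array(vertices), codes)


def _svg_rings(geometry: dict, tx) -> str:
    geom = shape(geometry)
    polys = [geom] if geom.geom_type == "Polygon" else list(geom.geoms)
    parts = []
    for poly in polys:
        for ring in [poly.exterior, *poly.interiors]:
            pts = " ".join(
                "L{:.2f},{:.2f}".format(*tx(x, y)) for x, y in ring.coords
            )
            parts.append("M" + pts[1:] + "Z")
    return " ".join(parts)


def render_interactive(
    annotated: dict,
    layers: Sequence[MapLayerSpec],
    out: str | Path,
    title: str = "Disease-mapping summary",
) -> Path:
    """Self-contained interactive HTML choropleth with layer toggles.

    Each layer is an SVG group; radio buttons switch layers, and every area
    carries a tooltip with its id, RR, 95% CI and exceedance probabilities.
    """
    features = annotated.get("features", [])
    if not features:
        raise MappingError("empty feature collection")
    if not layers:
        raise MappingError("at least one layer required")
    geoms = [shape(f["geometry"]) for f in features]
    minx = min(g.bounds[0] for g in geoms)
    miny = min(g.bounds[1] for g in geoms)
    maxx = max(g.bounds[2] for g in geoms)
    maxy = max(g.bounds[3] for g in geoms)
    W = 760.0
    scale = W / max(maxx - minx, 1e-12)
    H = (maxy - miny) * scale

    def tx(x, y):
        return (x - minx) * scale, (maxy - y) * scale

    def tooltip(props: dict) -> str:
        lines = [str(props.get("area_id", "?"))]
        if "rr_mean" in props:
            lines.append(
                "RR {:.2f} (95% CI {:.2f}-{:.2f})".format(
                    props["rr_mean"], props["rr_lo"], props["rr_hi"]
                )
            )
        for key in sorted(props):
            if key.startswith("exceedance@"):
                c = key.split("@", 1)[1]
                lines.append(f"P(RR>{c}) = {props[key]:.2f}")
        if "smr" in props:
            lines.append(f"SMR {props['smr']:.2f}")
        return html.escape("\n".join(lines))

    groups = []
    legends = []
    for li, layer in enumerate(layers):
        pairs = _annotated(features, layer.value_key)
        colors = layer.colors()
        bins = assign_bins([v for _, v in pairs], layer.breaks)
        paths = []
        for (feat, val), b in zip(pairs, bins):
            d = _svg_rings(feat["geometry"], tx)
            props = feat.get("properties") or {}
            paths.append(
                f'<path d="{d}" fill="{colors[b]}" stroke="#555" '
                f'stroke-width="0.4" data-area="{html.escape(str(props.get("area_id", "")))}" '
                f'data-value="{val:.6g}"><title>{tooltip(props)}</title></path>'
            )
        display = "inline" if li == 0 else "none"
        groups.append(
            f'<g id="layer{li}" class="map-layer" display="{display}">'
            + "".join(paths)
            + "</g>"
        )
        swatches = "".join(
            f'<span class="swatch"><i style="background:{c}"></i>{html.escape(lab)}</span>'
            for c, lab in zip(colors, layer.bin_labels())
        )
        legends.append(
            f'<div id="legend{li}" class="legend" style="display:{display}">'
            f"<b>{html.escape(layer.legend_title)}</b><br>{swatches}</div>"
        )
    buttons = "".join(
        f'<label><input type="radio" name="layer" value="{li}"'
        f'{" checked" if li == 0 else ""}> '
        f"{html.escape(layer.html_title or layer.legend_title)}</label> "
        for li, layer in enumerate(layers)
    )
    doc = f"""<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>{html.escape(title)}</title>
<style>
body {{ font-family: sans-serif; margin: 1em; }}
.legend {{ margin-top: .5em; font-size: 0.85em; }}
.swatch i {{ display:inline-block; width:1em; height:1em; margin:0 .3em 0 .8em;
             vertical-align:-0.15em; border:1px solid #888; }}
path:hover {{ stroke:#000; stroke-width:1.2; }}
</style>
</head>
<body>
<h2>{html.escape(title)}</h2>
<form id="layer-toggle">{buttons}</form>
<svg viewBox="0 0 {W:.0f} {H:.0f}" width="{W:.0f}" height="{H:.0f}"
     xmlns="http://www.w3.org/2000/svg">
{"".join(groups)}
</svg>
{"".join(legends)}
<script>
document.getElementById('layer-toggle').addEventListener('change', function (e) {{
  var v = e.target.value;
  document.querySelectorAll('.map-layer').forEach(function (g, i) {{
    g.setAttribute('display', String(i) === v ? 'inline' : 'none');
  }});
  document.querySelectorAll('.legend').forEach(function (d, i) {{
    d.style.display = String(i) === v ? 'block' : 'none';
  }});
}});
</script>
</body>
</html>
"""
    out = Path(out)
    out.write_text(doc, encoding="utf-8")
    return out
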