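"""Rendering: 2D contour + marginal histogram, 3D surface with CI layers.

Color contract: darker always means worse outcome.  For survival surfaces a
perceptually uniform sequential scale runs dark (low survival) to light
(high survival); for cumulative incidence the scale is reversed so that high
incidence -- the bad outcome -- stays dark.

Static exports (PNG/SVG) use matplotlib; interactive HTML is a single
self-contained file with the figure data embedded as JSON and the hover /
rotation logic inlined (no network fetches).  SVG output is byte-
deterministic: hash salt fixed, timestamps suppressed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib import cm

from ._template import render_page
from .data import CovariateSummary
from .errors import ConsistencyError, FormatError
from .surface import SurvivalSurface

__all__ = ["RenderOptions", "FigureArtifact", "render_contour2d", "render_surface3d", "export"]

#: max grid points per axis embedded in the 3D HTML (keeps rotation fluid)
_MAX_3D_AXIS = 60


@dataclass(frozen=True)
class RenderOptions:
    time_label: str = "Time"
    predictor_label: str | None = None   # default: the surface's predictor name
    level_step: float = 0.05             # probability band width
    cmap: str = "viridis"
    hist_color: str = "#ff7f0e"          # orange, the marginal histogram
    ci_opacity: float = 0.3
    percent_decimals: int = 1
    title: str = ""

    @classmethod
    def coerce(cls, options) -> "RenderOptions":
        if options is None:
            return cls()
        if isinstance(options, cls):
            return options
        return cls(**options)


@dataclass
class FigureArtifact:
    kind: str                      # "contour2d" | "surface3d"
    figure: "plt.Figure"
    payload: dict                  # everything the HTML export embeds
    color_scale: tuple[str, bool]  # (cmap name, reversed flag)

    def close(self):
        plt.close(self.figure)


def _effective_cmap(options: RenderOptions, outcome_type: str):
    """Scale oriented so darker = worse outcome in both modes."""
    reversed_ = outcome_type == "cumulative_incidence"
    name = options.cmap + ("_r" if reversed_ else "")
    return plt.get_cmap(name), reversed_


def _band_colors(cmap, level_step: float) -> list[str]:
    n = int(round(1.0 / level_step))
    mids = (np.arange(n) + 0.5) * level_step
    return [matplotlib.colors.to_hex(cmap(v)) for v in mids]


def _surface_payload(surface: SurvivalSurface) -> dict:
    d = json.loads(surface.to_json())
    return d


def _common_payload(surface, options, outcome_type):
    cmap, reversed_ = _effective_cmap(options, outcome_type)
    return {
        "options": {
            "time_label": options.time_label,
            "predictor_label": options.predictor_label or surface.predictor_name,
            "level_step": options.level_step,
            "hist_color": options.hist_color,
            "ci_opacity": options.ci_opacity,
            "percent_decimals": options.percent_decimals,
        },
        "colors": {
            "name": options.cmap,
            "reversed": reversed_,
            "band_colors": _band_colors(cmap, options.level_step),
        },
    }, cmap


def render_contour2d(
    surface: SurvivalSurface, summary: CovariateSummary | None = None, options=None
) -> FigureArtifact:
    """Filled contour (x = time, y = predictor, color = probability) with the
    predictor's histogram aligned on the shared y-axis at the right."""
    options = RenderOptions.coerce(options)
    if summary is not None and summary.column != surface.predictor_name:
        raise ConsistencyError(
            f"histogram summarizes {summary.column!r} but the surface plots "
            f"{surface.predictor_name!r}"
        )
    payload, cmap = _common_payload(surface, options, surface.outcome_type)
    payload["kind"] = "contour2d"
    payload["surface"] = _surface_payload(surface)
    payload["histogram"] = (
        None if summary is None else [list(b) for b in summary.histogram]
    )

    fig, (ax, axh) = plt.subplots(
        1, 2, figsize=(9, 5.2), sharey=True,
        gridspec_kw={"width_ratios": [4, 1], "wspace": 0.06},
    )
    tg, cv = surface.time_grid, surface.covariate_values
    levels = np.arange(0.0, 1.0 + options.level_step / 2, options.level_step)
    cs = ax.contourf(tg, cv, surface.values, levels=levels, cmap=cmap, vmin=0, vmax=1)
    ax.set_xlabel(options.time_label)
    ax.set_ylabel(options.predictor_label or surface.predictor_name)
    if options.title:
        ax.set_title(options.title)
    cb = fig.colorbar(cs, ax=ax, location="bottom", pad=0.14, aspect=40)
    cb.set_label(
        "predicted survival" if surface.outcome_type == "survival"
        else "predicted cumulative incidence"
    )
    if summary is not None and summary.kind == "continuous":
        lefts = np.array([b[0] for b in summary.histogram])
        rights = np.array([b[1] for b in summary.histogram])
        counts = np.array([b[2] for b in summary.histogram])
        axh.barh(
            (lefts + rights) / 2, counts, height=(rights - lefts),
            color=options.hist_color, edgecolor="none",
        )
        axh.set_xlabel("count")
    axh.tick_params(left=False)
    return FigureArtifact("contour2d", fig, payload, (options.cmap, payload["colors"]["reversed"]))


def _subsample(arr: np.ndarray, stride: int, axis: int) -> np.ndarray:
    idx = np.r_[np.arange(0, arr.shape[axis] - 1, stride), arr.shape[axis] - 1]
    return np.take(arr, idx.astype(int), axis=axis)


def render_surface3d(surface: SurvivalSurface, options=None) -> FigureArtifact:
    """3D surface z = probability over (time, predictor).  When bands exist
    they are drawn as semitransparent layers around the opaque estimate."""
    options = RenderOptions.coerce(options)
    payload, cmap = _common_payload(surface, options, surface.outcome_type)
    payload["kind"] = "surface3d"

    tg, cv, V = surface.time_grid, surface.covariate_values, surface.values
    st = max(1, int(np.ceil((tg.size - 1) / _MAX_3D_AXIS)))
    sc = max(1, int(np.ceil((cv.size - 1) / _MAX_3D_AXIS)))
    tg_s = _subsample(tg, st, 0)
    cv_s = _subsample(cv, sc, 0)

    def sub(mat):
        return _subsample(_subsample(mat, st, 1), sc, 0)

    sub_surface = SurvivalSurface(
        time_grid=tg_s, covariate_values=cv_s, values=sub(V),
        outcome_type=surface.outcome_type, model_tag=surface.model_tag,
        predictor_name=surface.predictor_name, ci_level=surface.ci_level,
    )
    payload["surface"] = _surface_payload(sub_surface)
    if surface.has_bands:
        layers = [
            {"z": sub(surface.lower).tolist(), "opacity": options.ci_opacity},
            {"z": sub(V).tolist(), "opacity": 1.0},
            {"z": sub(surface.upper).tolist(), "opacity": options.ci_opacity},
        ]
    else:
        layers = [{"z": sub(V).tolist(), "opacity": 1.0}]
    payload["layers"] = layers

    fig = plt.figure(figsize=(8, 6))
    ax = fig.add_subplot(projection="3d")
    T, C = np.meshgrid(tg_s, cv_s)
    ax.plot_surface(T, C, sub(V), cmap=cmap, vmin=0, vmax=1, antialiased=False)
    if surface.has_bands:
        for mat in (surface.lower, surface.upper):
            ax.plot_surface(
                T, C, sub(mat), color="#888888", alpha=options.ci_opacity,
                antialiased=False,
            )
    ax.set_xlabel(options.time_label)
    ax.set_ylabel(options.predictor_label or surface.predictor_name)
    ax.set_zlabel(
        "survival" if surface.outcome_type == "survival" else "cumulative incidence"
    )
    if options.title:
        ax.set_title(options.title)
    return FigureArtifact("surface3d", fig, payload, (options.cmap, payload["colors"]["reversed"]))


def export(artifact: FigureArtifact, path, format: str | None = None, dpi: int = 150) -> Path:
    """Write the artifact: ``html`` interactive, ``png``/``svg`` static.

    The format defaults to the file extension; an explicit format that
    contradicts the extension is an error rather than a silent mismatch.
    """
    path = Path(path)
    ext = path.suffix.lstrip(".").lower()
    fmt = (format or ext).lower()
    if fmt not in ("html", "png", "svg"):
        raise FormatError(f"unsupported format {fmt!r} (use html, png or svg)")
    if format is not None and ext and ext != fmt:
        raise FormatError(f"format {fmt!r} contradicts extension {ext!r}")

    if fmt == "html":
        title = artifact.payload["options"].get("predictor_label", "survcontour")
        html = render_page(artifact.kind, json.dumps(artifact.payload), f"survcontour: {title}")
        path.write_text(html)
        return path

    with matplotlib.rc_context({"svg.hashsalt": "survcontour"}):
        artifact.figure.savefig(
            path, format=fmt, dpi=dpi, metadata={"Date": None} if fmt == "svg" else None
        )
    return path
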