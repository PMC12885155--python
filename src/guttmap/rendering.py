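"""Render the Guttman error map as an annotated symmetric heatmap.

The map is a k x k grid with an empty diagonal: cell (i, j) is filled
with the band color of e_ij and annotated with the percentage. Both
triangles show identical values so the error profile can be read
vertically, following how errors shrink as item pairs move apart in
endorsement. An optional smoothing level blends the discrete blocks
with a bilinear interpolation of the cell-center values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import matplotlib

matplotlib.use("Agg")  # headless; figures are built without pyplot state

from matplotlib import font_manager
from matplotlib.cm import ScalarMappable
from matplotlib.colors import Normalize
from matplotlib.figure import Figure
from scipy.interpolate import griddata

from .classification import BandScheme, DEFAULT_SCHEME
from .data_model import ConfigurationError, ErrorMap, HSummary

logger = logging.getLogger("guttmap")

__all__ = ["RenderOptions", "render_map", "smooth_field", "export",
           "SUPPORTED_FORMATS"]

SUPPORTED_FORMATS = ("svg", "pdf", "png", "ps", "jpg")

#: pixels per grid cell when rasterizing the color field; odd so one pixel
#: center lands exactly on each cell center (an interpolation anchor)
FIELD_RESOLUTION = 25


@dataclass
class RenderOptions:
    """Appearance options for the error map figure.

    Sizes are in points except ``val_size``, which uses the same plot
    units as the originating routine and is mapped to points with a
    fixed x4 factor. ``smooth`` in [0, 100] blends the discrete heatmap
    (0) with a continuous bilinear gradient (100).
    """

    title: str = "Guttman Error Map"
    font_family: str = "Times New Roman"
    title_size: float = 18.0
    xlab_size: float = 12.0
    ylab_size: float = 12.0
    val_size: float = 3.5
    val_format: str = "%.1f"
    item_position: str = "bottom"      # or "top"
    legend_position: str = "bottom"    # bottom / right / left / top / none
    legend_title: str = "% error"
    legend_size: float = 100.0         # percent of the plot body
    smooth: float = 0.0
    show_item_h: bool = False          # h_i line under the item labels
    show_total_h: bool = False         # total H appended to the title
    scheme: BandScheme = field(default_factory=lambda: DEFAULT_SCHEME)
    suppress_warnings: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.smooth <= 100:
            raise ConfigurationError("smooth must lie in [0, 100]")
        if self.item_position not in ("bottom", "top"):
            raise ConfigurationError("item_position must be 'bottom' or 'top'")
        if self.legend_position not in ("bottom", "right", "left", "top", "none"):
            raise ConfigurationError(
                "legend_position must be bottom/right/left/top/none"
            )


def smooth_field(em: ErrorMap, smooth: float,
                 resolution: int = FIELD_RESOLUTION) -> np.ndarray:
    """Per-pixel error-value field for the color layer.

    smooth=0 returns the blockwise-constant field (each pixel carries its
    cell's e_ij); smooth=100 a bilinear interpolation of cell-center
    values with the diagonal excluded from the interpolation support;
    intermediate levels are the per-pixel convex combination of the two.
    Diagonal cells are masked (NaN) at every level.
    """
    if not 0 <= smooth <= 100:
        raise ConfigurationError("smooth must lie in [0, 100]")
    k = em.n_items
    e = em.e_percent
    px = k * resolution
    cell = (np.arange(px) + 0.5) / resolution  # pixel centers in cell units
    ci = np.floor(cell).astype(int)

    discrete = e[np.ix_(ci, ci)]

    t = smooth / 100.0
    if t == 0.0:
        blended = discrete.copy()
    else:
        rows, cols = np.nonzero(~np.eye(k, dtype=bool) & np.isfinite(e))
        pts = np.column_stack([rows + 0.5, cols + 0.5])
        vals = e[rows, cols]
        gy, gx = np.meshgrid(cell, cell, indexing="ij")
        cont = griddata(pts, vals, (gy, gx), method="linear")
        # corners fall outside the convex hull of off-diagonal centers
        holes = np.isnan(cont)
        if holes.any():
            cont[holes] = griddata(pts, vals, (gy[holes], gx[holes]),
                                   method="nearest")
        blended = (1.0 - t) * discrete + t * cont

    diag_mask = ci[:, None] == ci[None, :]
    blended[diag_mask] = np.nan
    return blended


def _resolve_font(family: str, suppress_warnings: bool) -> str:
    available = {f.name for f in font_manager.fontManager.ttflist}
    if family in available:
        return family
    if not suppress_warnings:
        warnings.warn(
            f"font family {family!r} is not available; falling back to serif",
            stacklevel=3,
        )
    return "serif"


def render_map(em: ErrorMap, hs: HSummary, opts: RenderOptions | None = None) -> Figure:
    """Build the error-map figure from a computed map and its coefficients.

    Rendering is a pure function of its inputs: identical arguments give
    identical figures (and byte-identical SVG once timestamps are
    suppressed). Smoothing changes only the color field, never the
    annotated values.
    """
    opts = opts or RenderOptions()
    k = em.n_items
    fontfam = _resolve_font(opts.font_family, opts.suppress_warnings)

    fig = Figure(figsize=(max(4.0, 1.1 * k + 1.5),) * 2)
    ax = fig.add_subplot(111)

    field_vals = smooth_field(em, opts.smooth)
    cmap = opts.scheme.colormap()
    anchors = [a for a, _ in opts.scheme.stops]
    norm = Normalize(vmin=anchors[0], vmax=anchors[-1], clip=True)
    ax.imshow(field_vals, cmap=cmap, norm=norm, origin="upper",
              extent=(0, k, k, 0), interpolation="nearest", aspect="equal")

    if opts.val_size > 0:
        for i in range(k):
            for j in range(k):
                if i == j or not np.isfinite(em.e_percent[i, j]):
                    continue
                ax.text(j + 0.5, i + 0.5, opts.val_format % em.e_percent[i, j],
                        ha="center", va="center",
                        fontsize=opts.val_size * 4.0, family=fontfam)

    xlabels = list(em.labels)
    if opts.show_item_h:
        xlabels = [
            f"{lab}\n" + ("%.3f" % h if np.isfinite(h) else "undef")
            for lab, h in zip(xlabels, hs.h_item)
        ]
    ticks = np.arange(k) + 0.5
    ax.set_xticks(ticks, xlabels, fontsize=opts.xlab_size, family=fontfam)
    ax.set_yticks(ticks, em.labels, fontsize=opts.ylab_size, family=fontfam)
    ax.tick_params(length=0)
    if opts.item_position == "top":
        ax.xaxis.set_ticks_position("top")
        ax.xaxis.set_label_position("top")
    for spine in ax.spines.values():
        spine.set_visible(False)

    title = opts.title
    if opts.show_total_h and np.isfinite(hs.h_total):
        title = f"{title} (H = {hs.h_total:.3f})"
    ax.set_title(title, fontsize=opts.title_size, family=fontfam,
                 pad=28 if opts.item_position == "top" else 8)

    if opts.legend_position != "none":
        mappable = ScalarMappable(norm=norm, cmap=cmap)
        horizontal = opts.legend_position in ("bottom", "top")
        cbar = fig.colorbar(
            mappable, ax=ax, location=opts.legend_position,
            orientation="horizontal" if horizontal else "vertical",
            fraction=0.046 * opts.legend_size / 100.0,
            shrink=opts.legend_size / 100.0, pad=0.12 if horizontal else 0.04,
        )
        cbar.set_label(opts.legend_title, fontsize=opts.xlab_size,
                       family=fontfam)
        cbar.set_ticks(list(anchors))
        cbar.ax.tick_params(labelsize=max(6.0, opts.xlab_size - 3))
    return fig


def export(fig: Figure, path, fmt: str = "svg", dpi: int = 150) -> None:
    """Write the figure to disk; SVG is the default vector format.

    SVG output is made deterministic by pinning the hash salt and
    stripping the creation date, so repeated renders of the same inputs
    are byte-identical.
    """
    fmt = fmt.lower().lstrip(".")
    if fmt == "jpeg":
        fmt = "jpg"
    if fmt not in SUPPORTED_FORMATS:
        raise ConfigurationError(
            f"unsupported format {fmt!r}; choose one of {SUPPORTED_FORMATS}"
        )
    save_kwargs: dict = {"format": fmt, "dpi": dpi}
    if fmt == "svg":
        save_kwargs["metadata"] = {"Date": None}
        with matplotlib.rc_context({"svg.hashsalt": "guttmap"}):
            fig.savefig(path, **save_kwargs)
    else:
        fig.savefig(path, **save_kwargs)
    logger.info("figure written to %s", path)
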