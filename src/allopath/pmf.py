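"""Two-dimensional pseudo-potentials of mean force.

PMF(x, y) = −k_B·T·ln H(x, y), with H a normalized 2D histogram of two
observables and T defaulting to 300.0 K.  Values are kcal/mol
(k_B = 0.0019872041 kcal mol⁻¹ K⁻¹), min-shifted to zero; empty bins are
masked (NaN), never assigned a finite penalty.  When the samples come
from driven, out-of-equilibrium trajectories the surface is only a
qualitative ("pseudo") free-energy landscape — the computation is the
same either way.

The canonical six-panel set pairs S4 displacement (1.0 Å bins), S4
rotation (2° bins), S6 bending (1°) and PD–CTD rotation (1°).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import GeometrySeries

__all__ = ["KB_KCAL_MOL_K", "PseudoPMF", "pmf_2d", "pmf_panel", "PANEL_BIN_WIDTHS"]

log = logging.getLogger(__name__)

KB_KCAL_MOL_K = 0.0019872041

# bin widths by observable, native units (Å or degrees)
PANEL_BIN_WIDTHS = {
    "s4_displacement": 1.0,
    "s4_rotation": 2.0,
    "s6_bending": 1.0,
    "pd_ctd_rotation": 1.0,
}

# (y, x) observable pairs of the canonical panel
PANEL_PAIRS = [
    ("s4_rotation", "s4_displacement"),
    ("s6_bending", "s4_displacement"),
    ("s6_bending", "s4_rotation"),
    ("pd_ctd_rotation", "s4_displacement"),
    ("pd_ctd_rotation", "s4_rotation"),
    ("pd_ctd_rotation", "s6_bending"),
]


class PMFError(Exception):
    pass


@dataclass(frozen=True)
class PseudoPMF:
    x_label: str
    y_label: str
    x_edges: np.ndarray
    y_edges: np.ndarray
    hist: np.ndarray  # normalized, sums to 1 over occupied bins
    pmf: np.ndarray  # kcal/mol, min-shifted to 0, NaN on empty bins
    pmf_raw: np.ndarray  # −k_B T ln H without the shift
    temperature: float

    @property
    def occupied(self) -> np.ndarray:
        return self.hist > 0


def _edges(series: np.ndarray, width: float) -> np.ndarray:
    lo = np.floor(series.min() / width) * width
    hi = np.ceil(series.max() / width) * width
    if hi <= lo:
        hi = lo + width
    n = int(round((hi - lo) / width))
    return lo + width * np.arange(n + 1)


def pmf_2d(
    x_series: np.ndarray,
    y_series: np.ndarray,
    bin_width_x: float,
    bin_width_y: float,
    temperature: float = 300.0,
    x_label: str = "x",
    y_label: str = "y",
) -> PseudoPMF:
    """Pseudo-PMF surface of two equal-length observable series.

    Bin edges are anchored at integer multiples of the bin width, so adding
    a constant to a series relabels bins without changing PMF values.
    """
    x = np.asarray(x_series, dtype=float)
    y = np.asarray(y_series, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise PMFError("x and y must be equal-length 1D series")
    if x.size < 1:
        raise PMFError("empty series")
    if bin_width_x <= 0 or bin_width_y <= 0:
        raise PMFError("bin widths must be positive")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    xe, ye = _edges(x, bin_width_x), _edges(y, bin_width_y)
    h, _, _ = np.histogram2d(x, y, bins=(xe, ye))
    hist = h / h.sum()
    if np.count_nonzero(hist) == 1:
        log.warning("single occupied bin: flat pseudo-PMF")
    with np.errstate(divide="ignore"):
        raw = -KB_KCAL_MOL_K * temperature * np.log(hist)
    raw[hist == 0] = np.nan
    pmf = raw - np.nanmin(raw)
    return PseudoPMF(
        x_label=x_label,
        y_label=y_label,
        x_edges=xe,
        y_edges=ye,
        hist=hist,
        pmf=pmf,
        pmf_raw=raw,
        temperature=temperature,
    )


def pmf_panel(
    geom: GeometrySeries, temperature: float = 300.0
) -> dict[tuple[str, str], PseudoPMF]:
    """The six canonical surfaces, keyed by (y_observable, x_observable)."""
    out = {}
    for y_name, x_name in PANEL_PAIRS:
        out[(y_name, x_name)] = pmf_2d(
            geom.observable(x_name),
            geom.observable(y_name),
            PANEL_BIN_WIDTHS[x_name],
            PANEL_BIN_WIDTHS[y_name],
            temperature=temperature,
            x_label=x_name,
            y_label=y_name,
        )
    return out
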