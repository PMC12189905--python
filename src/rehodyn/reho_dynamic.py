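"""Dynamic regional homogeneity: temporal variability of windowed ReHo.

The time series is cut into rectangular sliding windows (default 50 TRs
long, stepped by 5 TRs; 230 retained time points give 37 windows), static
ReHo is computed inside each window with the same neighbourhood and tie
conventions as the static module, and each voxel's dynamic ReHo is the
coefficient of variation of its windowed W values:

    CV_i = sqrt( (1/n) * sum_t (x_t - x_mean)^2 ) / x_mean,

with x_t the (raw, untransformed) ReHo of voxel i in window t and the
standard deviation in population form (divide by n).  CV maps are then
z-standardised over the mask and smoothed like the static maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import BoldSeries, ScalarMap
from .reho_static import NeighborhoodSpec, reho_map, standardize_reho

logger = logging.getLogger("rehodyn.dreho")

__all__ = [
    "WindowSpec",
    "DynReHoMap",
    "sliding_windows",
    "dynamic_reho_cv",
    "zscore_map",
    "WINDOW_LENGTH_DEFAULT_TR",
    "WINDOW_STEP_DEFAULT_TR",
]

WINDOW_LENGTH_DEFAULT_TR = 50
WINDOW_STEP_DEFAULT_TR = 5


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window layout: length L, step S, and the derived starts.

    ``n_windows = floor((T - L) / S) + 1``; every window fits in [0, T).
    """

    length_tr: int
    step_tr: int
    starts: tuple[int, ...] = field(default=())

    @property
    def n_windows(self) -> int:
        return len(self.starts)


def sliding_windows(
    n_timepoints: int,
    length_tr: int = WINDOW_LENGTH_DEFAULT_TR,
    step_tr: int = WINDOW_STEP_DEFAULT_TR,
) -> WindowSpec:
    """Enumerate window start indices: 0, S, 2S, ... while start + L <= T."""
    T, L, S = int(n_timepoints), int(length_tr), int(step_tr)
    if L <= 0 or S <= 0:
        raise ValueError("window length and step must be positive")
    if L > T:
        raise ValueError(f"window length {L} exceeds series length {T}")
    starts = tuple(range(0, T - L + 1, S))
    return WindowSpec(length_tr=L, step_tr=S, starts=starts)


@dataclass
class DynReHoMap:
    """CV of windowed ReHo per voxel, optionally with the window stack."""

    cv: ScalarMap
    windows: WindowSpec
    z: ScalarMap | None = None
    window_reho: np.ndarray | None = None  # (n_windows, x, y, z) of W


def dynamic_reho_cv(
    bold: BoldSeries,
    mask: np.ndarray,
    spec: NeighborhoodSpec = NeighborhoodSpec(),
    windows: WindowSpec | None = None,
    min_freq_hz: float | None = 0.01,
    on_transformed: bool = False,
    keep_window_stack: bool = False,
) -> DynReHoMap:
    """Coefficient of variation of windowed ReHo at every in-mask voxel.

    ``min_freq_hz`` triggers a warning when the window is shorter than
    the period of the slowest passband frequency (windows should be
    longer than 1/f_min to avoid spurious fluctuations).
    ``on_transformed`` computes the CV on Fisher-z values instead of raw
    W — a sensitivity option, off by default.
    """
    if windows is None:
        windows = sliding_windows(bold.n_volumes)
    if windows.starts and windows.starts[-1] + windows.length_tr > bold.n_volumes:
        raise ValueError("window specification exceeds series length")
    if min_freq_hz and windows.length_tr * bold.tr_s < 1.0 / min_freq_hz:
        logger.warning(
            "window length %.0f s is shorter than 1/f_min = %.0f s; "
            "windowed ReHo may show spurious fluctuations",
            windows.length_tr * bold.tr_s, 1.0 / min_freq_hz,
        )

    stack = np.empty((windows.n_windows, *bold.shape))
    for i, s in enumerate(windows.starts):
        sub = bold.with_data(bold.data[..., s : s + windows.length_tr])
        wmap = reho_map(sub, mask, spec)
        x = standardize_reho(wmap, "fisher") if on_transformed else wmap.w
        stack[i] = np.where(x.mask, x.data, np.nan)

    n_def = np.isfinite(stack).sum(axis=0)
    with np.errstate(invalid="ignore"):
        x_mean = np.nanmean(np.where(np.isfinite(stack), stack, np.nan), axis=0)
        x_sd = np.nanstd(stack, axis=0)  # population form: divide by n
    cv = np.full(bold.shape, np.nan)
    defined = np.asarray(mask, bool) & (n_def > 0) & (x_mean > 0)
    cv[defined] = x_sd[defined] / x_mean[defined]
    n_und = int(np.asarray(mask, bool).sum() - defined.sum())
    if n_und:
        logger.info("dynamic_reho_cv: %d in-mask voxels undefined", n_und)
    return DynReHoMap(
        cv=ScalarMap(cv, bold.affine, defined),
        windows=windows,
        window_reho=stack if keep_window_stack else None,
    )


def zscore_map(smap: ScalarMap, mask: np.ndarray | None = None) -> ScalarMap:
    """Z-standardise a map over its defined in-mask voxels (population SD)."""
    defined = smap.mask & np.isfinite(smap.data)
    if mask is not None:
        defined = defined & np.asarray(mask, bool)
    vals = smap.data[defined]
    if vals.size < 2:
        raise ValueError("need at least 2 defined voxels to z-score")
    sd = vals.std()  # ddof=0
    if sd == 0:
        raise ValueError("constant map: z-scoring undefined")
    out = np.full(smap.shape, np.nan)
    out[defined] = (smap.data[defined] - vals.mean()) / sd
    return ScalarMap(out, smap.affine, defined)
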