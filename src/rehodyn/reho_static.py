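"""Static regional homogeneity (ReHo) via Kendall's coefficient of concordance.

ReHo measures how synchronised a voxel's BOLD time course is with its
immediate spatial neighbours.  For each in-mask voxel the 27-voxel cube
centred on it (the standard ReHo neighbourhood, centre included) is
collected and Kendall's W is computed across the in-mask member series:

    rank each series over time (midranks for ties),
    R_t = sum of ranks at time t over the K series,
    S   = sum_t (R_t - mean(R))^2,
    W   = 12 S / (K^2 (n^3 - n) - K * sum_j T_j),

with the usual tie correction T_j = sum over tie groups of (t^3 - t) in
series j.  W lies in [0, 1]: 1 means all K series share one rank
ordering, and W is invariant to strictly monotone transforms of any
single series.

The map is computed on filtered, *unsmoothed* data; standardisation
(Fisher r-to-z by default) and 6 mm FWHM Gaussian smoothing follow, in
that order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.ndimage
import scipy.stats

from .core import BoldSeries, ScalarMap

logger = logging.getLogger("rehodyn.reho")

__all__ = [
    "NeighborhoodSpec",
    "ReHoMap",
    "kendalls_w",
    "reho_map",
    "standardize_reho",
    "gaussian_smooth",
    "ATANH_CLIP_EPS",
    "FWHM_DEFAULT_MM",
]

ATANH_CLIP_EPS = 1e-7
FWHM_DEFAULT_MM = 6.0
_SIGMA_PER_FWHM = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Neighbourhood for the concordance statistic.

    ``cube27`` is the 3x3x3 cube including the centre voxel.  Voxels
    whose neighbourhood has fewer than ``min_in_mask`` in-mask members
    are flagged undefined rather than silently zeroed.
    """

    kind: str = "cube27"
    min_in_mask: int = 2

    def __post_init__(self) -> None:
        if self.kind != "cube27":
            raise ValueError(f"unsupported neighborhood kind: {self.kind!r}")
        if not 2 <= self.min_in_mask <= 27:
            raise ValueError("min_in_mask must be in [2, 27]")


@dataclass
class ReHoMap:
    """Result of a ReHo run: raw W, optional standardised map, neighbour counts."""

    w: ScalarMap
    n_neighbors: ScalarMap
    z: ScalarMap | None = None


def _tie_correction_1d(series: np.ndarray) -> float:
    """Sum of (t^3 - t) over tie groups of one series."""
    _, counts = np.unique(series, return_counts=True)
    t = counts[counts > 1].astype(np.float64)
    return float((t**3 - t).sum())


def kendalls_w(series_block: np.ndarray) -> float:
    """Kendall's W across the rows of a ``(K, n)`` block of time series.

    Returns NaN when every series is constant (concordance undefined).
    """
    block = np.asarray(series_block, dtype=np.float64)
    if block.ndim != 2:
        raise ValueError("series_block must be 2D (K series x n time points)")
    K, n = block.shape
    if K < 2:
        raise ValueError("need at least 2 series")
    if n < 3:
        raise ValueError("need at least 3 time points")
    ranks = scipy.stats.rankdata(block, axis=1)
    rank_sums = ranks.sum(axis=0)
    S = float(((rank_sums - K * (n + 1) / 2.0) ** 2).sum())
    tie_sum = sum(_tie_correction_1d(row) for row in block)
    denom = K**2 * (n**3 - n) - K * tie_sum
    if denom <= 0:
        return float("nan")
    return 12.0 * S / denom


def _rank_time(data: np.ndarray) -> np.ndarray:
    """Midranks along the last axis, vectorised over leading axes.

    Equivalent to ranking each series independently with ties averaged;
    tie-free series take a pure double-argsort fast path.
    """
    n = data.shape[-1]
    order = np.argsort(data, axis=-1, kind="stable")
    srt = np.take_along_axis(data, order, axis=-1)
    idx = np.arange(1, n + 1, dtype=np.float64)
    ties = srt[..., 1:] == srt[..., :-1]
    if not ties.any():
        ranks = np.empty(data.shape, dtype=np.float64)
        np.put_along_axis(ranks, order, np.broadcast_to(idx, data.shape), axis=-1)
        return ranks
    # midrank at sorted position i = (first + last index of its tie run)/2 + 1
    pos = np.arange(n, dtype=np.float64)
    is_new = np.concatenate(
        [np.ones((*data.shape[:-1], 1), dtype=bool), ~ties], axis=-1
    )
    start = np.maximum.accumulate(np.where(is_new, pos, 0.0), axis=-1)
    is_last = np.concatenate([~ties, np.ones((*data.shape[:-1], 1), dtype=bool)], axis=-1)
    end = np.flip(
        np.minimum.accumulate(np.where(np.flip(is_last, -1), np.flip(pos, -1), n - 1.0), axis=-1),
        -1,
    )
    mid = (start + end) / 2.0 + 1.0
    ranks = np.empty(data.shape, dtype=np.float64)
    np.put_along_axis(ranks, order, mid, axis=-1)
    return ranks


def _neighborhood_sum(arr: np.ndarray, spatial_ndim: int = 3) -> np.ndarray:
    """Sum over the 3x3x3 spatial neighbourhood (zero-padded borders).

    Works on arrays whose first ``spatial_ndim`` axes are spatial;
    trailing axes (e.g. time) are carried along.
    """
    pad = [(1, 1)] * spatial_ndim + [(0, 0)] * (arr.ndim - spatial_ndim)
    p = np.pad(arr, pad)
    nx, ny, nz = arr.shape[:3]
    out = np.zeros_like(arr, dtype=np.float64)
    for dx in range(3):
        for dy in range(3):
            for dz in range(3):
                out += p[dx : dx + nx, dy : dy + ny, dz : dz + nz]
    return out


def _tie_corrections(data: np.ndarray) -> np.ndarray:
    """Per-voxel tie-correction term sum(t^3 - t) for a (x, y, z, T) array.

    Filtered float data essentially never ties, so the all-distinct case
    is a fast path; voxels with ties fall back to an exact per-voxel
    computation.
    """
    srt = np.sort(data, axis=-1)
    has_tie = (np.diff(srt, axis=-1) == 0).any(axis=-1)
    out = np.zeros(data.shape[:3], dtype=np.float64)
    if has_tie.any():
        for idx in zip(*np.nonzero(has_tie)):
            out[idx] = _tie_correction_1d(data[idx])
    return out


def reho_map(
    bold: BoldSeries,
    mask: np.ndarray,
    spec: NeighborhoodSpec = NeighborhoodSpec(),
) -> ReHoMap:
    """Voxelwise Kendall's W over the in-mask 27-voxel neighbourhood.

    Input should be preprocessed (filtered) but unsmoothed.  Undefined
    voxels — out of mask, too few in-mask neighbours, or all-constant
    neighbourhoods — are NaN and excluded from the mask of the result.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != bold.shape:
        raise ValueError("mask shape must match BOLD spatial grid")
    if not mask.any():
        raise ValueError("empty mask")
    data = bold.data
    T = bold.n_volumes
    if T < 3:
        raise ValueError("need at least 3 time points for ranking")

    ranks = _rank_time(data)
    ranks *= mask[..., None]
    maskf = mask.astype(np.float64)

    K = _neighborhood_sum(maskf)  # in-mask members incl. centre
    rank_sums = _neighborhood_sum(ranks)
    # mean rank sum per time point is K (T + 1) / 2 under midranks
    S = ((rank_sums - K[..., None] * (T + 1) / 2.0) ** 2).sum(axis=-1)
    tie_terms = _tie_corrections(data) * maskf
    tie_sums = _neighborhood_sum(tie_terms)
    denom = K**2 * (T**3 - T) - K * tie_sums

    defined = mask & (K >= spec.min_in_mask) & (denom > 0)
    w = np.full(bold.shape, np.nan)
    w[defined] = 12.0 * S[defined] / denom[defined]
    # guard tiny negative / >1 excursions from float accumulation
    np.clip(w, 0.0, 1.0, out=w)

    n_und = int(mask.sum() - defined.sum())
    if n_und:
        logger.info("reho_map: %d in-mask voxels undefined (flagged NaN)", n_und)
    return ReHoMap(
        w=ScalarMap(w, bold.affine, defined),
        n_neighbors=ScalarMap(K, bold.affine, mask),
    )


def standardize_reho(rmap: ReHoMap | ScalarMap, method: str = "fisher") -> ScalarMap:
    """Standardise a W map for group analysis.

    ``fisher``: z = atanh(W), with W clipped to 1 - 1e-7 so perfect
    concordance stays finite (the clip is logged when it triggers).
    ``zscore``: (W - mask mean) / mask SD.
    """
    wmap = rmap.w if isinstance(rmap, ReHoMap) else rmap
    out = np.full(wmap.shape, np.nan)
    defined = wmap.mask & np.isfinite(wmap.data)
    vals = wmap.data[defined]
    if method == "fisher":
        n_clip = int((vals >= 1.0 - ATANH_CLIP_EPS).sum())
        if n_clip:
            logger.info("standardize_reho: clipping %d voxels at W = 1 - %g", n_clip, ATANH_CLIP_EPS)
        out[defined] = np.arctanh(np.clip(vals, None, 1.0 - ATANH_CLIP_EPS))
    elif method == "zscore":
        sd = vals.std()
        if sd == 0:
            raise ValueError("constant W map: z-scoring undefined")
        out[defined] = (vals - vals.mean()) / sd
    else:
        raise ValueError(f"unknown standardization method: {method!r}")
    return ScalarMap(out, wmap.affine, defined)


def gaussian_smooth(
    smap: ScalarMap,
    fwhm_mm: float = FWHM_DEFAULT_MM,
    voxel_size_mm: float | np.ndarray | None = None,
    renormalize: bool = True,
) -> ScalarMap:
    """Separable Gaussian smoothing with sigma = FWHM / (2 sqrt(2 ln 2)).

    With ``renormalize`` (the default) kernel weights falling outside the
    mask are redistributed within it, so a constant map stays constant
    and no signal bleeds in from undefined voxels.  With
    ``renormalize=False`` a plain zero-padded convolution is used, which
    conserves total mass (an impulse integrates to 1).
    """
    if not fwhm_mm > 0:
        raise ValueError("fwhm_mm must be positive")
    if voxel_size_mm is None:
        voxel_size_mm = np.sqrt((smap.affine[:3, :3] ** 2).sum(axis=0))
    voxel_size_mm = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    sigma_vox = fwhm_mm * _SIGMA_PER_FWHM / voxel_size_mm

    defined = smap.mask & np.isfinite(smap.data)
    filled = np.where(defined, smap.data, 0.0)
    if not renormalize:
        out = scipy.ndimage.gaussian_filter(filled, sigma=sigma_vox, mode="constant")
        return ScalarMap(out, smap.affine, np.ones(smap.shape, dtype=bool))
    num = scipy.ndimage.gaussian_filter(filled, sigma=sigma_vox, mode="constant")
    den = scipy.ndimage.gaussian_filter(defined.astype(np.float64), sigma=sigma_vox, mode="constant")
    out = np.full(smap.shape, np.nan)
    ok = defined & (den > 1e-12)
    out[ok] = num[ok] / den[ok]
    return ScalarMap(out, smap.affine, ok)
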