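"""Resting-state BOLD preprocessing: the in-scope chain.

The pipeline assumes data already on a common voxel grid.  The steps
implemented here, in the fixed order they run:

1. discard of initial volumes (T1 equilibration),
2. nuisance regression — linear trend, white-matter and CSF mean signals
   (supplied as regressor columns), and the Friston-24 expansion of the
   six rigid-body motion parameters,
3. temporal bandpass filtering (default 0.01–0.08 Hz) as an FFT-domain
   ideal filter, which is idempotent and has exact passband edges,

plus head-motion quantification (Jenkinson framewise displacement) and
the exclusion rules (1.5 mm translation, 1.5 degrees rotation, mean FD
0.2, each read as a strict "exceeds").

Spatial steps (slice timing, realignment, coregistration, normalization,
segmentation) are out of scope; motion traces are realignment *estimates*
used only as regressors and for exclusion.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .core import BoldSeries

logger = logging.getLogger("rehodyn.preprocess")

__all__ = [
    "ConfoundMatrix",
    "MotionSummary",
    "discard_initial_volumes",
    "friston24",
    "build_confounds",
    "regress_nuisance",
    "bandpass",
    "framewise_displacement_jenkinson",
    "apply_exclusion",
    "preprocess_bold",
]

# Defaults from the study design this pipeline mirrors.
N_DISCARD_DEFAULT = 10
BAND_DEFAULT_HZ = (0.01, 0.08)
FD_RADIUS_DEFAULT_MM = 50.0
MAX_TRANSLATION_MM = 1.5
MAX_ROTATION_DEG = 1.5
MAX_MEAN_FD_MM = 0.2


@dataclass
class ConfoundMatrix:
    """Named nuisance regressors, one row per retained volume."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        cols = list(self.frame.columns)
        if len(cols) != len(set(cols)):
            raise ValueError("confound column names must be unique")

    @property
    def n_timepoints(self) -> int:
        return len(self.frame)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=np.float64)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


@dataclass
class MotionSummary:
    """Head-motion summary for one subject.

    ``fd_series`` has one entry per volume-to-volume transition
    (length ``n_volumes - 1``); translations in mm, rotations reported
    in degrees for threshold comparison.
    """

    fd_series: np.ndarray
    mean_fd: float
    max_abs_translation: float
    max_abs_rotation: float  # degrees
    excluded: bool = False
    reasons: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "mean_fd": self.mean_fd,
            "max_abs_translation_mm": self.max_abs_translation,
            "max_abs_rotation_deg": self.max_abs_rotation,
            "excluded": self.excluded,
            "reasons": self.reasons,
            "fd_series": np.asarray(self.fd_series).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def discard_initial_volumes(bold: BoldSeries, n_discard: int = N_DISCARD_DEFAULT) -> BoldSeries:
    """Drop the first ``n_discard`` volumes (T1 equilibration).

    240 acquired volumes with the default 10 discarded leave 230 time
    points for analysis.
    """
    n_discard = int(n_discard)
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if n_discard >= bold.n_volumes:
        raise ValueError(
            f"cannot discard {n_discard} of {bold.n_volumes} volumes: empty series"
        )
    if n_discard == 0:
        return bold
    return bold.with_data(bold.data[..., n_discard:])


def friston24(motion6: np.ndarray) -> pd.DataFrame:
    """Friston-24 expansion of a 6-parameter rigid-body motion trace.

    Columns: the 6 parameters, their one-volume-lagged copies (first row
    zero), and the squares of both sets — 24 regressors total.
    """
    motion6 = np.asarray(motion6, dtype=np.float64)
    if motion6.ndim != 2 or motion6.shape[1] != 6:
        raise ValueError(f"motion trace must have 6 columns, got shape {motion6.shape}")
    lagged = np.zeros_like(motion6)
    lagged[1:] = motion6[:-1]
    if not motion6.any():
        logger.warning("all-zero motion trace: Friston-24 regressors are degenerate")
    names = ["tx", "ty", "tz", "rx", "ry", "rz"]
    cols: dict[str, np.ndarray] = {}
    for i, nm in enumerate(names):
        cols[f"mot_{nm}"] = motion6[:, i]
    for i, nm in enumerate(names):
        cols[f"mot_{nm}_lag"] = lagged[:, i]
    for i, nm in enumerate(names):
        cols[f"mot_{nm}_sq"] = motion6[:, i] ** 2
    for i, nm in enumerate(names):
        cols[f"mot_{nm}_lag_sq"] = lagged[:, i] ** 2
    return pd.DataFrame(cols)


def build_confounds(
    n_timepoints: int,
    motion6: np.ndarray | None = None,
    wm_signal: np.ndarray | None = None,
    csf_signal: np.ndarray | None = None,
) -> ConfoundMatrix:
    """Assemble the nuisance matrix: linear trend, WM/CSF means, Friston-24.

    WM/CSF signals are precomputed regressor columns (tissue segmentation
    is out of scope).  The linear trend column folds detrending into the
    regression.
    """
    cols: dict[str, np.ndarray] = {
        "linear_trend": np.linspace(-1.0, 1.0, n_timepoints),
    }
    for name, sig in (("wm_mean", wm_signal), ("csf_mean", csf_signal)):
        if sig is not None:
            sig = np.asarray(sig, dtype=np.float64).ravel()
            if sig.size != n_timepoints:
                raise ValueError(f"{name} length {sig.size} != n_timepoints {n_timepoints}")
            cols[name] = sig
    frame = pd.DataFrame(cols)
    if motion6 is not None:
        motion6 = np.asarray(motion6, dtype=np.float64)
        if motion6.shape[0] != n_timepoints:
            raise ValueError(
                f"motion trace rows {motion6.shape[0]} != n_timepoints {n_timepoints}"
            )
        frame = pd.concat([frame, friston24(motion6)], axis=1)
    return ConfoundMatrix(frame)


def _prune_rank_deficient(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Drop linearly dependent columns via pivoted QR; warn about each."""
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    keep_rank = int((diag > tol).sum())
    if keep_rank == X.shape[1]:
        return X, names
    kept = sorted(piv[:keep_rank])
    dropped = [names[i] for i in sorted(piv[keep_rank:])]
    logger.warning("dropping linearly dependent confound columns: %s", ", ".join(dropped))
    return X[:, kept], [names[i] for i in kept]


def regress_nuisance(bold: BoldSeries, confounds: ConfoundMatrix) -> BoldSeries:
    """Voxelwise OLS residuals after regressing out the confounds.

    An intercept is added internally, so residuals are mean-free and
    orthogonal to every confound column.
    """
    T = bold.n_volumes
    if confounds.n_timepoints != T:
        raise ValueError(
            f"confound rows ({confounds.n_timepoints}) != time points ({T})"
        )
    X = np.column_stack([np.ones(T), confounds.values])
    names = ["intercept"] + list(confounds.frame.columns)
    X, _ = _prune_rank_deficient(X, names)
    Y = bold.data.reshape(-1, T).T  # (T, V)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return bold.with_data(resid.T.reshape(bold.data.shape))


def bandpass(
    bold: BoldSeries,
    low_hz: float = BAND_DEFAULT_HZ[0],
    high_hz: float = BAND_DEFAULT_HZ[1],
) -> BoldSeries:
    """Ideal FFT-domain bandpass; retains frequencies in [low, high].

    The DC component is always removed (low > 0 required), matching the
    REST/DPABI frequency-domain masking convention.  Applying the filter
    twice equals applying it once.
    """
    nyquist = 1.0 / (2.0 * bold.tr_s)
    if not (0 <= low_hz < high_hz):
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(f"high_hz {high_hz} >= Nyquist {nyquist:.4f} Hz for TR {bold.tr_s}s")
    T = bold.n_volumes
    freqs = np.fft.rfftfreq(T, d=bold.tr_s)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    keep[0] = False  # DC removed regardless of rounding at the low edge
    spec = np.fft.rfft(bold.data, axis=-1)
    spec[..., ~keep] = 0.0
    return bold.with_data(np.fft.irfft(spec, n=T, axis=-1))


def _rigid_matrix(params: np.ndarray) -> np.ndarray:
    """4x4 rigid-body transform from (tx, ty, tz, rx, ry, rz).

    Translations in mm, rotations in radians about x, y, z, composed in
    the SPM order T @ Rx @ Ry @ Rz.
    """
    tx, ty, tz, rx, ry, rz = params
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    M = np.eye(4)
    M[:3, :3] = Rx @ Ry @ Rz
    M[:3, 3] = (tx, ty, tz)
    return M


def framewise_displacement_jenkinson(
    motion6: np.ndarray, radius_mm: float = FD_RADIUS_DEFAULT_MM
) -> MotionSummary:
    """Jenkinson framewise displacement from a 6-parameter motion trace.

    For each volume-to-volume transition the relative rigid transform
    ``M = M_next @ inv(M_prev)`` is formed and the RMS displacement of a
    solid sphere of the given radius (centred at the origin) under ``M``
    is computed in closed form::

        FD = sqrt( (R^2 / 5) * tr(A^T A) + b^T b ),  A = M[:3,:3] - I, b = M[:3,3]

    The R^2/5 term is E[x x^T] over a uniform solid ball of radius R.
    """
    motion6 = np.asarray(motion6, dtype=np.float64)
    if motion6.ndim != 2 or motion6.shape[1] != 6:
        raise ValueError(f"motion trace must have 6 columns, got shape {motion6.shape}")
    if motion6.shape[0] < 2:
        raise ValueError("need at least 2 time points to compute FD")
    mats = [_rigid_matrix(p) for p in motion6]
    fd = np.empty(len(mats) - 1)
    for i in range(len(mats) - 1):
        M = mats[i + 1] @ np.linalg.inv(mats[i])
        A = M[:3, :3] - np.eye(3)
        b = M[:3, 3]
        fd[i] = np.sqrt(radius_mm**2 / 5.0 * np.trace(A.T @ A) + b @ b)
    return MotionSummary(
        fd_series=fd,
        mean_fd=float(fd.mean()),
        max_abs_translation=float(np.abs(motion6[:, :3]).max()),
        max_abs_rotation=float(np.degrees(np.abs(motion6[:, 3:]).max())),
    )


def apply_exclusion(
    summary: MotionSummary,
    max_mm: float = MAX_TRANSLATION_MM,
    max_deg: float = MAX_ROTATION_DEG,
    max_mean_fd: float = MAX_MEAN_FD_MM,
) -> MotionSummary:
    """Apply the motion exclusion rules; comparisons are strict (>).

    A subject is excluded iff translation exceeds ``max_mm``, rotation
    exceeds ``max_deg``, or mean FD exceeds ``max_mean_fd``; values
    exactly at a threshold are retained.
    """
    if not (max_mm > 0 and max_deg > 0 and max_mean_fd > 0):
        raise ValueError("exclusion thresholds must be positive")
    reasons = []
    if summary.max_abs_translation > max_mm:
        reasons.append("translation")
    if summary.max_abs_rotation > max_deg:
        reasons.append("rotation")
    if summary.mean_fd > max_mean_fd:
        reasons.append("mean_fd")
    summary.excluded = bool(reasons)
    summary.reasons = reasons
    return summary


def preprocess_bold(
    bold: BoldSeries,
    motion6: np.ndarray | None = None,
    wm_signal: np.ndarray | None = None,
    csf_signal: np.ndarray | None = None,
    n_discard: int = N_DISCARD_DEFAULT,
    band_hz: tuple[float, float] = BAND_DEFAULT_HZ,
) -> tuple[BoldSeries, ConfoundMatrix, MotionSummary | None]:
    """Run the fixed chain: discard -> nuisance regression -> bandpass.

    Motion and tissue regressors are truncated to the retained volumes.
    Returns the cleaned series, the confound matrix used, and the motion
    summary (None when no motion trace is given).
    """
    logger.info(
        "preprocess: discard %d -> nuisance regression -> bandpass %.3f-%.3f Hz",
        n_discard, band_hz[0], band_hz[1],
    )
    out = discard_initial_volumes(bold, n_discard)
    T = out.n_volumes

    def _trim(sig):
        return None if sig is None else np.asarray(sig)[n_discard:]

    confounds = build_confounds(
        T, motion6=_trim(motion6), wm_signal=_trim(wm_signal), csf_signal=_trim(csf_signal)
    )
    out = regress_nuisance(out, confounds)
    out = bandpass(out, *band_hz)
    summary = None
    if motion6 is not None:
        summary = apply_exclusion(framewise_displacement_jenkinson(np.asarray(motion6)))
    return out, confounds, summary
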