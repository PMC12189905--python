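"""Synthetic resting-state cohorts with known local-synchronisation structure.

The generator emulates a two-group hearing-loss imaging study: patients
and controls, 4D BOLD series on a common voxel grid, rigid-body motion
traces, and a clinical covariate table whose marginals imitate the
demographics of such a cohort (age ~39 y, education ~12.7 y, hearing-loss
duration ~9 d, PTA ~74 dB HL in patients vs ~13 dB HL in controls, THI
~48 points).

Signal model (shared-source construction).  Every voxel's series is a
weighted copy of one band-limited source ``g(t)`` plus independent
noise::

    y_v(t) = w_v(t) * g(t) + sigma * eps_v(t) + drift + tissue confounds

The weight ``w_v`` is the voxel's local synchronisation level: within a
neighbourhood sharing the source, the pairwise correlation is
``w^2 / (w^2 + sigma^2)``, so expected ReHo rises monotonically with
``w``.  Group effects add (``reho_up``) or subtract (``reho_down``) a
constant from ``w`` inside patient effect regions.  In ``dreho_up``
regions the weight is modulated slowly in time,
``w_v(t) = w_v (1 + m sin(2 pi t TR / period + phi))``, producing
window-to-window variability of ReHo and hence elevated CV.

Clinical links share a latent standard-normal factor between a patient's
regional synchronisation offset and one covariate, inducing a
configurable ROI-covariate correlation that the analysis should recover.

Scanner physics, slice timing, distortion and anatomy are not simulated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd

from .core import BoldSeries, default_affine

logger = logging.getLogger("rehodyn.synthetic")

__all__ = [
    "Region",
    "CohortConfig",
    "SubjectRecord",
    "generate_subject_bold",
    "generate_cohort",
    "write_cohort",
    "null_map_stack",
    "TABLE1_MARGINALS",
]

# Demographic / clinical sampling targets (mean, SD) per group.
TABLE1_MARGINALS = {
    "patient": {
        "age": (38.89, 12.11),
        "education_years": (12.67, 3.20),
        "duration_days": (9.03, 4.27),
        "pta_db": (73.66, 10.38),
        "thi_score": (47.54, 26.37),
    },
    "control": {
        "age": (38.01, 16.52),
        "education_years": (12.74, 2.93),
        "pta_db": (13.25, 5.08),
    },
}
_P_LEFT_SIDE = 56 / 102  # affected-side split among patients
_GMV_MEAN_ML, _GMV_SD_ML = 610.0, 55.0  # gray-matter volume covariate

EFFECT_KINDS = ("reho_up", "reho_down", "dreho_up")


@dataclass(frozen=True)
class Region:
    """Axis-aligned box region with an attached group effect.

    ``magnitude`` is a synchronisation offset for ``reho_up``/``reho_down``
    and a modulation depth (fraction of the weight, in [0, 1]) for
    ``dreho_up``.  Effects apply to the patient group.
    """

    name: str
    kind: str
    center: tuple[int, int, int]
    half_size: tuple[int, int, int]
    magnitude: float

    def __post_init__(self) -> None:
        if self.kind not in EFFECT_KINDS:
            raise ValueError(f"effect kind must be one of {EFFECT_KINDS}, got {self.kind!r}")
        if self.magnitude < 0:
            raise ValueError("effect magnitude must be non-negative")

    def mask(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        lo = np.asarray(self.center) - np.asarray(self.half_size)
        hi = np.asarray(self.center) + np.asarray(self.half_size)
        if (lo < 0).any() or (hi >= np.asarray(grid_shape)).any():
            raise ValueError(
                f"region {self.name!r} (box {lo.tolist()}..{hi.tolist()}) does not fit "
                f"grid {tuple(grid_shape)}"
            )
        m = np.zeros(grid_shape, dtype=bool)
        m[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] = True
        return m


def _default_regions() -> tuple[Region, ...]:
    # one decreased-sync region, one increased, one nonstationary —
    # mirroring the qualitative pattern of the emulated study
    return (
        Region("reho_down_box", "reho_down", (7, 7, 8), (3, 3, 2), 0.20),
        Region("reho_up_box", "reho_up", (16, 16, 8), (3, 3, 2), 0.20),
        Region("dreho_up_box", "dreho_up", (16, 7, 8), (3, 3, 2), 1.0),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults are a desk-scale run: 20 + 20 subjects on a 24 x 24 x 16
    grid of 3 mm voxels, 240 volumes at TR 2 s.  A full-size run
    (102 + 73 subjects) is a configuration change only.
    """

    n_patients: int = 20
    n_controls: int = 20
    grid_shape: tuple[int, int, int] = (24, 24, 16)
    voxel_size_mm: float = 3.0
    tr_s: float = 2.0
    n_volumes: int = 240
    effect_regions: tuple[Region, ...] = field(default_factory=_default_regions)
    sync_base: float = 0.5
    noise_sd: float = 1.0
    # clearly slower than the 100 s analysis window, so the sync modulation
    # is not averaged away within single windows (the amplitude-modulation
    # sidebands stay inside the passband)
    nonstationarity_period_s: float = 200.0
    # between-subject heterogeneity of synchronisation
    subject_sync_sd: float = 0.015
    region_sync_sd: float = 0.03
    # (region name, covariate, target correlation); patient-level latent link
    clinical_effects: tuple[tuple[str, str, float], ...] = (
        ("reho_down_box", "thi_score", 0.39),
        ("dreho_up_box", "duration_days", -0.35),
    )
    clinical_link_sync_sd: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0 or self.n_controls < 0:
            raise ValueError("group sizes must be non-negative")
        if any(s < 9 for s in self.grid_shape):
            raise ValueError("each grid axis must be >= 9 (neighbourhoods + smoothing)")
        if not 0.0 <= self.sync_base <= 1.0:
            raise ValueError("sync_base must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_volumes < 55:
            raise ValueError("n_volumes must cover at least one analysis window plus step")
        # normalise a single (roi, covariate, rho) tuple to a 1-tuple of links
        links = self.clinical_effects
        if links and isinstance(links[0], str):
            object.__setattr__(self, "clinical_effects", (tuple(links),))
        for _, _, rho in self.clinical_effects:
            if not abs(rho) < 1.0:
                raise ValueError("target correlation magnitude must be < 1")
        for reg in self.effect_regions:
            reg.mask(self.grid_shape)  # raises if the grid is too small
        names = [r.name for r in self.effect_regions]
        if len(names) != len(set(names)):
            raise ValueError("region names must be unique")
        for roi, _, _ in self.clinical_effects:
            if roi not in names:
                raise ValueError(f"clinical effect references unknown region {roi!r}")

    @property
    def affine(self) -> np.ndarray:
        return default_affine(self.grid_shape, self.voxel_size_mm)

    def region(self, name: str) -> Region:
        for r in self.effect_regions:
            if r.name == name:
                return r
        raise KeyError(name)

    def with_(self, **kw) -> "CohortConfig":
        return replace(self, **kw)


@dataclass
class SubjectRecord:
    """One simulated subject: data, motion, clinical row, and ground truth."""

    subject_id: str
    group: str
    bold: BoldSeries
    motion6: np.ndarray
    clinical: dict
    truth: dict  # 'sync' (3D), 'modulation' (3D), 'regions' {name: mask}
    wm_signal: np.ndarray
    csf_signal: np.ndarray

    def __post_init__(self) -> None:
        if self.motion6.shape[0] != self.bold.n_volumes:
            raise ValueError("motion trace length must equal n_volumes")
        if self.truth["sync"].shape != self.bold.shape:
            raise ValueError("truth grid must match BOLD grid")


def _bandlimited_series(T: int, tr_s: float, low_hz: float, high_hz: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Unit-SD Gaussian series with support restricted to [low, high] Hz."""
    x = rng.standard_normal(T)
    freqs = np.fft.rfftfreq(T, d=tr_s)
    spec = np.fft.rfft(x)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    keep[0] = False
    spec[~keep] = 0.0
    y = np.fft.irfft(spec, n=T)
    sd = y.std()
    return y / sd if sd > 0 else y


def _motion_trace(T: int, rng: np.random.Generator, spiky: bool = False) -> np.ndarray:
    """Bounded random-walk rigid-body trace (mm, mm, mm, rad, rad, rad).

    ``spiky`` injects large jumps so the exclusion rules have something
    to reject.
    """
    steps = np.empty((T, 6))
    steps[:, :3] = rng.normal(0.0, 0.02, size=(T, 3))
    steps[:, 3:] = rng.normal(0.0, 0.0003, size=(T, 3))
    trace = np.cumsum(steps, axis=0)
    trace -= trace[0]
    np.clip(trace[:, :3], -0.8, 0.8, out=trace[:, :3])
    np.clip(trace[:, 3:], -0.01, 0.01, out=trace[:, 3:])
    if spiky:
        for t in rng.choice(np.arange(T // 4, T), size=3, replace=False):
            trace[t:, :3] += rng.normal(0.0, 1.5, size=3)
    return trace


def _sample_clinical(group: str, rng: np.random.Generator,
                     latents: dict[str, float]) -> dict:
    """One clinical row; linked covariates share their latent factor."""
    marg = TABLE1_MARGINALS[group]
    row: dict = {
        "group": group,
        "age": rng.normal(*marg["age"]),
        "sex": int(rng.random() < 0.5),
        "education_years": rng.normal(*marg["education_years"]),
        "pta_db": rng.normal(*marg["pta_db"]),
        "gmv": rng.normal(_GMV_MEAN_ML, _GMV_SD_ML),
    }
    if group == "patient":
        for name in ("duration_days", "thi_score"):
            mu, sd = TABLE1_MARGINALS["patient"][name]
            if name in latents:
                z, rho = latents[name]
                val = mu + sd * (rho * z + np.sqrt(1 - rho**2) * rng.standard_normal())
            else:
                val = rng.normal(mu, sd)
            row[name] = val
        row["thi_score"] = float(np.clip(row["thi_score"], 0.0, 100.0))
        row["duration_days"] = float(max(row["duration_days"], 0.5))
        row["affected_side"] = "left" if rng.random() < _P_LEFT_SIDE else "right"
    else:
        row["duration_days"] = np.nan
        row["thi_score"] = np.nan
        row["affected_side"] = ""
    return row


def generate_subject_bold(
    config: CohortConfig,
    group: str,
    rng: np.random.Generator,
    subject_id: str = "sub-000",
    sync_offsets: dict[str, float] | None = None,
    spiky_motion: bool = False,
) -> SubjectRecord:
    """Simulate one subject's BOLD series, motion trace, and ground truth.

    ``sync_offsets`` adds per-region synchronisation offsets (used by the
    cohort generator to realise clinical links); the clinical row is
    filled by :func:`generate_cohort` and left empty here.
    """
    if group not in ("patient", "control"):
        raise ValueError(f"group must be 'patient' or 'control', got {group!r}")
    shape, T = config.grid_shape, config.n_volumes
    sync_offsets = sync_offsets or {}

    # per-voxel synchronisation weight and modulation depth
    sync = np.full(shape, config.sync_base)
    modulation = np.zeros(shape)
    for reg in config.effect_regions:
        m = reg.mask(shape)
        offset = rng.normal(0.0, config.region_sync_sd) + sync_offsets.get(reg.name, 0.0)
        if group == "patient":
            if reg.kind == "reho_up":
                offset += reg.magnitude
            elif reg.kind == "reho_down":
                offset -= reg.magnitude
            elif reg.kind == "dreho_up":
                modulation[m] = min(reg.magnitude, 1.0)
        sync[m] += offset
    sync += rng.normal(0.0, config.subject_sync_sd)
    np.clip(sync, 0.0, 1.0, out=sync)

    g = _bandlimited_series(T, config.tr_s, 0.01, 0.08, rng)
    t_s = np.arange(T) * config.tr_s
    phase = rng.uniform(0.0, 2.0 * np.pi)
    mod_t = np.sin(2.0 * np.pi * t_s / config.nonstationarity_period_s + phase)
    weight = sync[..., None] * (1.0 + modulation[..., None] * mod_t)
    data = weight * g

    if config.noise_sd > 0:
        data = data + config.noise_sd * rng.standard_normal((*shape, T))

    # recoverable nuisance structure: slow drift + tissue confounds
    trend = np.linspace(-1.0, 1.0, T)
    wm_sig = _bandlimited_series(T, config.tr_s, 0.0, 0.02, rng)
    csf_sig = _bandlimited_series(T, config.tr_s, 0.0, 0.04, rng)
    data += rng.normal(0.0, 0.3, size=shape)[..., None] * trend
    data += rng.normal(0.0, 0.2, size=shape)[..., None] * wm_sig
    data += rng.normal(0.0, 0.2, size=shape)[..., None] * csf_sig

    motion = _motion_trace(T, rng, spiky=spiky_motion)
    truth = {
        "sync": sync,
        "modulation": modulation,
        "regions": {r.name: r.mask(shape) for r in config.effect_regions},
    }
    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        bold=BoldSeries(data, config.affine, config.tr_s),
        motion6=motion,
        clinical={},
        truth=truth,
        wm_signal=wm_sig,
        csf_signal=csf_sig,
    )


def generate_cohort(
    config: CohortConfig,
    spiky_fraction: float = 0.0,
) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Simulate the full cohort and its clinical table.

    Patients come first, then controls.  Clinical links are realised by
    drawing one latent factor per link for every patient, feeding it
    into both the covariate and the subject's regional synchronisation
    offset (scale ``clinical_link_sync_sd``).  Identical seed and config
    give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    records: list[SubjectRecord] = []
    rows: list[dict] = []
    groups = ["patient"] * config.n_patients + ["control"] * config.n_controls
    for i, group in enumerate(groups):
        sid = f"sub-{i:03d}"
        latents: dict = {}
        offsets: dict[str, float] = {}
        if group == "patient":
            for roi, covariate, rho in config.clinical_effects:
                z = rng.standard_normal()
                latents[covariate] = (z, rho)
                offsets[roi] = offsets.get(roi, 0.0) + config.clinical_link_sync_sd * z
        spiky = bool(spiky_fraction) and rng.random() < spiky_fraction
        rec = generate_subject_bold(
            config, group, rng, subject_id=sid, sync_offsets=offsets, spiky_motion=spiky
        )
        row = _sample_clinical(group, rng, latents)
        row["subject_id"] = sid
        # ground-truth regional sync, for parameter-recovery checks
        for reg in config.effect_regions:
            row[f"truth_sync_{reg.name}"] = float(rec.truth["sync"][rec.truth["regions"][reg.name]].mean())
        rec.clinical = row
        records.append(rec)
        rows.append(row)
    columns = [
        "subject_id", "group", "age", "sex", "education_years", "duration_days",
        "pta_db", "thi_score", "affected_side", "gmv",
    ]
    table = pd.DataFrame(rows)
    extra = [c for c in table.columns if c not in columns]
    table = table[columns + extra]
    logger.info(
        "generated cohort: %d patients, %d controls, grid %s, %d volumes",
        config.n_patients, config.n_controls, config.grid_shape, config.n_volumes,
    )
    return records, table


def write_cohort(records: list[SubjectRecord], table: pd.DataFrame, outdir) -> None:
    """Write BOLD as NIfTI-1, motion as SPM-style rp_<id>.txt, clinical CSV,
    and ground-truth synchronisation / modulation maps as companion NIfTIs."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rec in records:
        rec.bold.save(outdir / f"{rec.subject_id}_bold.nii.gz")
        np.savetxt(outdir / f"rp_{rec.subject_id}.txt", rec.motion6, fmt="%.8f")
        np.savetxt(
            outdir / f"{rec.subject_id}_tissue.txt",
            np.column_stack([rec.wm_signal, rec.csf_signal]),
            fmt="%.8f", header="wm csf",
        )
        affine = rec.bold.affine
        nib.save(
            nib.Nifti1Image(rec.truth["sync"].astype(np.float32), affine),
            outdir / f"{rec.subject_id}_truth_sync.nii.gz",
        )
        nib.save(
            nib.Nifti1Image(rec.truth["modulation"].astype(np.float32), affine),
            outdir / f"{rec.subject_id}_truth_modulation.nii.gz",
        )
    table.to_csv(outdir / "clinical.csv", index=False)


def null_map_stack(
    n_subjects: int,
    grid_shape: tuple[int, int, int],
    fwhm_vox: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stack of independent smooth Gaussian null fields, one per subject.

    This is the exact null of the map-level inference stage: no group
    effect, spatial smoothness matching ``fwhm_vox``.  Fields are
    variance-normalised after smoothing.
    """
    import scipy.ndimage

    sigma = fwhm_vox / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    maps = rng.standard_normal((n_subjects, *grid_shape))
    if sigma > 0:
        for i in range(n_subjects):
            maps[i] = scipy.ndimage.gaussian_filter(maps[i], sigma=sigma, mode="wrap")
    maps /= maps.std(axis=(1, 2, 3), keepdims=True)
    return maps
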