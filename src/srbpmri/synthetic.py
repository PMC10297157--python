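"""Synthetic bi-parametric phantom volumes and whole cohorts.

The generator emulates the statistical structure the spectral analysis
rests on, without any anatomical pretension:

* a latent 3-channel tissue field on the reference (coarsest) grid whose
  normal-prostate voxels follow a multivariate normal with a *nearly
  degenerate* channel covariance -- the three sequences are strongly
  redundant, so one linear combination of channels has almost no
  variance.  That low-clutter direction is what whitening-based detection
  exploits and what makes the raw inverse fragile;
* an ellipsoidal tumor focus whose mean departs from normal tissue along
  the (-ADC, +HBV, -T2) contrast direction, linearly in ISUP grade, plus a
  small per-patient signature offset (candidate ROIs are *selected* for
  looking abnormal, so even benign foci carry a mild offset);
* a handful of aberrant voxels per prostate (artifact spikes) displaced
  by a fixed magnitude in a random channel direction.  They are rare
  enough for volume-minimisation to remove, yet each one is enormous
  relative to the near-degenerate covariance axis, which is exactly why
  they destabilise the unconditioned inverse;
* three channel grids with mismatched in-plane resolution and small
  origin offsets, so that the registration stage has real work to do;
* clinical covariates (PSA, age, prostate volume) drawn *independently*
  of grade from scaled Beta distributions matched to the cohort table's
  ranges -- they should carry no signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CHANNELS, SequenceImage, write_cohort_table, write_mask, write_sequence

logger = logging.getLogger(__name__)

#: Normal-prostate channel covariance (ADC, HBV, T2; arbitrary intensity
#: units).  Eigenvalues (1.6, 0.7, 0.002): the minor axis is nearly
#: degenerate and overlaps the tumor contrast direction by ~0.7;
#: the leading eigvector carries a 0.55 overlap so that variance-filtered
#: scoring retains real signal.
DEFAULT_SIGMA_BG = np.array(
    [
        [0.95703714, -0.42162385, -0.1235908],
        [-0.42162385, 0.92091587, 0.60004138],
        [-0.1235908, 0.60004138, 0.424047],
    ]
)

#: Tumor contrast direction: low ADC, high HBV, low T2 (renders green in
#: the RGB composite).  Unit norm.
DEFAULT_CONTRAST_DIRECTION = np.array([-0.55, 0.65, -0.52]) / np.linalg.norm(
    [-0.55, 0.65, -0.52]
)

#: ISUP grade distribution of the emulated 42-patient cohort.
DEFAULT_GRADE_COUNTS = {0: 17, 1: 14, 2: 5, 3: 3, 4: 1, 5: 2}

DEFAULT_SCANNER_COUNTS = {
    "Skyra": 24,
    "Ingenia": 12,
    "Trio Tim": 1,
    "Aera": 2,
    "Prisma Fit": 3,
}

DEFAULT_TECHNIQUE_COUNTS = {"SysBx": 15, "MRBx": 16, "SysBx+MRBx": 8, "RP": 3}


@dataclass
class PhantomSpec:
    """Parameters of one synthetic bi-parametric exam.

    Geometry: the reference (ADC) grid doubles as the latent tissue grid;
    HBV and T2 are sampled from the latent field on finer in-plane grids
    with their own origin offsets (mm).  Offsets default to integer
    multiples of the reference spacing, which the header-driven
    registration undoes exactly.
    """

    ref_shape: tuple[int, int, int] = (14, 56, 56)
    ref_spacing: tuple[float, float, float] = (3.6, 2.4, 2.4)
    channel_spacing: dict = field(
        default_factory=lambda: {
            "ADC": (3.6, 2.4, 2.4),
            "HBV": (3.6, 1.2, 1.2),
            "T2": (3.6, 0.8, 0.8),
        }
    )
    channel_offset_mm: dict = field(
        default_factory=lambda: {
            "ADC": (0.0, 0.0, 0.0),
            "HBV": (0.0, 4.8, -2.4),
            "T2": (3.6, -2.4, 7.2),
        }
    )
    mu_bg: np.ndarray = field(default_factory=lambda: np.array([10.0, 10.0, 10.0]))
    sigma_bg: np.ndarray = field(default_factory=lambda: DEFAULT_SIGMA_BG.copy())
    contrast_direction: np.ndarray = field(
        default_factory=lambda: DEFAULT_CONTRAST_DIRECTION.copy()
    )
    contrast_scale: float = 0.35
    f_out: float = 0.0011
    outlier_scale: tuple[float, float] = (8.0, 16.0)
    roi_jitter_sd: float = 0.05
    prostate_semiaxes: tuple[float, float, float] = (4.5, 11.0, 13.0)
    prostate_scale_range: tuple[float, float] = (0.90, 1.05)
    tumor_semiaxes: tuple[float, float, float] = (1.7, 5.5, 5.5)
    seed: int = 0

    def __post_init__(self) -> None:
        self.mu_bg = np.asarray(self.mu_bg, dtype=float)
        self.sigma_bg = np.asarray(self.sigma_bg, dtype=float)
        self.contrast_direction = np.asarray(self.contrast_direction, dtype=float)
        nrm = np.linalg.norm(self.contrast_direction)
        if abs(nrm - 1.0) > 1e-9:
            self.contrast_direction = self.contrast_direction / nrm
        if not np.allclose(self.sigma_bg, self.sigma_bg.T, atol=1e-10):
            raise ValueError("sigma_bg must be symmetric")
        if np.linalg.eigvalsh(self.sigma_bg).min() <= 0:
            raise ValueError("sigma_bg must be positive definite")
        if not 0.0 <= self.f_out < 0.5:
            raise ValueError("f_out must lie in [0, 0.5)")
        for ch in CHANNELS:
            if any(s <= 0 for s in self.channel_spacing[ch]):
                raise ValueError(f"non-positive spacing for channel {ch}")

    @property
    def outlier_magnitude_range(self) -> tuple[float, float]:
        sc = self.outlier_scale
        if np.isscalar(sc):
            return float(sc), float(sc)
        return float(sc[0]), float(sc[1])

    @property
    def sigma_mean_sd(self) -> float:
        """Root-mean channel variance, the unit for outlier magnitudes."""
        return float(np.sqrt(np.mean(np.diag(self.sigma_bg))))

    def channel_shape(self, ch: str) -> tuple[int, int, int]:
        """Grid shape covering the reference FOV at the channel's spacing."""
        fov = np.array(self.ref_shape) * np.array(self.ref_spacing)
        sp = np.array(self.channel_spacing[ch])
        return tuple(int(round(f / s)) for f, s in zip(fov, sp))


@dataclass
class CohortSpec:
    """Composition of a synthetic patient cohort."""

    n: int = 42
    grade_counts: dict = field(default_factory=lambda: dict(DEFAULT_GRADE_COUNTS))
    scanner_counts: dict = field(default_factory=lambda: dict(DEFAULT_SCANNER_COUNTS))
    technique_counts: dict = field(default_factory=lambda: dict(DEFAULT_TECHNIQUE_COUNTS))
    age_range: tuple[float, float] = (50.0, 78.0)
    age_beta: tuple[float, float] = (2.7, 2.3)
    psa_range: tuple[float, float] = (1.5, 81.95)
    psa_beta: tuple[float, float] = (1.2, 6.0)
    volume_range: tuple[float, float] = (19.0, 192.0)
    volume_beta: tuple[float, float] = (1.5, 4.5)
    scanner_outlier_multiplier: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.grade_counts.values()) != self.n:
            raise ValueError(
                f"grade counts sum to {sum(self.grade_counts.values())}, expected n={self.n}"
            )
        for rng_ in (self.age_range, self.psa_range, self.volume_range):
            if rng_[0] <= 0 or rng_[1] <= rng_[0]:
                raise ValueError(f"invalid covariate range {rng_}")


def _ellipsoid_mask(shape, center, semiaxes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape)
    for g, c, a in zip(grids, center, semiaxes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def _sample_latent(latent: np.ndarray, spec: PhantomSpec, ch: str) -> np.ndarray:
    """Sample one channel volume from the latent field on its own grid.

    Bilinear in-plane, nearest-neighbour axially, edge clamped -- the
    mirror image of what the registration stage undoes.
    """
    shape = spec.channel_shape(ch)
    sp = spec.channel_spacing[ch]
    off = spec.channel_offset_mm[ch]
    ref_sp = spec.ref_spacing
    nz, ny, nx = latent.shape[:3]

    kz = np.clip(
        np.round((np.arange(shape[0]) * sp[0] + off[0]) / ref_sp[0]).astype(int), 0, nz - 1
    )
    yy = np.clip((np.arange(shape[1]) * sp[1] + off[1]) / ref_sp[1], 0, ny - 1)
    xx = np.clip((np.arange(shape[2]) * sp[2] + off[2]) / ref_sp[2], 0, nx - 1)
    y0 = np.floor(yy).astype(int)
    y1 = np.minimum(y0 + 1, ny - 1)
    fy = (yy - y0)[:, None, None]
    x0 = np.floor(xx).astype(int)
    x1 = np.minimum(x0 + 1, nx - 1)
    fx = (xx - x0)[None, :, None]

    out = np.empty(shape)
    ci = CHANNELS.index(ch)
    for k, z in enumerate(kz):
        sl = latent[z, :, :, ci]
        top = sl[np.ix_(y0, x0)][..., None] * (1 - fx) + sl[np.ix_(y0, x1)][..., None] * fx
        bot = sl[np.ix_(y1, x0)][..., None] * (1 - fx) + sl[np.ix_(y1, x1)][..., None] * fx
        out[k] = (top * (1 - fy) + bot * fy)[..., 0]
    return out


def generate_phantom(
    spec: PhantomSpec,
    grade: int,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, SequenceImage], np.ndarray, np.ndarray]:
    """One synthetic exam: three channel volumes plus masks.

    Returns ``(sequences, prostate_mask, tumor_mask)`` with the masks on
    the reference grid.  Normal prostate voxels are multivariate normal
    ``(mu_bg, sigma_bg)``; tumor voxels add ``grade * c * d`` plus the
    per-patient ROI offset; ``round(f_out * n_prostate)`` normal voxels
    are replaced by artifact spikes of magnitude ``outlier_scale`` (in
    units of the mean channel SD) in random directions.
    """
    if not 0 <= int(grade) <= 5:
        raise ValueError(f"grade must be in 0..5, got {grade}")
    grade = int(grade)
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    shape = spec.ref_shape
    L = np.linalg.cholesky(spec.sigma_bg)

    # anatomy on the reference grid
    scale = rng.uniform(*spec.prostate_scale_range)
    center = (np.array(shape) - 1) / 2.0
    semi = np.array(spec.prostate_semiaxes) * np.array([1.0, scale, scale])
    prostate = _ellipsoid_mask(shape, center, semi)
    u = rng.standard_normal(3)
    u /= np.linalg.norm(u)
    t_semi = np.array(spec.tumor_semiaxes)
    t_center = center + 0.40 * (semi - t_semi) * u
    tumor = _ellipsoid_mask(shape, t_center, t_semi) & prostate
    if tumor.sum() == 0:
        raise ValueError("tumor mask is empty")

    # latent 3-channel field
    latent = spec.mu_bg * 0.8 + rng.standard_normal(shape + (3,)) @ L.T
    latent[prostate] = spec.mu_bg + rng.standard_normal((int(prostate.sum()), 3)) @ L.T
    delta = rng.standard_normal(3) * spec.roi_jitter_sd * spec.sigma_mean_sd
    contrast = grade * spec.contrast_scale * spec.contrast_direction + delta
    latent[tumor] += contrast

    # artifact spikes among normal-prostate voxels
    normal_idx = np.argwhere(prostate & ~tumor)
    n_out = int(round(spec.f_out * len(normal_idx)))
    if n_out > 0:
        pick = normal_idx[rng.choice(len(normal_idx), size=n_out, replace=False)]
        dirs = rng.standard_normal((n_out, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        lo, hi = spec.outlier_magnitude_range
        magnitude = rng.uniform(lo, hi)  # artifact severity varies by exam
        latent[tuple(pick.T)] = spec.mu_bg + dirs * magnitude * spec.sigma_mean_sd

    seqs = {
        ch: SequenceImage(
            _sample_latent(latent, spec, ch),
            spec.channel_spacing[ch],
            spec.channel_offset_mm[ch],
            ch,
        )
        for ch in CHANNELS
    }
    return seqs, prostate, tumor


def _counts_for_n(counts: dict, n: int) -> list:
    """Scale a count table to n labels (largest-remainder rounding)."""
    total = sum(counts.values())
    raw = {k: v * n / total for k, v in counts.items()}
    base = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(base.values())
    for k in sorted(raw, key=lambda k: raw[k] - base[k], reverse=True)[:short]:
        base[k] += 1
    out = []
    for k, v in base.items():
        out.extend([k] * v)
    return out


def generate_cohort(
    cspec: CohortSpec,
    pspec: PhantomSpec,
    out_dir: str | Path | None = None,
):
    """A full synthetic cohort, optionally written to disk.

    Returns ``(cohort_table, patients)`` where ``patients`` maps patient
    id to ``(sequences, prostate_mask, tumor_mask)``.  When ``out_dir``
    is given, each patient gets a directory with the three ``.mha``
    volumes plus a single label mask (0 background / 1 prostate /
    2 tumor), and ``cohort.csv`` is written at the top level.
    Everything is deterministic given the cohort seed.
    """
    rng = np.random.default_rng(cspec.seed)

    grades = []
    for g in sorted(cspec.grade_counts):
        grades.extend([g] * cspec.grade_counts[g])
    grades = np.array(grades)
    rng.shuffle(grades)
    scanners = _counts_for_n(cspec.scanner_counts, cspec.n)
    rng.shuffle(scanners)
    techniques = _counts_for_n(cspec.technique_counts, cspec.n)
    rng.shuffle(techniques)

    def beta_draw(lo, hi, ab):
        return lo + (hi - lo) * rng.beta(*ab)

    rows = []
    patients = {}
    for i in range(cspec.n):
        pid = f"pt{i + 1:03d}"
        rows.append(
            {
                "patient_id": pid,
                "isup": int(grades[i]),
                "psa_ng_ml": round(beta_draw(*cspec.psa_range, cspec.psa_beta), 2),
                "age_years": round(beta_draw(*cspec.age_range, cspec.age_beta), 1),
                "prostate_vol_cc": round(
                    beta_draw(*cspec.volume_range, cspec.volume_beta), 1
                ),
                "scanner": scanners[i],
                "technique": techniques[i],
            }
        )
        mult = cspec.scanner_outlier_multiplier.get(scanners[i], 1.0)
        spec_i = replace(pspec, f_out=pspec.f_out * mult) if mult != 1.0 else pspec
        child = np.random.default_rng(rng.integers(0, 2**31 - 1))
        patients[pid] = generate_phantom(spec_i, int(grades[i]), child)

    table = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_cohort_table(table, out_dir / "cohort.csv")
        for pid, (seqs, prost, tumor) in patients.items():
            pdir = out_dir / pid
            for ch, seq in seqs.items():
                write_sequence(seq, pdir / f"{ch.lower()}.mha")
            labels = prost.astype(np.uint8)
            labels[tumor] = 2
            write_mask(labels, pspec.ref_spacing, (0.0, 0.0, 0.0), pdir / "mask.mha")
    return table, patients
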