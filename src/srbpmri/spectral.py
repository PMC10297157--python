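"""Normal-prostate statistics, tumor signatures, and the two scores.

The tumor signature is the mean channel vector over a radiologist-style
ROI; the normal-prostate background is summarised by its mean, per-channel
standard deviations and channel covariance.  Two scalar scores compare
signature and background:

* the z-score, a per-channel standardised difference combined across
  channels by the Euclidean norm -- it ignores inter-channel correlation;
* the signal-to-clutter ratio (SCR), the squared Mahalanobis distance of
  the signature from the background under a (possibly conditioned)
  covariance -- whitening decorrelates the sequences, so correlated
  channels are not double counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .registration import Hypercube

MIN_NORMAL_VOXELS = 30

#: The seven scoring variants, keyed by how the covariance is conditioned.
VARIANTS = (
    "unprocessed",
    "regularized",
    "modified_regularized",
    "pc1_removed",
    "pc2_removed",
    "evm",
    "zscore",
)


@dataclass
class NormalStats:
    """Second-order statistics of normal prostate tissue."""

    mean: np.ndarray          # (3,)
    std: np.ndarray           # (3,)
    cov: np.ndarray           # (3, 3), unbiased (n-1) denominator
    n_voxels: int

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.mean.shape != (3,) or self.std.shape != (3,) or self.cov.shape != (3, 3):
            raise ValueError("NormalStats needs 3-channel mean/std and 3x3 covariance")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        if self.n_voxels < MIN_NORMAL_VOXELS:
            raise ValueError(
                f"too few normal voxels: {self.n_voxels} < {MIN_NORMAL_VOXELS}"
            )


@dataclass
class TumorSignature:
    """Mean channel vector over a candidate tumor ROI."""

    mean: np.ndarray          # (3,)
    n_voxels: int
    label: str = "roi"
    primary: bool = True

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        if self.mean.shape != (3,):
            raise ValueError("signature must be a 3-vector")
        if self.n_voxels < 1:
            raise ValueError("signature needs at least one voxel")
        if not np.all(np.isfinite(self.mean)):
            raise ValueError("signature must be finite")


def compute_normal_stats(cube: Hypercube) -> NormalStats:
    """Background statistics over prostate voxels, tumor ROI excluded."""
    vox = cube.normal_voxels()
    return normal_stats_from_voxels(vox)


def normal_stats_from_voxels(vox: np.ndarray) -> NormalStats:
    vox = np.asarray(vox, dtype=float)
    if vox.ndim != 2 or vox.shape[1] != 3:
        raise ValueError("expected voxel array of shape (n, 3)")
    n = len(vox)
    if n < MIN_NORMAL_VOXELS:
        raise ValueError(f"too few normal voxels: {n} < {MIN_NORMAL_VOXELS}")
    mean = vox.mean(axis=0)
    cov = np.cov(vox.T, ddof=1)
    std = np.sqrt(np.diag(cov))
    if np.any(std < 1e-12):
        raise ValueError("zero variance in at least one channel")
    return NormalStats(mean=mean, std=std, cov=cov, n_voxels=n)


def extract_signature(
    cube: Hypercube, rois: np.ndarray | dict[str, np.ndarray] | None = None
) -> list[TumorSignature]:
    """Channel-wise mean over each candidate ROI.

    With several candidates the largest-area one is flagged primary, the
    convention being that the most prominent focus carries the score.
    ``rois`` defaults to the cube's tumor mask.
    """
    if rois is None:
        rois = {"tumor": cube.tumor_mask}
    elif isinstance(rois, np.ndarray):
        rois = {"roi": rois}
    sigs: list[TumorSignature] = []
    for label, mask in rois.items():
        vox = cube.voxel_vectors(np.asarray(mask))
        if len(vox) == 0:
            raise ValueError(f"empty ROI {label!r}")
        sigs.append(
            TumorSignature(mean=vox.mean(axis=0), n_voxels=len(vox), label=label, primary=False)
        )
    largest = max(range(len(sigs)), key=lambda i: sigs[i].n_voxels)
    sigs[largest].primary = True
    return sigs


def primary_signature(cube: Hypercube, rois=None) -> TumorSignature:
    sigs = extract_signature(cube, rois)
    return next(s for s in sigs if s.primary)


def z_score(sig: TumorSignature, stats: NormalStats, combine: str = "norm") -> float:
    """Per-channel standardised contrast combined across channels.

    ``combine='norm'`` (default) takes the Euclidean norm of the
    per-channel z values; ``combine='mean_abs'`` averages their absolute
    values instead.
    """
    if np.any(stats.std < 1e-12):
        raise ValueError("zero standard deviation")
    z = (sig.mean - stats.mean) / stats.std
    if combine == "norm":
        return float(np.sqrt(np.sum(z * z)))
    if combine == "mean_abs":
        return float(np.mean(np.abs(z)))
    raise ValueError(f"unknown combine rule {combine!r}")


def scr(
    sig: TumorSignature,
    stats: NormalStats,
    inv: np.ndarray | None = None,
    squared: bool = True,
) -> float:
    """Signal-to-clutter ratio of the signature against the background.

    ``inv`` is the (possibly conditioned) inverse of the background
    covariance; by default the plain inverse is used.  The score is the
    squared Mahalanobis distance ``(s - mu)^T inv (s - mu)``; with
    ``squared=False`` its square root is returned.  Both variants are
    monotone in each other, so every ordering property is shared.
    """
    if inv is None:
        inv = np.linalg.inv(stats.cov)
    inv = np.asarray(inv, dtype=float)
    if inv.shape != (3, 3):
        raise ValueError(f"conditioned inverse must be 3x3, got {inv.shape}")
    r = sig.mean - stats.mean
    val = float(r @ inv @ r)
    if val < 0 and val > -1e-10:
        val = 0.0
    return val if squared else float(np.sqrt(val))
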