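"""Voxel-level spatial registration of the three channel volumes.

The three sequences arrive on their own grids (different in-plane
resolution, small origin offsets).  Following the usual workflow for
multichannel spectral analysis they are

1. resampled in-plane to the grid of the *reference* channel (the one with
   the coarsest in-plane spacing; bilinear interpolation per axial slice),
2. translated by the integer voxel shift implied by the header origins
   (axial slices are *selected* by nearest world z-position, not
   interpolated),
3. cropped to the common field of view, and stacked into a
   :class:`Hypercube` in which every voxel is a 3-vector (ADC, HBV, T2).

Axial slices can additionally be unrolled side by side into a 2-D mosaic,
and an RGB composite (R=ADC, G=HBV, B=T2) renders tumors green
(low ADC, high HBV, low T2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import CHANNELS, SequenceImage

logger = logging.getLogger(__name__)


@dataclass
class Hypercube:
    """Spatially registered stack of the three channels plus masks.

    ``channels`` has shape ``(3, slices, rows, cols)`` in the fixed order
    (ADC, HBV, T2); ``valid`` flags voxels where all three channels carry
    interpolated source data; the masks live on the same grid.
    """

    channels: np.ndarray
    valid: np.ndarray
    prostate_mask: np.ndarray
    tumor_mask: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    channel_order: tuple[str, str, str] = CHANNELS

    def __post_init__(self) -> None:
        if self.channels.shape[0] != 3:
            raise ValueError("hypercube needs exactly 3 channels")
        grid = self.channels.shape[1:]
        for name in ("valid", "prostate_mask", "tumor_mask"):
            if getattr(self, name).shape != grid:
                raise ValueError(f"{name} shape {getattr(self, name).shape} != grid {grid}")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.channels.shape[1:]

    def voxel_vectors(self, mask: np.ndarray) -> np.ndarray:
        """Channel vectors ``(n, 3)`` for the valid voxels selected by ``mask``."""
        sel = mask.astype(bool) & self.valid
        return self.channels[:, sel].T

    def normal_voxels(self) -> np.ndarray:
        """Prostate voxels with the tumor ROI excluded."""
        return self.voxel_vectors(self.prostate_mask.astype(bool) & ~self.tumor_mask.astype(bool))

    def tumor_voxels(self) -> np.ndarray:
        return self.voxel_vectors(self.tumor_mask.astype(bool))


@dataclass
class MosaicImage:
    """All axial slices of each channel placed side by side.

    ``mosaic`` has shape ``(3, rows, n_slices * cols)``; the slice-to-column
    mapping is invertible via :meth:`to_mosaic` / :meth:`to_volume`.
    """

    mosaic: np.ndarray
    n_slices: int
    slice_width: int

    def to_mosaic(self, s: int, r: int, c: int) -> tuple[int, int]:
        if not (0 <= s < self.n_slices and 0 <= c < self.slice_width):
            raise IndexError("voxel index outside mosaic")
        return r, s * self.slice_width + c

    def to_volume(self, r: int, col: int) -> tuple[int, int, int]:
        s, c = divmod(col, self.slice_width)
        if not 0 <= s < self.n_slices:
            raise IndexError("mosaic column out of range")
        return s, r, c


def select_reference(seqs: dict[str, SequenceImage]) -> str:
    """Channel with the coarsest in-plane spacing; ties break ADC > HBV > T2."""
    best = None
    for name in CHANNELS:
        seq = seqs[name]
        coarse = max(seq.spacing[1], seq.spacing[2])
        if best is None or coarse > best[0] + 1e-12:
            best = (coarse, name)
    return best[1]


def resample_to_reference(seq: SequenceImage, reference: SequenceImage) -> tuple[SequenceImage, np.ndarray]:
    """Resample in-plane onto the reference grid (bilinear, per axial slice).

    The output keeps the source origin and slice positions -- translation
    is a separate, integer-voxel step (:func:`align_by_offsets`).  Returns
    the resampled image and a validity mask flagging voxels that fall
    inside the source extent; voxels outside are set to 0.
    """
    n_s = seq.array.shape[0]
    n_r, n_c = reference.array.shape[1:]
    sp_r, sp_c = reference.spacing[1], reference.spacing[2]
    # continuous source indices of the output in-plane sample points
    rr = np.arange(n_r) * sp_r / seq.spacing[1]
    cc = np.arange(n_c) * sp_c / seq.spacing[2]
    valid_r = rr <= seq.array.shape[1] - 1 + 1e-9
    valid_c = cc <= seq.array.shape[2] - 1 + 1e-9
    out = np.zeros((n_s, n_r, n_c))
    r0 = np.clip(np.floor(rr).astype(int), 0, seq.array.shape[1] - 1)
    r1 = np.clip(r0 + 1, 0, seq.array.shape[1] - 1)
    fr = np.clip(rr - r0, 0.0, 1.0)
    c0 = np.clip(np.floor(cc).astype(int), 0, seq.array.shape[2] - 1)
    c1 = np.clip(c0 + 1, 0, seq.array.shape[2] - 1)
    fc = np.clip(cc - c0, 0.0, 1.0)
    for s in range(n_s):
        sl = seq.array[s]
        top = sl[np.ix_(r0, c0)] * (1 - fc) + sl[np.ix_(r0, c1)] * fc
        bot = sl[np.ix_(r1, c0)] * (1 - fc) + sl[np.ix_(r1, c1)] * fc
        out[s] = top * (1 - fr[:, None]) + bot * fr[:, None]
    valid = np.zeros_like(out, dtype=bool)
    valid[:, valid_r[:, None] & valid_c[None, :]] = True
    out[~valid] = 0.0
    res = SequenceImage(
        out,
        (seq.spacing[0], sp_r, sp_c),
        seq.origin,
        seq.channel,
    )
    if not valid.any():
        raise ValueError("no spatial overlap between sequence and reference")
    return res, valid


def align_by_offsets(
    seq: SequenceImage,
    valid: np.ndarray,
    reference: SequenceImage,
    extra_shift: tuple[int, int] = (0, 0),
) -> tuple[SequenceImage, np.ndarray]:
    """Translate onto the reference grid using the header origins.

    The in-plane shift is ``round((origin_seq - origin_ref) / spacing_ref)``
    voxels (the header offsets amount to "a few pixels"); axial slices are
    selected by nearest world z-position.  ``extra_shift`` is an optional
    manual in-plane adjustment in voxels ``(rows, cols)``, mirroring the
    small visual-inspection translations applied to T2 in practice.
    """
    sp = (reference.spacing[1], reference.spacing[2])
    dy = int(round((seq.origin[1] - reference.origin[1]) / sp[0])) + int(extra_shift[0])
    dx = int(round((seq.origin[2] - reference.origin[2]) / sp[1])) + int(extra_shift[1])

    n_s = reference.array.shape[0]
    ref_z = np.array([reference.slice_z(k) for k in range(n_s)])
    seq_z = np.array([seq.slice_z(k) for k in range(seq.array.shape[0])])
    half = max(reference.spacing[0], seq.spacing[0]) / 2 + 1e-9
    if seq_z.max() < ref_z.min() - half or seq_z.min() > ref_z.max() + half:
        raise ValueError("axial ranges are disjoint")

    out = np.zeros((n_s,) + seq.array.shape[1:])
    out_valid = np.zeros_like(out, dtype=bool)
    for k in range(n_s):
        j = int(np.argmin(np.abs(seq_z - ref_z[k])))
        if abs(seq_z[j] - ref_z[k]) > half:
            continue
        out[k] = seq.array[j]
        out_valid[k] = valid[j]

    shifted = np.zeros_like(out)
    shifted_valid = np.zeros_like(out_valid)
    n_r, n_c = out.shape[1:]
    # content at source voxel j appears at output voxel j + shift
    r_src = slice(max(0, -dy), min(n_r, n_r - dy))
    r_dst = slice(max(0, dy), min(n_r, n_r + dy))
    c_src = slice(max(0, -dx), min(n_c, n_c - dx))
    c_dst = slice(max(0, dx), min(n_c, n_c + dx))
    if r_src.stop > r_src.start and c_src.stop > c_src.start:
        shifted[:, r_dst, c_dst] = out[:, r_src, c_src]
        shifted_valid[:, r_dst, c_dst] = out_valid[:, r_src, c_src]
    aligned = SequenceImage(shifted, reference.spacing, reference.origin, seq.channel)
    return aligned, shifted_valid


def crop_and_stack(
    seqs: dict[str, SequenceImage],
    valids: dict[str, np.ndarray],
    prostate_mask: np.ndarray,
    tumor_mask: np.ndarray,
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float],
) -> Hypercube:
    """Crop to the common field of view and stack the channels.

    A voxel survives only if all three channels carry valid data there;
    the cube is cropped to the bounding box of that intersection.
    """
    valid = np.logical_and.reduce([valids[c] for c in CHANNELS])
    if not valid.any():
        raise ValueError("empty intersection field of view")
    s_idx, r_idx, c_idx = np.nonzero(valid)
    box = (
        slice(s_idx.min(), s_idx.max() + 1),
        slice(r_idx.min(), r_idx.max() + 1),
        slice(c_idx.min(), c_idx.max() + 1),
    )
    channels = np.stack([seqs[c].array[box] for c in CHANNELS])
    new_origin = (
        origin[0] + box[0].start * spacing[0],
        origin[1] + box[1].start * spacing[1],
        origin[2] + box[2].start * spacing[2],
    )
    return Hypercube(
        channels=channels,
        valid=valid[box],
        prostate_mask=prostate_mask[box].astype(bool),
        tumor_mask=tumor_mask[box].astype(bool),
        spacing=spacing,
        origin=new_origin,
    )


def build_hypercube(
    seqs: dict[str, SequenceImage],
    prostate_mask: np.ndarray,
    tumor_mask: np.ndarray,
    extra_shifts: dict[str, tuple[int, int]] | None = None,
) -> Hypercube:
    """Full registration pipeline: resample, align, crop, stack.

    Masks are expected on the reference-channel grid.
    """
    extra_shifts = extra_shifts or {}
    ref_name = select_reference(seqs)
    reference = seqs[ref_name]
    aligned: dict[str, SequenceImage] = {}
    valids: dict[str, np.ndarray] = {}
    for name in CHANNELS:
        res, valid = resample_to_reference(seqs[name], reference)
        res, valid = align_by_offsets(
            res, valid, reference, extra_shifts.get(name, (0, 0))
        )
        aligned[name] = res
        valids[name] = valid
    if prostate_mask.shape != reference.array.shape:
        raise ValueError(
            f"masks must be on the reference grid {reference.array.shape}, "
            f"got {prostate_mask.shape}"
        )
    return crop_and_stack(
        aligned, valids, prostate_mask, tumor_mask, reference.spacing, reference.origin
    )


def stitch_mosaic(cube: Hypercube) -> MosaicImage:
    """Concatenate the axial slices left-to-right for each channel."""
    n_s, n_r, n_c = cube.grid_shape
    if n_s == 0:
        raise ValueError("empty hypercube")
    mosaic = np.concatenate([cube.channels[:, s] for s in range(n_s)], axis=2)
    return MosaicImage(mosaic=mosaic, n_slices=n_s, slice_width=n_c)


def color_composite(cube: Hypercube) -> np.ndarray:
    """RGB composite with R=ADC, G=HBV, B=T2.

    Each channel is min-max normalised over the prostate mask, then clipped
    to [0, 1] globally; tumors (low ADC, high HBV, low T2) render green.
    Returns an array of shape ``(slices, rows, cols, 3)``.
    """
    sel = cube.prostate_mask & cube.valid
    if not sel.any():
        raise ValueError("empty prostate mask")
    rgb = np.zeros(cube.grid_shape + (3,))
    for i in range(3):
        vals = cube.channels[i, sel]
        lo, hi = vals.min(), vals.max()
        if hi - lo < 1e-12:
            logger.warning(
                "channel %s has zero dynamic range; set to 0 in composite",
                cube.channel_order[i],
            )
            continue
        rgb[..., i] = np.clip((cube.channels[i] - lo) / (hi - lo), 0.0, 1.0)
    return rgb


def detection_centroid(
    volume: np.ndarray,
    mask: np.ndarray,
    sign: float,
    nsigma: float = 3.0,
) -> np.ndarray:
    """Centroid of the voxels deviating by more than ``nsigma`` robust SDs.

    Used to check registration fidelity: on a high-contrast phantom the
    per-channel detection blob should sit where the tumor mask sits.
    ``sign`` states the expected contrast direction (+1 hyper-, -1
    hypo-intense).  Deviations are measured from the masked median in units
    of the median absolute deviation (scaled to Gaussian sigma).
    """
    vals = volume[mask]
    med = np.median(vals)
    mad = np.median(np.abs(vals - med)) * 1.4826
    if mad <= 0:
        raise ValueError("degenerate intensity distribution")
    score = sign * (volume - med) / mad
    hot = (score > nsigma) & mask
    if not hot.any():
        raise ValueError("no voxels above detection threshold")
    idx = np.argwhere(hot)
    w = score[hot]
    return (idx * w[:, None]).sum(0) / w.sum()


def mask_centroid(mask: np.ndarray) -> np.ndarray:
    idx = np.argwhere(mask.astype(bool))
    if len(idx) == 0:
        raise ValueError("empty mask")
    return idx.mean(0)
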