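"""RGB rendering of DSEG segmentations.

Each segment gets one colour from the rank (1 = lowest, 16 = highest) of
its within-segment median T2, p and q: T2 ranks drive the red channel,
p ranks the green channel and q ranks the blue channel, each scaled to a
byte as round(255 * rank / 16).  White-matter damage therefore shows as
grey-ish (high p rank, mid q rank), CSF as bright green, healthy white
matter as strongly blue.  The rank-to-byte scaling is a single fixed
rendering convention; any monotone mapping preserves the semantics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dseg_core import K_SEGMENTS

logger = logging.getLogger(__name__)


@dataclass
class SegmentRanks:
    """Per-segment ranks 1..k of the median T2, p and q.

    Each channel's ranks are a permutation of 1..k; median ties break by
    segment label order (lower label gets the lower rank).
    """

    t2: np.ndarray
    p: np.ndarray
    q: np.ndarray
    has_t2: bool = True

    def __post_init__(self) -> None:
        for name in ("t2", "p", "q"):
            r = np.asarray(getattr(self, name), dtype=np.int64)
            setattr(self, name, r)
            if sorted(r.tolist()) != list(range(1, r.size + 1)):
                raise ValueError(f"{name} ranks are not a permutation of 1..{r.size}")


def _rank_medians(medians: np.ndarray) -> np.ndarray:
    """Ranks 1..k, ties broken by segment label order (stable sort)."""
    order = np.argsort(medians, kind="stable")
    ranks = np.empty(medians.size, dtype=np.int64)
    ranks[order] = np.arange(1, medians.size + 1)
    return ranks


def rank_segments(
    seg: np.ndarray,
    p_map: np.ndarray,
    q_map: np.ndarray,
    t2_map: np.ndarray | None = None,
    k: int = K_SEGMENTS,
) -> SegmentRanks:
    """Rank within-segment medians of T2, p and q from 1 (lowest) to k.

    Without a T2 map the red channel repeats the p ranks and the result
    is flagged ``has_t2=False``.  An empty segment raises, naming it.
    """
    seg = np.asarray(seg)
    p_map = np.asarray(p_map, dtype=np.float64)
    q_map = np.asarray(q_map, dtype=np.float64)
    if seg.shape != p_map.shape or seg.shape != q_map.shape:
        raise ValueError("segmentation and maps disagree on grid shape")

    med_p = np.empty(k)
    med_q = np.empty(k)
    med_t2 = np.empty(k) if t2_map is not None else None
    for lab in range(1, k + 1):
        sel = seg == lab
        if not sel.any():
            raise ValueError(f"segment {lab} is empty")
        med_p[lab - 1] = np.median(p_map[sel])
        med_q[lab - 1] = np.median(q_map[sel])
        if med_t2 is not None:
            med_t2[lab - 1] = np.median(np.asarray(t2_map, dtype=np.float64)[sel])

    rp, rq = _rank_medians(med_p), _rank_medians(med_q)
    if med_t2 is None:
        logger.info("no T2 map supplied; red channel repeats the p ranks")
        return SegmentRanks(t2=rp.copy(), p=rp, q=rq, has_t2=False)
    return SegmentRanks(t2=_rank_medians(med_t2), p=rp, q=rq, has_t2=True)


def render_colormap(seg: np.ndarray, ranks: SegmentRanks, k: int = K_SEGMENTS) -> np.ndarray:
    """RGB byte volume: voxel of segment i gets round(255 * rank_i / k).

    Background (label 0) is black.  Returns an array of shape
    ``seg.shape + (3,)`` with dtype uint8.
    """
    seg = np.asarray(seg)
    lut = np.zeros((k + 1, 3), dtype=np.uint8)
    for lab in range(1, k + 1):
        lut[lab] = [
            int(round(255 * ranks.t2[lab - 1] / k)),
            int(round(255 * ranks.p[lab - 1] / k)),
            int(round(255 * ranks.q[lab - 1] / k)),
        ]
    return lut[seg.astype(np.int64)]


def save_rgb_nifti(path, rgb: np.ndarray, affine: np.ndarray | None = None) -> None:
    """Write an RGB volume as a 3-volume 4D uint8 NIfTI."""
    import nibabel as nib

    nib.save(nib.Nifti1Image(rgb.astype(np.uint8),
                             np.eye(4) if affine is None else affine), str(path))


def save_slice_png(path, rgb: np.ndarray, axis: int = 2, index: int | None = None) -> None:
    """Export one axial (or other-axis) slice of an RGB volume as PNG."""
    from PIL import Image

    if index is None:
        index = rgb.shape[axis] // 2
    sl = np.take(rgb, index, axis=axis)
    Image.fromarray(np.asarray(sl, dtype=np.uint8)).save(str(path))
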