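"""Conventional DTI histogram comparators over white matter.

Normalised histograms of MD and FA within a white-matter mask, after
removing spurious CSF voxels (MD > 0.0026 mm^2/s, strict inequality),
with two summaries per metric: the voxelwise median of the raw values
(never binned — binning would quantise it) and the normalised peak
height (NPH), the maximum normalised bin frequency.  The MD histogram
spans 0–0.004 mm^2/s in 4e-6-wide bins and the FA histogram 0–1 in
0.001-wide bins (1000 bins each); bins are half-open with the last bin
closed, and values outside the range are excluded from the histogram
but counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

CSF_MD_THRESHOLD = 0.0026  # mm^2/s; voxels strictly above are CSF-like


@dataclass(frozen=True)
class HistogramSpec:
    metric: str
    lo: float
    hi: float
    bin_width: float

    def __post_init__(self) -> None:
        n = (self.hi - self.lo) / self.bin_width
        if abs(n - round(n)) > 1e-9:
            raise ValueError("range span must be an integer number of bins")

    @property
    def n_bins(self) -> int:
        return int(round((self.hi - self.lo) / self.bin_width))

    @property
    def edges(self) -> np.ndarray:
        return self.lo + self.bin_width * np.arange(self.n_bins + 1)


MD_HISTOGRAM = HistogramSpec("MD", 0.0, 0.004, 4e-6)
FA_HISTOGRAM = HistogramSpec("FA", 0.0, 1.0, 0.001)


@dataclass
class HistogramMetrics:
    metric: str
    median: float
    nph: float
    n_voxels: int
    n_out_of_range: int
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        assert abs(self.frequencies.sum() - 1.0) <= 1e-9


def remove_csf_voxels(
    md_map: np.ndarray,
    wm_mask: np.ndarray,
    threshold: float = CSF_MD_THRESHOLD,
) -> tuple[np.ndarray, int]:
    """Drop WM-mask voxels with MD strictly above the CSF threshold.

    Returns the filtered boolean mask and the number of removed voxels;
    raises if nothing survives.
    """
    md_map = np.asarray(md_map, dtype=np.float64)
    wm = np.asarray(wm_mask).astype(bool)
    if md_map.shape != wm.shape:
        raise ValueError("MD map and WM mask disagree on grid shape")
    keep = wm & ~(md_map > threshold)
    n_removed = int(wm.sum() - keep.sum())
    if not keep.any():
        raise ValueError("CSF removal left no white-matter voxels")
    return keep, n_removed


def histogram_metrics(values: np.ndarray, spec: HistogramSpec) -> HistogramMetrics:
    """Median and normalised peak height of a metric over a voxel set.

    Counts use half-open bins [edge, edge + width) with the last bin
    closed; frequencies are normalised by the in-range count.  The
    median is the voxelwise median of the raw values.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise ValueError("empty value set")
    in_range = (values >= spec.lo) & (values <= spec.hi)
    counts, _ = np.histogram(values[in_range], bins=spec.edges)
    total = counts.sum()
    if total == 0:
        raise ValueError("no values inside the histogram range")
    freqs = counts / total
    return HistogramMetrics(
        metric=spec.metric,
        median=float(np.median(values)),
        nph=float(freqs.max()),
        n_voxels=int(total),
        n_out_of_range=int(values.size - total),
        frequencies=freqs,
    )


def wm_histogram_summary(md_map, fa_map, wm_mask) -> list[dict]:
    """Run the full comparator: CSF removal then MD and FA histograms.

    Returns one record per metric with median, NPH, voxel counts and the
    CSF-removal count, ready for a TSV dump.
    """
    keep, n_csf = remove_csf_voxels(md_map, wm_mask)
    out = []
    for spec, vol in ((MD_HISTOGRAM, md_map), (FA_HISTOGRAM, fa_map)):
        m = histogram_metrics(np.asarray(vol, dtype=np.float64)[keep], spec)
        out.append({
            "metric": m.metric,
            "median": m.median,
            "nph": m.nph,
            "n_voxels": m.n_voxels,
            "n_csf_removed": n_csf,
        })
    return out
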