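"""DSEG spectra, the theta angular metric and the reference-spectrum search.

A DSEG spectrum summarises one scan as the percentage of cerebrum
volume assigned to each of the 16 segments.  Two spectra A and B are
compared by the angle between them,

    theta = arccos( A.B / (|A| |B|) ),

reported in degrees; for non-negative spectra theta lies in [0, 90].
theta is scale-invariant and invariant to any fixed permutation of the
segment labels applied to both spectra, so the canonical segment
ordering never affects it.

The "least damaged" reference spectrum is found iteratively: starting
from a randomly chosen spectrum A, replace A by the spectrum at maximum
theta from it, and repeat until the sequence oscillates between two
spectra — the mutually most distant pair, in practice the least and the
most damaged scans in the cohort.  Which member of the pair is the
"least damaged" one is decided by the spectrum-weighted mean normalised
isotropy d(S) = sum_i s_i * p_i(centroid): CSF- and damage-like segments
sit at high p, so the member with the smaller isotropy load is the
healthier one.  An externally chosen healthy reference can be pinned
instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dseg_core import DsegModel, K_SEGMENTS


@dataclass
class DsegSpectrum:
    """Percentages of cerebrum volume per segment for one scan."""

    s: np.ndarray
    subject_id: str = ""
    timepoint: int = 0

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=np.float64).ravel()
        if np.any(self.s < 0):
            raise ValueError("spectrum components must be non-negative")
        if abs(self.s.sum() - 100.0) > 1e-9:
            raise ValueError(f"spectrum must sum to 100, got {self.s.sum()!r}")

    @property
    def k(self) -> int:
        return self.s.size

    @property
    def scan_id(self) -> str:
        return f"{self.subject_id}/t{self.timepoint}"


@dataclass
class ThetaValue:
    theta_deg: float
    reference_id: str = ""


@dataclass
class ReferenceSearchResult:
    """Outcome of the iterative mutually-farthest-pair search."""

    reference_index: int
    oscillating_pair: tuple[int, int]
    trajectory: list[int] = field(default_factory=list)
    seed: int = 0
    theta_pair_deg: float = 0.0


def compute_spectrum(
    seg: np.ndarray,
    k: int = K_SEGMENTS,
    subject_id: str = "",
    timepoint: int = 0,
) -> DsegSpectrum:
    """Percentage of labelled voxels in each segment.

    ``seg`` is a label volume (0 = background, 1..k = segments) or a flat
    vector of in-mask labels.  The denominator is the count of labelled
    voxels, i.e. the cerebrum volume.
    """
    seg = np.asarray(seg)
    labels = seg[seg > 0]
    if labels.size == 0:
        raise ValueError("no labelled voxels: empty mask or unsegmented volume")
    counts = np.bincount(labels.astype(np.int64), minlength=k + 1)[1:k + 1]
    return DsegSpectrum(100.0 * counts / labels.size, subject_id, timepoint)


def _as_vec(a) -> np.ndarray:
    return a.s if isinstance(a, DsegSpectrum) else np.asarray(a, dtype=np.float64).ravel()


def theta(a, b) -> float:
    """Angle in degrees between two spectra (cosine clamped to [-1, 1])."""
    va, vb = _as_vec(a), _as_vec(b)
    if va.shape != vb.shape:
        raise ValueError("spectra must have equal dimension")
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("zero-norm spectrum has no direction")
    c = np.clip(np.dot(va, vb) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def damage_score(spectrum: DsegSpectrum, model: DsegModel) -> float:
    """Spectrum-weighted mean normalised isotropy, sum_i s_i * p_i / 100.

    High-p segments are CSF- and damage-like, so a larger score means a
    larger isotropy (damage/CSF) load.
    """
    p_cent = model.canonical_centroids()[:, 0]
    return float(np.dot(spectrum.s, p_cent) / 100.0)


def find_reference(
    spectra: list[DsegSpectrum],
    seed: int = 0,
    model: DsegModel | None = None,
) -> ReferenceSearchResult:
    """Iterate A <- argmax_X theta(A, X) until a 2-cycle; pick the reference.

    The terminal 2-cycle is the mutually farthest pair.  When a fitted
    model is supplied, the pair member with the smaller damage score is
    designated the "least damaged" reference; without a model the pair
    member with the smaller index is returned.  ``seed`` controls only
    the starting spectrum.  Argmax ties break to the lowest spectrum
    index; a cycle longer than 2 (possible under exact ties) raises.
    """
    n = len(spectra)
    if n < 3:
        raise ValueError("reference search needs at least 3 spectra")
    vecs = np.array([s.s for s in spectra])
    norms = np.linalg.norm(vecs, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-norm spectrum in cohort")
    cos = np.clip((vecs @ vecs.T) / np.outer(norms, norms), -1.0, 1.0)
    ang = np.degrees(np.arccos(cos))

    rng = np.random.default_rng(seed)
    current = int(rng.integers(n))
    trajectory = [current]
    while True:
        row = ang[current].copy()
        row[current] = -1.0  # never map a spectrum to itself
        nxt = int(np.argmax(row))  # argmax ties -> lowest index
        trajectory.append(nxt)
        if len(trajectory) >= 3 and trajectory[-1] == trajectory[-3] != trajectory[-2]:
            pair = (trajectory[-2], trajectory[-1])
            break
        if len(trajectory) > 2 * n + 4:
            # only reachable through exact-tie longer cycles
            raise RuntimeError(f"reference search cycled without a 2-cycle: {trajectory}")
        current = nxt

    i, j = sorted(pair)
    if model is not None:
        ref = i if damage_score(spectra[i], model) <= damage_score(spectra[j], model) else j
    else:
        ref = i
    return ReferenceSearchResult(
        reference_index=ref,
        oscillating_pair=(i, j),
        trajectory=trajectory,
        seed=seed,
        theta_pair_deg=float(ang[i, j]),
    )


def theta_table(spectra: list[DsegSpectrum], reference: DsegSpectrum) -> pd.DataFrame:
    """theta against one fixed reference for every scan (long format)."""
    rows = [
        {
            "subject": s.subject_id,
            "timepoint": s.timepoint,
            "theta_deg": theta(s, reference),
        }
        for s in spectra
    ]
    return pd.DataFrame(rows, columns=["subject", "timepoint", "theta_deg"])


def annualised_theta_change(table: pd.DataFrame, times: pd.DataFrame | dict) -> pd.Series:
    """Per-subject OLS slope of theta on time (degrees / year).

    ``times`` maps (subject, timepoint) to years since baseline — either
    a DataFrame with columns subject/timepoint/years or a dict keyed by
    (subject, timepoint).  Subjects with a single timepoint get NaN.
    """
    if isinstance(times, dict):
        years = table.apply(lambda r: times[(r["subject"], r["timepoint"])], axis=1)
        df = table.assign(years=years)
    else:
        df = table.merge(times, on=["subject", "timepoint"], validate="one_to_one")
    slopes = {}
    for subject, grp in df.groupby("subject", sort=True):
        if len(grp) < 2 or grp["years"].nunique() < 2:
            slopes[subject] = np.nan
        else:
            slopes[subject] = float(np.polyfit(grp["years"], grp["theta_deg"], 1)[0])
    return pd.Series(slopes, name="theta_slope_deg_per_year").rename_axis("subject")


def spectra_to_frame(spectra: list[DsegSpectrum]) -> pd.DataFrame:
    """Wide table: subject, timepoint, s1..s16."""
    k = spectra[0].k
    rows = []
    for s in spectra:
        row = {"subject": s.subject_id, "timepoint": s.timepoint}
        row.update({f"s{i + 1}": s.s[i] for i in range(k)})
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_spectra(df: pd.DataFrame) -> list[DsegSpectrum]:
    cols = [c for c in df.columns if c.startswith("s") and c[1:].isdigit()]
    cols = sorted(cols, key=lambda c: int(c[1:]))
    return [
        DsegSpectrum(row[cols].to_numpy(dtype=float),
                     str(row.get("subject", "")), int(row.get("timepoint", 0)))
        for _, row in df.iterrows()
    ]
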