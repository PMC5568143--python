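"""Cohort-level (p, q) normalisation and 16-cluster k-medians segmentation.

The segmentation is fitted once on the POOLED in-mask (p, q) values of
all subjects and timepoints: spectra are only comparable when every scan
is partitioned by the same model.  The fit has three stages:

1. *Normalisation* — the 1st and 99.99th percentiles of the pooled p and
   pooled q distributions define clamping bounds; values outside are set
   to 0 or 1 and the rest scaled linearly into [0, 1].  Clamped voxels
   are retained (not discarded) so spectra denominators are unchanged.
2. *Initialisation* — quartile boundaries of normalised p and q define a
   deterministic 4x4 grid of cells of roughly equal occupancy; each
   initial centroid is the component-wise median of its cell.
3. *k-medians* — alternate (a) nearest-centroid assignment under the
   Euclidean distance in normalised (p, q) space and (b) centroid update
   to the component-wise median of the assigned samples, until no sample
   changes cluster or 250 iterations.

Medians (not means) are used because the pooled (p, q) density is
strongly non-Gaussian.  "Component-wise median" means the marginal
median of p and of q separately, not the geometric (spatial) median.

After the fit, segments get a canonical 1..16 labelling by ascending
centroid p (ties by ascending q).  The labelling is a presentation
convention only: the theta angle between spectra is invariant to any
fixed relabelling applied to all spectra.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial.distance import cdist

from .tensor_maps import BrainMask, ScalarMap

logger = logging.getLogger(__name__)

K_SEGMENTS = 16
MAX_ITER = 250
#: pooled-sample cap above which the fit subsamples by deterministic stride
SUBSAMPLE_CAP = 5_000_000


@dataclass(frozen=True)
class NormalisationParams:
    """Percentile clamping bounds for p and q, in mm^2/s."""

    p_lo: float
    p_hi: float
    q_lo: float
    q_hi: float

    def __post_init__(self) -> None:
        if not (self.p_lo < self.p_hi and self.q_lo < self.q_hi):
            raise ValueError("normalisation bounds degenerate: lo must be < hi")


@dataclass
class DsegModel:
    """Fitted segmentation: normalisation bounds + k centroids + labelling.

    ``centroids`` are in normalised [0,1]^2 space, in raw (fit) order;
    ``ordering[i]`` is the canonical segment label (1..k) of raw cluster
    ``i``.  ``canonical_centroids()`` returns them sorted by label.
    """

    norm: NormalisationParams
    centroids: np.ndarray
    ordering: np.ndarray
    iterations_run: int = 0
    converged: bool = False
    k: int = K_SEGMENTS
    objective_trace: list[float] = field(default_factory=list)
    #: J of the previous labelling under the same centroids, aligned with
    #: objective_trace: objective_trace[i] <= objective_pre_assign[i] always.
    objective_pre_assign: list[float] = field(default_factory=list)
    n_samples_fit: int = 0
    subsample_stride: int = 1

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=np.float64)
        self.ordering = np.asarray(self.ordering, dtype=np.int64)
        if self.centroids.shape != (self.k, 2):
            raise ValueError(f"expected {self.k} centroids in 2D, got {self.centroids.shape}")
        if sorted(self.ordering.tolist()) != list(range(1, self.k + 1)):
            raise ValueError("ordering must be a permutation of 1..k")

    def canonical_centroids(self) -> np.ndarray:
        """Centroids sorted so row i is the centroid of segment label i+1."""
        out = np.empty_like(self.centroids)
        out[self.ordering - 1] = self.centroids
        return out

    # -- serialisation ----------------------------------------------------
    def to_json(self) -> str:
        d = {
            "norm": asdict(self.norm),
            "centroids": self.centroids.tolist(),
            "ordering": self.ordering.tolist(),
            "iterations_run": self.iterations_run,
            "converged": self.converged,
            "k": self.k,
            "objective_trace": self.objective_trace,
            "objective_pre_assign": self.objective_pre_assign,
            "n_samples_fit": self.n_samples_fit,
            "subsample_stride": self.subsample_stride,
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DsegModel":
        d = json.loads(text)
        return cls(
            norm=NormalisationParams(**d["norm"]),
            centroids=np.array(d["centroids"]),
            ordering=np.array(d["ordering"]),
            iterations_run=d["iterations_run"],
            converged=d["converged"],
            k=d["k"],
            objective_trace=list(d["objective_trace"]),
            objective_pre_assign=list(d.get("objective_pre_assign", [])),
            n_samples_fit=d.get("n_samples_fit", 0),
            subsample_stride=d.get("subsample_stride", 1),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "DsegModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def fit_normalisation(pooled_p: np.ndarray, pooled_q: np.ndarray) -> NormalisationParams:
    """1st and 99.99th percentiles of the pooled p and q distributions.

    Percentiles use the linear-interpolation definition.  Fewer than 1e4
    pooled voxels makes the 99.99th percentile unstable and triggers a
    warning; a degenerate distribution (lo == hi) raises.
    """
    pooled_p = np.asarray(pooled_p, dtype=np.float64).ravel()
    pooled_q = np.asarray(pooled_q, dtype=np.float64).ravel()
    if pooled_p.size < 10_000:
        warnings.warn(
            f"only {pooled_p.size} pooled voxels; the 99.99th percentile is unstable",
            stacklevel=2,
        )
    p_lo, p_hi = np.percentile(pooled_p, [1.0, 99.99])
    q_lo, q_hi = np.percentile(pooled_q, [1.0, 99.99])
    if p_lo >= p_hi or q_lo >= q_hi:
        raise ValueError("degenerate pooled distribution: percentile bounds coincide")
    return NormalisationParams(float(p_lo), float(p_hi), float(q_lo), float(q_hi))


def normalise_pq(
    p_map: ScalarMap | np.ndarray,
    q_map: ScalarMap | np.ndarray,
    norm: NormalisationParams,
    mask: BrainMask | None = None,
) -> np.ndarray:
    """Map in-mask (p, q) values into [0,1]^2 under the fitted bounds.

    Values below/above the percentile bounds clamp to 0/1; every in-mask
    voxel is retained.  Returns an (n, 2) array in in-mask scan order.
    """
    if isinstance(p_map, ScalarMap):
        if mask is None:
            mask = p_map.mask
        p = p_map.values
        q = q_map.values if isinstance(q_map, ScalarMap) else q_map
    else:
        p, q = p_map, q_map
    if mask is not None:
        p, q = p[mask.data], q[mask.data]
    p = np.clip((np.asarray(p, float).ravel() - norm.p_lo) / (norm.p_hi - norm.p_lo), 0.0, 1.0)
    q = np.clip((np.asarray(q, float).ravel() - norm.q_lo) / (norm.q_hi - norm.q_lo), 0.0, 1.0)
    return np.column_stack([p, q])


def initialise_centroids(samples: np.ndarray, k: int = K_SEGMENTS) -> np.ndarray:
    """Deterministic quartile-grid initialisation.

    Quartile boundaries of normalised p and of normalised q split [0,1]^2
    into a sqrt(k) x sqrt(k) grid of cells of roughly equal occupancy;
    each initial centroid is the component-wise median of its cell.
    Empty cells are reseeded at the cell's geometric centre.
    """
    samples = np.asarray(samples, dtype=np.float64)
    if samples.ndim != 2 or samples.shape[1] != 2:
        raise ValueError("samples must be an (n, 2) array")
    if samples.shape[0] == 0:
        raise ValueError("empty sample set")
    side = int(round(np.sqrt(k)))
    if side * side != k:
        raise ValueError(f"quartile-grid initialisation needs a square k, got {k}")

    qs = np.linspace(0, 100, side + 1)[1:-1]  # interior quantile levels
    p_edges = np.percentile(samples[:, 0], qs)
    q_edges = np.percentile(samples[:, 1], qs)
    # outer cell bounds in normalised space, for geometric centres
    p_bounds = np.concatenate([[0.0], p_edges, [1.0]])
    q_bounds = np.concatenate([[0.0], q_edges, [1.0]])

    pi = np.digitize(samples[:, 0], p_edges)
    qi = np.digitize(samples[:, 1], q_edges)

    centroids = np.empty((k, 2))
    for a in range(side):
        for b in range(side):
            cell = samples[(pi == a) & (qi == b)]
            j = a * side + b
            if cell.shape[0] == 0:
                centroids[j] = [(p_bounds[a] + p_bounds[a + 1]) / 2,
                                (q_bounds[b] + q_bounds[b + 1]) / 2]
                logger.info("empty initial cell (%d,%d); reseeded at geometric centre", a, b)
            else:
                centroids[j] = np.median(cell, axis=0)
    return centroids


def _assign(samples: np.ndarray, centroids: np.ndarray,
            prev_labels: np.ndarray | None = None) -> tuple[np.ndarray, float, float]:
    """Nearest-centroid labels (ties to the lowest index) and squared-J.

    Returns (labels, J_after, J_before) where J_before evaluates the
    previous labelling under the same centroids — the assignment pass is
    guaranteed not to increase J at fixed centroids, so J_after <=
    J_before always; the median *update* step optimises an L1 criterion
    and may transiently raise the squared J.
    """
    d2 = cdist(samples, centroids, metric="sqeuclidean")
    labels = np.argmin(d2, axis=1)
    rows = np.arange(samples.shape[0])
    obj = float(d2[rows, labels].sum())
    obj_before = obj if prev_labels is None else float(d2[rows, prev_labels].sum())
    return labels, obj, obj_before


def kmedians_fit(
    samples: np.ndarray,
    init: np.ndarray,
    norm: NormalisationParams | None = None,
    max_iter: int = MAX_ITER,
) -> DsegModel:
    """Alternating assignment / component-wise-median updates.

    Terminates when an assignment pass moves no sample between clusters,
    or after ``max_iter`` iterations.  A cluster emptied during iteration
    is reseeded to the sample farthest from its previous centroid
    (logged).  The sum-of-squared-distances objective is recorded after
    every assignment step.
    """
    samples = np.asarray(samples, dtype=np.float64)
    centroids = np.array(init, dtype=np.float64)
    k = centroids.shape[0]

    labels, obj, _ = _assign(samples, centroids)
    trace = [obj]
    pre_trace = [obj]
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        # update step: marginal medians per cluster
        for j in range(k):
            members = samples[labels == j]
            if members.shape[0] == 0:
                far = np.argmax(np.linalg.norm(samples - centroids[j], axis=1))
                centroids[j] = samples[far]
                logger.warning("cluster %d emptied at iteration %d; reseeded to farthest sample",
                               j, iterations)
            else:
                centroids[j] = np.median(members, axis=0)
        new_labels, obj, obj_before = _assign(samples, centroids, prev_labels=labels)
        trace.append(obj)
        pre_trace.append(obj_before)
        if np.array_equal(new_labels, labels):
            converged = True
            labels = new_labels
            break
        labels = new_labels

    ordering = canonical_ordering(centroids)
    if norm is None:
        norm = NormalisationParams(0.0, 1.0, 0.0, 1.0)
    return DsegModel(
        norm=norm,
        centroids=centroids,
        ordering=ordering,
        iterations_run=iterations,
        converged=converged,
        k=k,
        objective_trace=trace,
        objective_pre_assign=pre_trace,
        n_samples_fit=samples.shape[0],
    )


def canonical_ordering(centroids: np.ndarray) -> np.ndarray:
    """Segment labels 1..k by ascending centroid p, ties by ascending q.

    Returns ``ordering`` with ``ordering[i]`` the canonical label of raw
    cluster ``i``.
    """
    centroids = np.asarray(centroids, dtype=np.float64)
    order = np.lexsort((centroids[:, 1], centroids[:, 0]))
    ordering = np.empty(centroids.shape[0], dtype=np.int64)
    ordering[order] = np.arange(1, centroids.shape[0] + 1)
    return ordering


def assign_segments(
    p_map: ScalarMap | np.ndarray,
    q_map: ScalarMap | np.ndarray,
    model: DsegModel,
    mask: BrainMask | None = None,
) -> np.ndarray:
    """Label every in-mask voxel with its nearest segment (canonical 1..k).

    Ties break deterministically to the lowest canonical label.  Returns
    an integer volume (0 outside the mask) when given maps, or a flat
    label vector when given flat p/q arrays without a mask.
    """
    if model.centroids.size == 0:
        raise ValueError("model is not fitted")
    if isinstance(p_map, ScalarMap) and mask is None:
        mask = p_map.mask
    xy = normalise_pq(p_map, q_map, model.norm, mask=mask)
    # centroid rows sorted by canonical label so argmin ties pick the lowest
    cano = model.canonical_centroids()
    d2 = cdist(xy, cano, metric="sqeuclidean")
    labels = np.argmin(d2, axis=1).astype(np.int64) + 1
    if mask is None:
        return labels
    out = np.zeros(mask.shape, dtype=np.int16)
    out[mask.data] = labels
    return out


def subsample_stride(n: int, cap: int = SUBSAMPLE_CAP, seed: int = 0) -> tuple[np.ndarray, int]:
    """Deterministic stride-subsampling indices for pooled fits above ``cap``.

    The fit targets the empirical (p, q) density, which a uniform stride
    preserves; the offset is derived from ``seed`` and logged.
    """
    if n <= cap:
        return np.arange(n), 1
    stride = int(np.ceil(n / cap))
    offset = int(seed) % stride
    logger.info("subsampling %d pooled samples with stride %d (offset %d)", n, stride, offset)
    return np.arange(offset, n, stride), stride


# ---------------------------------------------------------------------------
# Model/Results front-end

class PQSegmentation:
    """k-medians segmentation model over pooled normalised (p, q) samples.

    Statsmodels-style front door: build from pooled raw p/q values (all
    subjects and timepoints jointly), then ``fit()`` returns a
    :class:`DsegResults` carrying the fitted :class:`DsegModel` plus
    diagnostics.

    Parameters
    ----------
    pooled_p, pooled_q : array-like
        Raw in-mask p and q values (mm^2/s) pooled over the whole cohort.
    k : int
        Number of segments (16 in the standard DSEG configuration).
    """

    def __init__(self, pooled_p, pooled_q, k: int = K_SEGMENTS):
        self.pooled_p = np.asarray(pooled_p, dtype=np.float64).ravel()
        self.pooled_q = np.asarray(pooled_q, dtype=np.float64).ravel()
        if self.pooled_p.shape != self.pooled_q.shape:
            raise ValueError("pooled p and q must have equal length")
        self.k = k

    @classmethod
    def from_cohort(cls, scans, k: int = K_SEGMENTS) -> "PQSegmentation":
        """Pool (p_map, q_map, mask) triples or Phantom-like objects."""
        ps, qs = [], []
        for scan in scans:
            if hasattr(scan, "p_map"):  # Phantom
                m = scan.mask.data
                ps.append(scan.p_map[m])
                qs.append(scan.q_map[m])
            else:
                p_map, q_map, mask = scan
                ps.append(np.asarray(p_map)[mask.data])
                qs.append(np.asarray(q_map)[mask.data])
        return cls(np.concatenate(ps), np.concatenate(qs), k=k)

    def fit(self, max_iter: int = MAX_ITER, subsample_cap: int = SUBSAMPLE_CAP,
            seed: int = 0) -> "DsegResults":
        norm = fit_normalisation(self.pooled_p, self.pooled_q)
        idx, stride = subsample_stride(self.pooled_p.size, subsample_cap, seed)
        xy = normalise_pq(self.pooled_p[idx], self.pooled_q[idx], norm)
        init = initialise_centroids(xy, k=self.k)
        model = kmedians_fit(xy, init, norm=norm, max_iter=max_iter)
        model.subsample_stride = stride
        return DsegResults(self, model)


class DsegResults:
    """Fitted segmentation results: centroids, ordering and diagnostics."""

    def __init__(self, model: PQSegmentation, dseg_model: DsegModel):
        self.model = model
        self.dseg_model = dseg_model

    @property
    def centroids(self) -> np.ndarray:
        """Centroids in canonical label order (row i = segment i+1)."""
        return self.dseg_model.canonical_centroids()

    @property
    def converged(self) -> bool:
        return self.dseg_model.converged

    @property
    def iterations_run(self) -> int:
        return self.dseg_model.iterations_run

    @property
    def objective(self) -> float:
        return self.dseg_model.objective_trace[-1]

    def assign(self, p_map, q_map, mask: BrainMask | None = None) -> np.ndarray:
        return assign_segments(p_map, q_map, self.dseg_model, mask=mask)

    def summary(self) -> str:
        m = self.dseg_model
        lines = [
            "        (p,q) k-medians segmentation results",
            "=" * 56,
            f"segments (k):        {m.k}",
            f"samples fitted:      {m.n_samples_fit}"
            + (f" (stride {m.subsample_stride})" if m.subsample_stride > 1 else ""),
            f"iterations run:      {m.iterations_run}",
            f"converged:           {m.converged}",
            f"final objective J:   {m.objective_trace[-1]:.6g}",
            f"p bounds (mm^2/s):   [{m.norm.p_lo:.6g}, {m.norm.p_hi:.6g}]",
            f"q bounds (mm^2/s):   [{m.norm.q_lo:.6g}, {m.norm.q_hi:.6g}]",
            "-" * 56,
            "segment   p_norm    q_norm",
        ]
        for lab, (cp, cq) in enumerate(self.centroids, start=1):
            lines.append(f"{lab:7d}   {cp:.4f}    {cq:.4f}")
        return "\n".join(lines)
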