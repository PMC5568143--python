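"""Synthetic multi-subject longitudinal phantoms with known (p, q) mixtures.

Each phantom is a small ellipsoidal "cerebrum" whose voxels belong to
one of five tissue classes — grey matter (GM), white matter (WM), CSF,
a GM/CSF boundary (partial-volume) class and a WMH-like damage class —
with class-conditional (p, q) values drawn from truncated Gaussians.
Disease progression is a single damage fraction ``d`` per timepoint:
each WM voxel converts to the damage class with probability ``d`` and
each GM voxel to the boundary class with probability ``d``, emulating
the loss of healthy tissue to white-matter damage and to CSF-boundary
partial volume as small vessel disease progresses.

Sampled (p, q) pairs are converted to axially symmetric (prolate)
tensor eigenvalues through

    MD = p / sqrt(3),   delta = q * sqrt(2/3),
    lam1 = MD + delta,  lam2 = lam3 = MD - delta / 2,

which reproduces the sampled (p, q) exactly and keeps lam3 >= 0
whenever q <= sqrt(2) * p (the realisability constraint enforced at
model validation).  Axial symmetry is sufficient because the whole
pipeline is rotation-invariant — only (p, q) magnitudes matter.

Class means are plausible literature-scale diffusivities (not derived
from any specific cohort); they satisfy the qualitative ordering
p(CSF) > p(damage) > p(boundary) > p(GM) ~ p(WM), q(WM) > q(GM) and
q(damage) < q(WM).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .tensor_maps import BrainMask, EigenField

SQRT2 = float(np.sqrt(2.0))

CLASS_NAMES = ("GM", "WM", "CSF", "boundary", "damage")
#: truth-label codes; 0 is background
CLASS_CODES = {name: i + 1 for i, name in enumerate(CLASS_NAMES)}


@dataclass(frozen=True)
class TissueClassModel:
    """Class-conditional (p, q) Gaussian in mm^2/s plus a T2-like level."""

    name: str
    mean_p: float
    mean_q: float
    sd_p: float
    sd_q: float
    baseline_fraction: float
    t2_mean: float = 1000.0
    t2_sd: float = 30.0

    def __post_init__(self) -> None:
        if self.mean_q > SQRT2 * self.mean_p:
            raise ValueError(
                f"class {self.name!r} unrealisable: mean_q > sqrt(2)*mean_p "
                "implies a negative smallest eigenvalue"
            )
        if self.mean_p <= 0 or self.mean_q < 0:
            raise ValueError(f"class {self.name!r}: mean_p must be > 0 and mean_q >= 0")
        if not 0 <= self.baseline_fraction <= 1:
            raise ValueError(f"class {self.name!r}: baseline_fraction outside [0, 1]")


def default_tissue_models(well_separated: bool = False) -> list[TissueClassModel]:
    """The five-class mixture used throughout the synthetic cohort.

    ``well_separated=True`` shrinks every standard deviation eightfold so
    that each class's spread in cohort-normalised (p, q) units stays below
    ~0.02 — nearly disjoint class clouds for parameter-recovery tests.
    """
    s = 0.125 if well_separated else 1.0
    e3 = 1e-3
    return [
        TissueClassModel("GM", 1.386 * e3, 0.15 * e3, s * 0.10 * e3, s * 0.05 * e3,
                         0.40, t2_mean=1000.0),
        TissueClassModel("WM", 1.247 * e3, 0.70 * e3, s * 0.10 * e3, s * 0.12 * e3,
                         0.35, t2_mean=800.0),
        TissueClassModel("CSF", 5.196 * e3, 0.25 * e3, s * 0.30 * e3, s * 0.10 * e3,
                         0.12, t2_mean=2000.0),
        TissueClassModel("boundary", 2.078 * e3, 0.30 * e3, s * 0.20 * e3, s * 0.10 * e3,
                         0.08, t2_mean=1400.0),
        TissueClassModel("damage", 2.940 * e3, 0.35 * e3, s * 0.20 * e3, s * 0.10 * e3,
                         0.05, t2_mean=1250.0),
    ]


def validate_models(models: list[TissueClassModel]) -> None:
    total = sum(m.baseline_fraction for m in models)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"baseline fractions must sum to 1, got {total}")
    names = [m.name for m in models]
    if len(set(names)) != len(names):
        raise ValueError("duplicate class names")


@dataclass
class Phantom:
    """One synthetic subject/timepoint with full voxelwise ground truth."""

    subject_id: str
    timepoint: int
    damage_fraction: float
    lam1: np.ndarray
    lam2: np.ndarray
    lam3: np.ndarray
    mask: BrainMask
    t2: np.ndarray
    truth_labels: np.ndarray  # class codes, 0 = background
    p_map: np.ndarray  # sampled ground-truth p (mm^2/s)
    q_map: np.ndarray
    seed: int = 0
    class_names: tuple = CLASS_NAMES

    def eigenfield(self) -> EigenField:
        return EigenField(self.lam1, self.lam2, self.lam3, mask=self.mask)

    def class_fractions(self) -> dict[str, float]:
        """In-mask fraction of each tissue class (ground truth)."""
        labels = self.truth_labels[self.mask.data]
        return {
            name: float(np.mean(labels == CLASS_CODES[name]))
            for name in self.class_names
        }

    @property
    def scan_id(self) -> str:
        return f"{self.subject_id}/t{self.timepoint}"

    def save_nifti(self, out_dir) -> None:
        """Write eigenvalues (4D), mask, T2 and truth labels as NIfTI."""
        import nibabel as nib
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stem = f"{self.subject_id}_t{self.timepoint}"
        aff = np.eye(4)
        lams = np.stack([self.lam1, self.lam2, self.lam3], axis=-1)
        nib.save(nib.Nifti1Image(lams, aff), out / f"{stem}_eig.nii.gz")
        nib.save(nib.Nifti1Image(self.mask.data.astype(np.uint8), aff),
                 out / f"{stem}_mask.nii.gz")
        nib.save(nib.Nifti1Image(self.t2, aff), out / f"{stem}_t2.nii.gz")
        nib.save(nib.Nifti1Image(self.truth_labels.astype(np.int16), aff),
                 out / f"{stem}_truth.nii.gz")


def _ellipsoid_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Ellipsoid filling ~95% of each half-dimension; the radius field is
    reused for shell geometry."""
    centre = [(n - 1) / 2 for n in shape]
    semi = [0.95 * (n - 1) / 2 for n in shape]
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centre, semi))
    return r2 <= 1.0, np.sqrt(r2)


#: shell order from the ellipsoid centre outwards: ventricular CSF core,
#: baseline damage around it, then WM, GM cortex and a boundary rim.
_SHELL_ORDER = ("CSF", "damage", "WM", "GM", "boundary")


def _base_labels(mask: np.ndarray, radius: np.ndarray, models, geometry: str,
                 rng: np.random.Generator) -> np.ndarray:
    frac = {m.name: m.baseline_fraction for m in models}
    labels = np.zeros(mask.shape, dtype=np.int16)
    n = int(mask.sum())
    if geometry == "random":
        names = [m.name for m in models]
        codes = np.array([CLASS_CODES[nm] for nm in names])
        probs = np.array([frac[nm] for nm in names])
        labels[mask] = rng.choice(codes, size=n, p=probs)
    elif geometry == "shells":
        order = np.argsort(radius[mask], kind="stable")
        flat = np.zeros(n, dtype=np.int16)
        cuts = np.cumsum([frac[nm] for nm in _SHELL_ORDER])
        start = 0
        for nm, cut in zip(_SHELL_ORDER, cuts):
            stop = int(round(cut * n))
            flat[order[start:stop]] = CLASS_CODES[nm]
            start = stop
        flat[order[start:]] = CLASS_CODES[_SHELL_ORDER[-1]]
        labels[mask] = flat
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    return labels


def _sample_pq(model: TissueClassModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Truncated-Gaussian (p, q) samples obeying 0 < p, 0 <= q <= sqrt(2) p."""
    p = rng.normal(model.mean_p, model.sd_p, size=n)
    q = rng.normal(model.mean_q, model.sd_q, size=n)
    for _ in range(100):
        bad = (p <= 0) | (q < 0) | (q > SQRT2 * p)
        if not bad.any():
            break
        nb = int(bad.sum())
        p[bad] = rng.normal(model.mean_p, model.sd_p, size=nb)
        q[bad] = rng.normal(model.mean_q, model.sd_q, size=nb)
    else:
        # pathological model: clip the stragglers into the valid cone
        p = np.maximum(p, 1e-12)
        q = np.clip(q, 0.0, SQRT2 * p)
    return np.column_stack([p, q])


def pq_to_eigenvalues(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Axially symmetric eigenvalues reproducing (p, q) exactly."""
    md = np.asarray(p) / np.sqrt(3.0)
    delta = np.asarray(q) * np.sqrt(2.0 / 3.0)
    return md + delta, md - delta / 2.0, md - delta / 2.0


def make_phantom(
    subject_id: str,
    timepoint: int,
    damage_fraction: float,
    models: list[TissueClassModel] | None = None,
    shape: tuple[int, int, int] = (32, 32, 32),
    geometry: str = "shells",
    seed: int = 0,
) -> Phantom:
    """Generate one subject/timepoint phantom.

    Reproducible: the voxel stream is fully determined by ``seed`` (plus
    subject/timepoint when called through :func:`make_cohort`).
    """
    if not 0 <= damage_fraction < 1:
        raise ValueError("damage_fraction must lie in [0, 1)")
    models = default_tissue_models() if models is None else models
    validate_models(models)
    by_name = {m.name: m for m in models}
    rng = np.random.default_rng(seed)

    mask_arr, radius = _ellipsoid_mask(shape)
    labels = _base_labels(mask_arr, radius, models, geometry, rng)

    # disease progression: WM -> damage, GM -> boundary, each with prob d
    d = float(damage_fraction)
    if d > 0:
        u = rng.random(mask_arr.shape)
        wm_hit = mask_arr & (labels == CLASS_CODES["WM"]) & (u < d)
        gm_hit = mask_arr & (labels == CLASS_CODES["GM"]) & (u < d)
        labels[wm_hit] = CLASS_CODES["damage"]
        labels[gm_hit] = CLASS_CODES["boundary"]
    else:
        rng.random(mask_arr.shape)  # keep the voxel stream aligned across d

    p_map = np.zeros(shape)
    q_map = np.zeros(shape)
    t2 = np.zeros(shape)
    for name in CLASS_NAMES:
        sel = labels == CLASS_CODES[name]
        n = int(sel.sum())
        if n == 0:
            continue
        m = by_name[name]
        pq = _sample_pq(m, n, rng)
        p_map[sel] = pq[:, 0]
        q_map[sel] = pq[:, 1]
        t2[sel] = rng.normal(m.t2_mean, m.t2_sd, size=n)

    lam1, lam2, lam3 = pq_to_eigenvalues(p_map, q_map)
    lam1[~mask_arr] = lam2[~mask_arr] = lam3[~mask_arr] = 0.0
    return Phantom(
        subject_id=subject_id,
        timepoint=timepoint,
        damage_fraction=d,
        lam1=lam1, lam2=lam2, lam3=lam3,
        mask=BrainMask(mask_arr),
        t2=t2,
        truth_labels=labels,
        p_map=p_map,
        q_map=q_map,
        seed=seed,
    )


def default_damage_schedule(n_subjects: int, n_timepoints: int) -> np.ndarray:
    """Baseline severity spread over 0–0.25 plus 0.05/timepoint progression."""
    base = np.linspace(0.0, 0.25, n_subjects)
    steps = 0.05 * np.arange(n_timepoints)
    return np.clip(base[:, None] + steps[None, :], 0.0, 0.95)


def make_cohort(
    n_subjects: int,
    n_timepoints: int,
    damage_schedule: np.ndarray | None = None,
    geometry: str = "shells",
    seed: int = 0,
    models: list[TissueClassModel] | None = None,
    shape: tuple[int, int, int] = (32, 32, 32),
) -> list[Phantom]:
    """Generate a longitudinal cohort of phantoms.

    ``damage_schedule`` is an (n_subjects, n_timepoints) array of damage
    fractions, non-decreasing along time; by default severity is spread
    across subjects and grows by 0.05 per timepoint.  Each phantom gets
    an independent child seed derived from ``seed`` and its indices, so
    the same seed reproduces the cohort bit-identically.
    """
    if damage_schedule is None:
        damage_schedule = default_damage_schedule(n_subjects, n_timepoints)
    damage_schedule = np.asarray(damage_schedule, dtype=np.float64)
    if damage_schedule.shape != (n_subjects, n_timepoints):
        raise ValueError("damage_schedule must have shape (n_subjects, n_timepoints)")
    if np.any(np.diff(damage_schedule, axis=1) < -1e-12):
        raise ValueError("damage_schedule must be non-decreasing along time")

    cohort = []
    for i in range(n_subjects):
        for t in range(n_timepoints):
            child = np.random.SeedSequence([int(seed), i, t])
            child_seed = int(child.generate_state(1)[0] % (2**31))
            cohort.append(make_phantom(
                subject_id=f"sub{i + 1:03d}",
                timepoint=t,
                damage_fraction=float(damage_schedule[i, t]),
                models=models,
                shape=shape,
                geometry=geometry,
                seed=child_seed,
            ))
    return cohort


def save_truth_table(cohort: list[Phantom], path) -> None:
    """TSV of per-scan ground truth: damage fraction and class fractions."""
    import pandas as pd

    rows = []
    for ph in cohort:
        row = {"subject": ph.subject_id, "timepoint": ph.timepoint,
               "damage_fraction": ph.damage_fraction,
               "n_voxels": ph.mask.n_voxels}
        row.update({f"frac_{k}": v for k, v in ph.class_fractions().items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_config(path) -> dict:
    """Read a JSON or YAML simulation config."""
    text = open(path).read()
    try:
        return json.loads(text)
    except json.JSONDecodeError:
        import yaml

        return yaml.safe_load(text)


def cohort_from_config(cfg: dict) -> list[Phantom]:
    models = None
    if "classes" in cfg:
        models = [TissueClassModel(**c) for c in cfg["classes"]]
    sched = np.array(cfg["damage_schedule"]) if "damage_schedule" in cfg else None
    return make_cohort(
        n_subjects=cfg.get("n_subjects", 5),
        n_timepoints=cfg.get("n_timepoints", 4),
        damage_schedule=sched,
        geometry=cfg.get("geometry", "shells"),
        seed=cfg.get("seed", 0),
        models=models,
        shape=tuple(cfg.get("shape", (32, 32, 32))),
    )
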