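# pqdseg

Whole-brain diffusion-MRI segmentation biomarkers from the isotropic /
anisotropic (p, q) tensor decomposition.

`pqdseg` is for researchers tracking diffuse microstructural brain damage —
typified by cerebral small vessel disease (SVD) — who want a single, stable,
whole-brain biomarker from diffusion tensor imaging (DTI) instead of
region-of-interest statistics. It implements the DSEG technique: segment the
pooled two-dimensional density of isotropic and anisotropic tensor magnitudes
into 16 diffusion-profile clusters, summarise each scan as a 16-component
spectrum, and reduce each spectrum to one angle, DSEG θ, measuring its
deviation from a "least damaged" reference brain. Conventional DTI histogram
comparators (MD/FA median and normalised peak height) are included, along
with a synthetic phantom cohort generator so the whole pipeline can be
exercised and validated without any imaging data.

## The model

Each voxel's diffusion tensor with eigenvalues λ₁ ≥ λ₂ ≥ λ₃ (mm²/s) is
decomposed into two orthogonal magnitudes:

    MD = (λ₁ + λ₂ + λ₃) / 3
    p  = √3 · MD                      (isotropic component)
    q  = √( Σᵢ (λᵢ − MD)² )           (anisotropic component)
    FA = √(3/2) · q / √(λ₁² + λ₂² + λ₃²)

so that p² + q² = λ₁² + λ₂² + λ₃² identically. Grey matter, white matter,
CSF and damaged tissue occupy characteristic regions of the (p, q) plane.

The pooled in-mask (p, q) values of **all** subjects and timepoints are
clamped at the 1st and 99.99th percentiles, scaled to [0, 1]², and
partitioned into k = 16 clusters by k-medians: alternate nearest-centroid
assignment under the Euclidean distance with centroid updates to the
component-wise median, until no voxel moves or 250 iterations. Medians are
used because the pooled (p, q) density is strongly non-Gaussian.

Each scan's **DSEG spectrum** is the percentage of cerebrum volume in each
segment, S = (s₁, …, s₁₆) with Σ sᵢ = 100. Two spectra A, B are compared by

    θ = arccos( A·B / (‖A‖‖B‖) )      (degrees; 0–90 for non-negative spectra)

The reference spectrum is found by iterating A ← argmaxₓ θ(A, X) until the
sequence oscillates between two spectra (the least and most damaged scans);
the member with the smaller spectrum-weighted mean isotropy is taken as the
"least damaged" reference, or an external healthy reference can be pinned.
Higher θ means greater deviation from healthy whole-brain microstructure.

## Worked example

```python
import numpy as np
from pqdseg import make_phantom
from pqdseg.dseg_core import PQSegmentation
from pqdseg.spectra_theta import compute_spectrum, theta

# one phantom per damage level, pooled into a single segmentation fit
levels = [0.0, 0.1, 0.2, 0.3, 0.4, 0.5]
cohort = [make_phantom(f"d{int(10*d)}", 0, d, seed=1000 + i)
          for i, d in enumerate(levels)]
results = PQSegmentation.from_cohort(cohort).fit()
print(results.summary())

spectra = [compute_spectrum(results.assign(ph.p_map, ph.q_map, ph.mask),
                            subject_id=ph.subject_id) for ph in cohort]
for d, s in zip(levels, spectra):
    print(f"damage {d:.1f}  theta vs d=0 reference: {theta(s, spectra[0]):6.2f} deg")
```

prints

```
        (p,q) k-medians segmentation results
========================================================
segments (k):        16
samples fitted:      80496
iterations run:      69
converged:           True
final objective J:   219.167
p bounds (mm^2/s):   [0.00106952, 0.00617518]
q bounds (mm^2/s):   [5.14093e-05, 0.0011131]
--------------------------------------------------------
segment   p_norm    q_norm
      1   0.0343    0.6144
      ...
     16   0.8098    0.1253
damage 0.0  theta vs d=0 reference:   0.00 deg
damage 0.1  theta vs d=0 reference:   9.45 deg
damage 0.2  theta vs d=0 reference:  19.72 deg
damage 0.3  theta vs d=0 reference:  29.16 deg
damage 0.4  theta vs d=0 reference:  36.78 deg
damage 0.5  theta vs d=0 reference:  45.35 deg
```

The fit pools ~80k voxels from six phantoms, converges in 69 iterations,
and the centroid table spans the (p, q) plane from low-isotropy/high-
anisotropy white-matter-like profiles (segments 1–5) to high-isotropy
CSF-like profiles (15–16). θ against the undamaged phantom grows strictly
with the simulated damage fraction — the behaviour that makes θ a disease
progression marker.

## Command line

A `dseg` console script wraps the library for NIfTI volumes:

```sh
dseg simulate --out-dir cohort/                     # synthetic cohort
dseg pq --tensors T.nii.gz --mask M.nii.gz --out-prefix subj01
dseg fit --pq-list cohort.tsv --out model.json
dseg apply --model model.json --p p.nii.gz --q q.nii.gz --mask M.nii.gz --out seg.nii.gz
dseg spectrum --seg seg.nii.gz --out spec.tsv
dseg theta --spectra all.tsv --find-reference --seed 1 --model model.json --out theta.tsv
dseg colormap --seg seg.nii.gz --p p.nii.gz --q q.nii.gz --t2 b0.nii.gz --out rgb.nii.gz
dseg histogram --md MD.nii.gz --fa FA.nii.gz --wm-mask WM.nii.gz --out hist.tsv
```

Inputs are NIfTI-1 volumes: tensors as 6-volume 4D files (dxx, dxy, dyy,
dxz, dyz, dzz), eigenvalues as 3-volume 4D files, masks as 3D 0/1 volumes.

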