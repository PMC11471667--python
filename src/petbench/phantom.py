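"""Synthetic paired low-time / full-time whole-body PET phantom.

The phantom realizes the statistical structure the downstream analysis
assumes: one underlying activity distribution per session, imaged at 30, 60
and 90 s per bed, with counting noise whose variance scales inversely with
acquisition time (a "short time frame" acquisition, not list-mode
decimation).

Noise model
-----------
Expected detected events per voxel are

    lambda_v = blur(C)_v [kBq/ml] * 1000 [Bq/kBq] * V_vox [ml] * t [s] * eta

where ``blur`` is an isotropic Gaussian PSF and ``eta`` a dimensionless
detector sensitivity.  Observed counts are Poisson(lambda_v) and the returned
concentration estimate divides counts by the same factors, making it unbiased
for the blurred truth with per-voxel variance proportional to 1/t — hence the
sqrt(3) error-SD ratio between 30 s and 90 s acquisitions.
"""

from __future__ import annotations

import json
import logging
import shutil
from pathlib import Path

import numpy as np
from scipy import ndimage

from .suv import decayed_dose
from .types import (
    DOSE_PER_KG,
    PROTOCOL_TIMES,
    AcquisitionMeta,
    Ellipsoid,
    PairedStudy,
    PETVolume,
    PhantomSpec,
    Sphere,
)

log = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Default organ template (SUV targets spanning the lesion-filter thresholds).
DEFAULT_ORGANS = {
    "body": 1.0,
    "lungs": 0.3,
    "liver": 2.5,
    "brain": 6.0,
    "bladder": 10.0,
}


def _voxel_centers(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _clip_warn(kind: str, center, shape, spacing) -> None:
    extent = [n * s for n, s in zip(shape, spacing)]
    if any(c < 0 or c > e for c, e in zip(center, extent)):
        log.warning("%s centered at %s extends outside the %s mm grid; clipped",
                    kind, center, extent)


def build_activity_map(spec: PhantomSpec, meta: AcquisitionMeta):
    """Rasterize the phantom scene into a concentration volume plus labels.

    Later scene entries overwrite earlier ones inside their support; lesions
    are painted after organs and labeled 1..n in list order.  Each voxel's
    concentration is ``target_SUV * decayed_dose / weight`` (kBq/ml), so SUV
    conversion recovers the target SUVs exactly.

    Returns ``(concentration, lesion_labels, organ_labels)``.
    """
    zz, yy, xx = _voxel_centers(spec.shape, spec.spacing)
    conc = np.zeros(spec.shape, dtype=np.float64)
    organ_labels = np.zeros(spec.shape, dtype=np.int32)
    lesion_labels = np.zeros(spec.shape, dtype=np.int32)

    # kBq/ml per unit SUV: decayed dose [MBq] -> kBq over weight [kg] -> g
    suv_to_conc = decayed_dose(meta) * 1000.0 / (meta.weight * 1000.0)

    for i, organ in enumerate(spec.organs, start=1):
        _clip_warn("organ", organ.center, spec.shape, spec.spacing)
        c, a = organ.center, organ.semi_axes
        inside = ((zz - c[0]) / a[0]) ** 2 + ((yy - c[1]) / a[1]) ** 2 \
            + ((xx - c[2]) / a[2]) ** 2 <= 1.0
        conc[inside] = organ.suv * suv_to_conc
        organ_labels[inside] = i

    for i, lesion in enumerate(spec.lesions, start=1):
        _clip_warn("lesion", lesion.center, spec.shape, spec.spacing)
        c, r = lesion.center, lesion.diameter / 2.0
        inside = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= r**2
        conc[inside] = lesion.suv * suv_to_conc
        lesion_labels[inside] = i

    return conc, lesion_labels, organ_labels


def simulate_acquisition(truth: np.ndarray, meta: AcquisitionMeta,
                         spec: PhantomSpec,
                         rng: np.random.Generator) -> PETVolume:
    """Simulate one acquisition of ``truth`` (kBq/ml) at ``meta.time_per_bed``.

    Applies the PSF blur, draws Poisson counts at the expected-event rate and
    converts back to concentration.  The estimator is unbiased for the
    blurred truth; per-voxel variance scales as 1/t.
    """
    truth = np.asarray(truth, dtype=np.float64)
    if np.any(truth < 0):
        raise ValueError("truth concentrations must be non-negative")
    t = meta.time_per_bed
    if t <= 0:
        raise ValueError("acquisition time must be strictly positive")

    sigma_vox = [spec.psf_fwhm_mm * FWHM_TO_SIGMA / s for s in spec.spacing]
    blurred = ndimage.gaussian_filter(truth, sigma=sigma_vox)
    np.clip(blurred, 0.0, None, out=blurred)

    scale = 1000.0 * spec.voxel_volume_ml * t * spec.sensitivity
    lam = blurred * scale
    if lam.max(initial=0.0) > 1e12:
        raise ValueError(
            "expected-event rate overflows the Poisson sampler; "
            "lower the detector sensitivity eta")
    counts = rng.poisson(lam).astype(np.float64)
    return PETVolume(values=counts / scale, spacing=spec.spacing, meta=meta)


def sample_phantom_spec(template: PhantomSpec,
                        rng: np.random.Generator,
                        p_no_lesion: float = 0.2,
                        max_lesions: int = 5) -> PhantomSpec:
    """Randomize a patient scene from a geometry template.

    Organs follow a fixed whole-body template scaled to the grid; lesion
    count, positions, diameters (6–30 mm) and uptake (SUV 2–15) are sampled,
    with probability ``p_no_lesion`` of a tumor-free patient.  Diameters and
    uptakes straddle the 7 mm / SUV 0.5 analysis filters on the low side via
    occasional sub-7 mm lesions.
    """
    ez, ey, ex = [n * s for n, s in zip(template.shape, template.spacing)]
    organs = (
        Ellipsoid((ez * 0.55, ey * 0.5, ex * 0.5),
                  (ez * 0.42, ey * 0.38, ex * 0.30), DEFAULT_ORGANS["body"]),
        Ellipsoid((ez * 0.38, ey * 0.45, ex * 0.40),
                  (ez * 0.10, ey * 0.16, ex * 0.10), DEFAULT_ORGANS["lungs"]),
        Ellipsoid((ez * 0.38, ey * 0.45, ex * 0.62),
                  (ez * 0.10, ey * 0.16, ex * 0.10), DEFAULT_ORGANS["lungs"]),
        Ellipsoid((ez * 0.52, ey * 0.50, ex * 0.38),
                  (ez * 0.09, ey * 0.14, ex * 0.14), DEFAULT_ORGANS["liver"]),
        Ellipsoid((ez * 0.08, ey * 0.50, ex * 0.50),
                  (ez * 0.07, ey * 0.12, ex * 0.12), DEFAULT_ORGANS["brain"]),
        Ellipsoid((ez * 0.88, ey * 0.55, ex * 0.50),
                  (ez * 0.05, ey * 0.08, ex * 0.08), DEFAULT_ORGANS["bladder"]),
    )
    lesions: list[Sphere] = []
    if rng.random() >= p_no_lesion:
        n_lesions = int(rng.integers(1, max_lesions + 1))
        for _ in range(n_lesions):
            # torso band of the body ellipsoid, away from brain and bladder
            center = (
                float(rng.uniform(0.25 * ez, 0.72 * ez)),
                float(rng.uniform(0.30 * ey, 0.70 * ey)),
                float(rng.uniform(0.30 * ex, 0.70 * ex)),
            )
            diameter = float(rng.uniform(6.0, 30.0))
            suv = float(rng.uniform(2.0, 15.0))
            lesions.append(Sphere(center, diameter, suv))
    return PhantomSpec(
        shape=template.shape,
        spacing=template.spacing,
        organs=organs,
        lesions=tuple(lesions),
        sensitivity=template.sensitivity,
        psf_fwhm_mm=template.psf_fwhm_mm,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def simulate_study(spec: PhantomSpec, meta: AcquisitionMeta,
                   rng: np.random.Generator,
                   times=PROTOCOL_TIMES, patient_id: str = "phantom") -> PairedStudy:
    """Build one paired study: shared truth, one acquisition per bed time."""
    conc, lesion_labels, organ_labels = build_activity_map(spec, meta)
    volumes = {
        int(t): simulate_acquisition(conc, meta.with_time(t), spec, rng)
        for t in times
    }
    return PairedStudy(
        volumes=volumes,
        lesion_labels=lesion_labels,
        organ_labels=organ_labels,
        meta=meta,
        spacing=spec.spacing,
        patient_id=patient_id,
    )


def _sample_weight(rng: np.random.Generator) -> float:
    """Body weight in kg: normal(79, 18) clipped to the cohort range 34–150."""
    return float(np.clip(rng.normal(79.0, 18.0), 34.0, 150.0))


def generate_patient(template: PhantomSpec, rng: np.random.Generator,
                     patient_id: str = "phantom",
                     times=PROTOCOL_TIMES) -> PairedStudy:
    """Sample one synthetic patient (weight, dose, scene) and simulate."""
    weight = _sample_weight(rng)
    meta = AcquisitionMeta(weight=weight, total_dose=DOSE_PER_KG * weight,
                           delay=3600.0)
    spec = sample_phantom_spec(template, rng)
    return simulate_study(spec, meta, rng, times=times, patient_id=patient_id)


def generate_dataset(n_train: int, n_val: int, n_test: int, out_dir,
                     template: PhantomSpec | None = None, seed: int = 0,
                     times=PROTOCOL_TIMES, overwrite: bool = False) -> dict:
    """Generate a split dataset on disk and return the split manifest.

    Layout: ``<out>/<patient_id>/pet_<t>s.nii.gz`` plus ``lesion_labels`` /
    ``organ_labels`` NIfTI volumes and a ``meta.json`` sidecar;
    ``<out>/manifest.json`` lists patient ids per split.  Deterministic for a
    fixed seed, including across process restarts.
    """
    from . import io as pio

    if min(n_train, n_val, n_test) < 0:
        raise ValueError("split sizes must be non-negative")
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()):
        if not overwrite:
            raise FileExistsError(
                f"{out} is not empty; pass overwrite=True to replace it")
        shutil.rmtree(out)
    out.mkdir(parents=True, exist_ok=True)

    template = template or PhantomSpec()
    root_ss = np.random.SeedSequence(seed)
    manifest: dict = {"seed": seed, "times_s": list(times), "splits": {}}
    splits = [("train", n_train), ("val", n_val), ("test", n_test)]
    child_seeds = root_ss.spawn(sum(n for _, n in splits))
    k = 0
    for split, n in splits:
        ids = []
        for i in range(n):
            pid = f"{split}_{i:03d}"
            rng = np.random.default_rng(child_seeds[k])
            k += 1
            study = generate_patient(template, rng, patient_id=pid, times=times)
            pio.save_study(study, out / pid)
            ids.append(pid)
        manifest["splits"][split] = ids
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
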