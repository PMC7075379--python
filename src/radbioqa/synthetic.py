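"""Synthetic planned/measured DVH pairs, dose-grid pairs, and cohorts.

No patient-level plan-verification data are publicly deposited, so every
downstream stage of the pipeline is exercised on generated inputs.  The
generator emulates the shapes that matter to the models rather than
anatomy:

* a target (PTV) DVH concentrated near the prescription dose (narrow
  truncated-normal differential histogram);
* organ-at-risk DVHs as monotone sigmoid-decay cumulative curves spanning
  zero to near-prescription doses;
* planned dose grids as a superposition of Gaussian blobs on a low-dose
  bath, mimicking a modulated distribution with steep falloff.

Measurement discrepancy is modelled phenomenologically with three knobs —
systematic dose scaling, spatial Gaussian blur (grids only), and
multiplicative noise — the effect classes that plan-verification practice
attributes differences to (detector resolution, reconstruction accuracy,
plan complexity).

Reproducibility: a cohort takes one root seed; per-patient child seeds are
spawned deterministically with ``numpy.random.SeedSequence(root).spawn``,
so any single patient can be regenerated in isolation from its recorded
seed.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.stats import truncnorm

from .dvh_io import DVHFile, Prescription, read_dvh_file, write_dvh_file
from .gamma3d import DoseGrid, load_dose_grid, save_dose_grid
from .rb_core import DVH, DVHForm, ValidationError

__all__ = [
    "PerturbationSpec",
    "SyntheticPatient",
    "SITE_STRUCTURES",
    "PRESCRIPTION_RANGES",
    "make_planned_dvh_set",
    "perturb_to_measured",
    "make_grid_pair",
    "make_cohort",
    "write_cohort",
    "read_cohort",
]

#: Structure sets evaluated per treatment group.
SITE_STRUCTURES: dict[str, tuple[str, ...]] = {
    "brain": ("Brain", "Brainstem", "Chiasm", "Rt. optic nerve", "Lt. optic nerve", "PTV"),
    "head_neck": (
        "Rt. parotid", "Lt. parotid", "Mandible",
        "Rt. brachial plexus", "Lt. brachial plexus", "PTV7000", "PTV5400",
    ),
    "lung": ("Esophagus", "Heart", "Lung", "PTV"),
    "pelvis": ("Bladder", "Rectum", "Sigmoid", "Bowel", "Penile bulb", "PTV"),
    "prostate": ("Bladder", "Rectum", "Sigmoid", "Penile bulb", "PTV"),
}

#: (dose range Gy, fraction range) the prescriptions are drawn from, per
#: treatment group — the conventionally fractionated ranges these cohorts
#: span in clinical practice.
PRESCRIPTION_RANGES: dict[str, tuple[tuple[float, float], tuple[int, int]]] = {
    "brain": ((50.4, 60.0), (28, 30)),
    "head_neck": ((30.0, 69.96), (5, 35)),
    "lung": ((30.0, 60.0), (3, 30)),
    "pelvis": ((34.2, 79.2), (11, 28)),
    "prostate": ((45.0, 70.2), (25, 30)),
}

_TARGET_RE = re.compile(r"ptv|gtv|ctv", re.IGNORECASE)


@dataclass(frozen=True)
class PerturbationSpec:
    """Phenomenological planned -> measured discrepancy model.

    ``dose_scale`` multiplies every structure's (or voxel's) dose;
    ``target_dose_scale`` / ``oar_dose_scale`` override it for target /
    organ-at-risk structures so systematic under- or over-dosing of one
    tissue class can be emulated.  ``gaussian_blur_mm`` smooths dose grids
    only; ``noise_sd_pct`` adds multiplicative Gaussian noise (per structure
    for DVHs, per voxel for grids); ``dvh_shift_gy`` shifts DVH bin doses
    additively (clamped at zero).  The identity spec leaves inputs
    byte-identical.
    """

    dose_scale: float = 1.0
    target_dose_scale: float | None = None
    oar_dose_scale: float | None = None
    gaussian_blur_mm: float = 0.0
    noise_sd_pct: float = 0.0
    dvh_shift_gy: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_pct < 0 or self.gaussian_blur_mm < 0:
            raise ValidationError("noise_sd_pct and gaussian_blur_mm must be >= 0")
        for name in ("dose_scale", "target_dose_scale", "oar_dose_scale"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ValidationError(f"{name} must be positive")

    def scale_for(self, structure_label: str) -> float:
        if _TARGET_RE.search(structure_label):
            return self.target_dose_scale if self.target_dose_scale is not None else self.dose_scale
        return self.oar_dose_scale if self.oar_dose_scale is not None else self.dose_scale

    @property
    def is_identity(self) -> bool:
        return (
            self.dose_scale == 1.0
            and self.target_dose_scale in (None, 1.0)
            and self.oar_dose_scale in (None, 1.0)
            and self.gaussian_blur_mm == 0.0
            and self.noise_sd_pct == 0.0
            and self.dvh_shift_gy == 0.0
        )


@dataclass(frozen=True)
class SyntheticPatient:
    """One generated plan-verification case."""

    patient_id: str
    site: str
    prescription: Prescription
    planned: DVHFile
    measured: DVHFile
    planned_grid: DoseGrid | None = None
    measured_grid: DoseGrid | None = None
    seed: int = 0


def _ptv_dvh(label: str, rx: float, rng: np.random.Generator) -> DVH:
    """Narrow truncated-normal differential DVH centred near prescription."""
    mean = rx * (1.0 + rng.uniform(-0.01, 0.01))
    sd = rx * rng.uniform(0.015, 0.03)
    lo, hi = rx * 0.85, rx * 1.10
    edges = np.linspace(lo, hi, 121)
    cdf = truncnorm.cdf(edges, (lo - mean) / sd, (hi - mean) / sd, loc=mean, scale=sd)
    dv = np.diff(cdf)
    return DVH(label, DVHForm.DIFFERENTIAL, edges[:-1], dv)


def _oar_dvh(label: str, rx: float, rng: np.random.Generator) -> DVH:
    """Sigmoid-decay cumulative DVH from full volume at 0 Gy to ~0 near Rx."""
    d_half = rx * rng.uniform(0.15, 0.6)
    k = rng.uniform(2.5, 6.0)
    doses = np.linspace(0.0, 1.02 * rx, 150)
    v = 1.0 / (1.0 + (doses / d_half) ** k)
    v = (v - v[-1]) / (1.0 - v[-1])  # pin V(0)=1, V(max)=0, still monotone
    return DVH(label, DVHForm.CUMULATIVE, doses, v)


def make_planned_dvh_set(site: str, prescription: Prescription, seed: int) -> DVHFile:
    """Generate a planning-system DVH set for one patient (deterministic in
    ``seed``)."""
    if site not in SITE_STRUCTURES:
        raise ValidationError(f"unknown site {site!r}")
    rng = np.random.default_rng(seed)
    structures = []
    for label in SITE_STRUCTURES[site]:
        if _TARGET_RE.search(label):
            # low-risk head-neck target sits at ~77% of the high-risk dose
            rx = prescription.total_dose_gy * (0.77 if "5400" in label else 1.0)
            structures.append(_ptv_dvh(label, rx, rng))
        else:
            structures.append(_oar_dvh(label, prescription.total_dose_gy, rng))
    return DVHFile(
        plan_label=f"{site}-synthetic",
        source="planning_system",
        prescription=prescription,
        structures=tuple(structures),
    )


def perturb_to_measured(planned: DVHFile, spec: PerturbationSpec) -> DVHFile:
    """Apply the discrepancy model to a planned DVH set.

    Bin doses are scaled and shifted (clamped at 0; duplicate clamped bins
    merged); multiplicative noise enters as a per-structure dose-scale
    draw, keeping each curve monotone as a real reconstructed DVH is.
    """
    rng = np.random.default_rng(spec.seed)
    structures = []
    for s in planned.structures:
        scale = spec.scale_for(s.structure_label)
        if spec.noise_sd_pct > 0:
            scale *= 1.0 + rng.normal(0.0, spec.noise_sd_pct / 100.0)
            scale = max(scale, 1e-3)
        doses = np.maximum(s.bin_doses * scale + spec.dvh_shift_gy, 0.0)
        vols = s.volumes
        if doses.size > 1 and np.any(np.diff(doses) <= 0):
            # clamping at 0 collapsed leading bins; merge them
            doses, inverse = np.unique(doses, return_inverse=True)
            if s.form is DVHForm.DIFFERENTIAL:
                merged = np.zeros_like(doses)
                np.add.at(merged, inverse, vols)
                vols = merged
            else:
                keep = np.zeros_like(doses)
                np.maximum.at(keep, inverse, vols)
                vols = keep
        structures.append(DVH(s.structure_label, s.form, doses, vols))
    return DVHFile(
        plan_label=planned.plan_label,
        source="measurement_reconstruction",
        prescription=planned.prescription,
        structures=tuple(structures),
    )


def make_grid_pair(
    shape: tuple[int, int, int] = (16, 20, 20),
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5),
    spec: PerturbationSpec = PerturbationSpec(),
    peak_dose: float = 10.0,
    n_blobs: int = 3,
) -> tuple[DoseGrid, DoseGrid]:
    """Generate a (planned, measured) dose-grid pair.

    The planned grid is ``n_blobs`` Gaussian dose blobs on a 15%-of-peak
    bath, normalized to ``peak_dose``; the measured grid applies the
    perturbation spec (scale, then blur, then voxel noise).
    """
    if min(shape) < 8:
        raise ValidationError("grid shape must be at least 8 voxels per axis")
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = shape
    dx, dy, dz = spacing
    z, y, x = np.meshgrid(
        np.arange(nz) * dz, np.arange(ny) * dy, np.arange(nx) * dx, indexing="ij"
    )
    extent = np.array([nx * dx, ny * dy, nz * dz])
    planned = np.full(shape, 0.15)
    for _ in range(n_blobs):
        cx, cy, cz = rng.uniform(0.30, 0.70, size=3) * extent
        sigma = rng.uniform(8.0, 15.0)
        r2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
        planned += rng.uniform(0.5, 1.0) * np.exp(-r2 / (2.0 * sigma**2))
    planned *= peak_dose / planned.max()

    measured = planned * spec.dose_scale
    if spec.gaussian_blur_mm > 0:
        measured = gaussian_filter(
            measured, sigma=[spec.gaussian_blur_mm / s for s in (dz, dy, dx)]
        )
    if spec.noise_sd_pct > 0:
        measured = measured * (
            1.0 + rng.normal(0.0, spec.noise_sd_pct / 100.0, size=shape)
        )
    measured = np.maximum(measured, 0.0)
    return (
        DoseGrid(planned, spacing),
        DoseGrid(measured, spacing),
    )


def make_cohort(
    site: str,
    n_patients: int,
    spec: PerturbationSpec = PerturbationSpec(),
    seed: int = 0,
    include_grids: bool = True,
    grid_shape: tuple[int, int, int] = (16, 20, 20),
) -> list[SyntheticPatient]:
    """Generate a reproducible synthetic cohort for one treatment group.

    Prescriptions are drawn uniformly from the group's dose range with the
    fraction count chosen nearest 2 Gy/fraction inside the group's fraction
    range.  The same perturbation knobs apply to every patient, but each
    patient receives its own spawned child seed.
    """
    if n_patients < 1:
        raise ValidationError("n_patients must be >= 1")
    (d_lo, d_hi), (f_lo, f_hi) = PRESCRIPTION_RANGES[site]
    children = np.random.SeedSequence(seed).spawn(n_patients)
    patients = []
    for i, child in enumerate(children):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(child_seed)
        rx = float(np.round(rng.uniform(d_lo, d_hi), 2))
        n_fx = int(np.clip(round(rx / 2.0), f_lo, f_hi))
        prescription = Prescription(rx, n_fx)
        planned = make_planned_dvh_set(site, prescription, seed=child_seed)
        pspec = dataclasses.replace(spec, seed=child_seed)
        measured = perturb_to_measured(planned, pspec)
        planned_grid = measured_grid = None
        if include_grids:
            planned_grid, measured_grid = make_grid_pair(grid_shape, spec=pspec)
        patients.append(
            SyntheticPatient(
                patient_id=f"{site}-{i + 1:03d}",
                site=site,
                prescription=prescription,
                planned=planned,
                measured=measured,
                planned_grid=planned_grid,
                measured_grid=measured_grid,
                seed=child_seed,
            )
        )
    return patients


def write_cohort(patients: list[SyntheticPatient], out_dir) -> Path:
    """Write a cohort to disk (generic_csv DVHs, CSV+JSON grids, JSON
    manifest); returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"site": patients[0].site if patients else None, "patients": []}
    for p in patients:
        entry: dict = {
            "patient_id": p.patient_id,
            "site": p.site,
            "seed": p.seed,
            "prescription_gy": p.prescription.total_dose_gy,
            "n_fractions": p.prescription.n_fractions,
            "planned_dvh": f"{p.patient_id}_planned.csv",
            "measured_dvh": f"{p.patient_id}_measured.csv",
        }
        write_dvh_file(p.planned, out_dir / entry["planned_dvh"])
        write_dvh_file(p.measured, out_dir / entry["measured_dvh"])
        if p.planned_grid is not None:
            entry["planned_grid"] = f"{p.patient_id}_planned_grid.csv"
            entry["measured_grid"] = f"{p.patient_id}_measured_grid.csv"
            save_dose_grid(p.planned_grid, out_dir / entry["planned_grid"])
            save_dose_grid(p.measured_grid, out_dir / entry["measured_grid"])
        manifest["patients"].append(entry)
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_cohort(manifest_path) -> list[SyntheticPatient]:
    """Load a cohort previously written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    patients = []
    for entry in manifest["patients"]:
        planned = read_dvh_file(base / entry["planned_dvh"])
        measured = read_dvh_file(base / entry["measured_dvh"])
        pg = mg = None
        if "planned_grid" in entry:
            pg = load_dose_grid(base / entry["planned_grid"])
            mg = load_dose_grid(base / entry["measured_grid"])
        patients.append(
            SyntheticPatient(
                patient_id=entry["patient_id"],
                site=entry["site"],
                prescription=Prescription(
                    entry["prescription_gy"], entry["n_fractions"]
                ),
                planned=planned,
                measured=measured,
                planned_grid=pg,
                measured_grid=mg,
                seed=entry.get("seed", 0),
            )
        )
    return patients
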