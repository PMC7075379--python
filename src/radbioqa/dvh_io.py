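"""Reading, writing and converting dose-volume histograms.

Two plain-text dialects are supported:

``generic_csv``
    File-level comment headers (``# plan_label=``, ``# source=``,
    ``# prescription_gy=``, ``# n_fractions=``) followed by one block per
    structure: ``# structure=<label>``, ``# form=<cumulative|differential>``,
    ``# dose_unit=<Gy|cGy>`` and two-column ``dose,volume_fraction`` rows.

``wide_csv``
    The same file-level headers plus a single ``# form=`` declaration, then
    a header row ``dose,<label>,<label>,...`` and one column per structure.

Dose units are Gy throughout the package; cGy inputs are converted at read
time when the header declares them — units are never inferred from
magnitudes.  Differential bins carry their left-edge dose; cumulative
``V(D)`` is the volume fraction receiving at least ``D``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .rb_core import DVH, DVHForm, FractionSchedule, ValidationError

__all__ = [
    "Prescription",
    "DVHFile",
    "DVHParseError",
    "read_dvh_file",
    "write_dvh_file",
    "cumulative_to_differential",
    "differential_to_cumulative",
    "dvh_from_dose_grid",
]


class DVHParseError(ValidationError):
    """Malformed DVH file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class Prescription:
    """Prescribed total dose (Gy) and fraction count of a plan."""

    total_dose_gy: float
    n_fractions: int

    def __post_init__(self) -> None:
        if not self.total_dose_gy > 0:
            raise ValidationError("prescription total dose must be positive")
        FractionSchedule(self.n_fractions)  # validates

    @property
    def schedule(self) -> FractionSchedule:
        return FractionSchedule(self.n_fractions)


@dataclass(frozen=True)
class DVHFile:
    """A set of per-structure DVHs from one dose source for one plan.

    ``source`` distinguishes the treatment-planning-system computation from
    the measurement-reconstructed dose.
    """

    plan_label: str
    source: str  # "planning_system" | "measurement_reconstruction"
    prescription: Prescription
    structures: tuple[DVH, ...]

    def __post_init__(self) -> None:
        if self.source not in ("planning_system", "measurement_reconstruction"):
            raise ValidationError(f"unknown DVH source {self.source!r}")
        labels = [s.structure_label for s in self.structures]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise ValidationError(f"duplicate structure labels: {sorted(dupes)}")

    @property
    def structure_labels(self) -> tuple[str, ...]:
        return tuple(s.structure_label for s in self.structures)

    def structure(self, label: str) -> DVH:
        for s in self.structures:
            if s.structure_label == label:
                return s
        raise KeyError(label)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _parse_header(line: str) -> tuple[str, str] | None:
    body = line[1:].strip()
    if "=" not in body:
        return None
    key, _, value = body.partition("=")
    return key.strip().lower(), value.strip()


def _finish_structure(label, form, unit, doses, vols, start_line):
    if label is None:
        raise DVHParseError("data rows before any '# structure=' header", start_line)
    if form is None:
        raise DVHParseError(
            f"structure {label!r} missing '# form=' declaration; the form is "
            "never guessed from the data shape",
            start_line,
        )
    scale = 0.01 if unit == "cgy" else 1.0
    try:
        return DVH(label, DVHForm(form), np.asarray(doses) * scale, np.asarray(vols))
    except ValidationError as err:
        raise DVHParseError(f"structure starting here: {err}", start_line) from None


def read_dvh_file(path, dialect: str = "generic_csv") -> DVHFile:
    """Read a DVH text file; validation errors carry line numbers."""
    path = Path(path)
    text = path.read_text()
    if dialect == "generic_csv":
        return _read_generic_csv(text)
    if dialect == "wide_csv":
        return _read_wide_csv(text)
    raise ValidationError(f"unknown dialect {dialect!r}")


def _read_generic_csv(text: str) -> DVHFile:
    meta: dict[str, str] = {}
    structures: list[DVH] = []
    label = form = None
    unit = "gy"
    doses: list[float] = []
    vols: list[float] = []
    block_start: int | None = None

    def close_block():
        nonlocal label, form, unit, doses, vols, block_start
        if label is not None:
            structures.append(
                _finish_structure(label, form, unit, doses, vols, block_start)
            )
        label = form = None
        unit = "gy"
        doses, vols = [], []
        block_start = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            parsed = _parse_header(line)
            if parsed is None:
                continue
            key, value = parsed
            if key == "structure":
                close_block()
                label, block_start = value, lineno
            elif key == "form":
                form = value.lower()
            elif key == "dose_unit":
                unit = value.lower()
                if unit not in ("gy", "cgy"):
                    raise DVHParseError(f"unknown dose unit {value!r}", lineno)
            else:
                meta[key] = value
            continue
        parts = [p for p in line.replace("\t", ",").split(",") if p.strip()]
        if len(parts) != 2:
            raise DVHParseError(f"expected 'dose,volume_fraction', got {raw!r}", lineno)
        try:
            doses.append(float(parts[0]))
            vols.append(float(parts[1]))
        except ValueError:
            raise DVHParseError(f"non-numeric row {raw!r}", lineno) from None
    close_block()
    return _assemble(meta, structures)


def _read_wide_csv(text: str) -> DVHFile:
    meta: dict[str, str] = {}
    data_lines: list[str] = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            parsed = _parse_header(line)
            if parsed:
                meta[parsed[0]] = parsed[1]
            continue
        data_lines.append(line)
    if not data_lines:
        raise DVHParseError("no data rows")
    form = meta.pop("form", None)
    if form is None:
        raise DVHParseError("wide_csv requires a single '# form=' declaration")
    unit = meta.pop("dose_unit", "Gy").lower()
    scale = 0.01 if unit == "cgy" else 1.0
    frame = pd.read_csv(io.StringIO("\n".join(data_lines)))
    if frame.shape[1] < 2:
        raise DVHParseError("wide_csv needs a dose column plus >=1 structure column")
    doses = frame.iloc[:, 0].to_numpy(dtype=float) * scale
    structures = [
        DVH(str(col), DVHForm(form.lower()), doses, frame[col].to_numpy(dtype=float))
        for col in frame.columns[1:]
    ]
    return _assemble(meta, structures)


def _assemble(meta: dict[str, str], structures: list[DVH]) -> DVHFile:
    if not structures:
        raise DVHParseError("file contains no structures")
    for key in ("prescription_gy", "n_fractions"):
        if key not in meta:
            raise DVHParseError(f"missing file header '# {key}='")
    return DVHFile(
        plan_label=meta.get("plan_label", "unnamed"),
        source=meta.get("source", "planning_system"),
        prescription=Prescription(
            float(meta["prescription_gy"]), int(meta["n_fractions"])
        ),
        structures=tuple(structures),
    )


def write_dvh_file(dvh_file: DVHFile, path) -> None:
    """Write the ``generic_csv`` dialect (round-trips with read_dvh_file)."""
    lines = [
        f"# plan_label={dvh_file.plan_label}",
        f"# source={dvh_file.source}",
        f"# prescription_gy={dvh_file.prescription.total_dose_gy!r}",
        f"# n_fractions={dvh_file.prescription.n_fractions}",
    ]
    for s in dvh_file.structures:
        lines.append(f"# structure={s.structure_label}")
        lines.append(f"# form={s.form.value}")
        lines.append("# dose_unit=Gy")
        for d, v in zip(s.bin_doses, s.volumes):
            lines.append(f"{float(d)!r},{float(v)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# conversions
# ---------------------------------------------------------------------------

def cumulative_to_differential(dvh: DVH) -> DVH:
    """Difference a cumulative DVH into fractional subvolumes.

    ``dv_i = V(D_i) - V(D_{i+1})`` is assigned to the bin's left-edge dose
    ``D_i``; the last bin keeps its full remaining volume ``V(D_last)``.
    The differential constructor renormalizes to sum to 1.
    """
    if dvh.form is not DVHForm.CUMULATIVE:
        raise ValidationError(f"{dvh.structure_label!r}: expected cumulative form")
    v = dvh.volumes
    dv = np.append(-np.diff(v), v[-1])
    if dv.sum() <= 0:
        raise ValidationError(
            f"{dvh.structure_label!r}: cumulative DVH carries zero volume"
        )
    return DVH(dvh.structure_label, DVHForm.DIFFERENTIAL, dvh.bin_doses, dv)


def differential_to_cumulative(dvh: DVH) -> DVH:
    """Reverse cumulative sum: ``V(D_i) = sum_{j >= i} dv_j`` (non-increasing)."""
    if dvh.form is not DVHForm.DIFFERENTIAL:
        raise ValidationError(f"{dvh.structure_label!r}: expected differential form")
    v = np.cumsum(dvh.volumes[::-1])[::-1]
    return DVH(dvh.structure_label, DVHForm.CUMULATIVE, dvh.bin_doses, v)


def as_differential(dvh: DVH) -> DVH:
    """Return the DVH in differential form, converting if necessary."""
    if dvh.form is DVHForm.DIFFERENTIAL:
        return dvh
    return cumulative_to_differential(dvh)


def dvh_from_dose_grid(grid, mask, bin_width: float = 0.1, label: str = "structure") -> DVH:
    """Histogram the masked voxels of a dose grid into a differential DVH.

    ``mask`` is a boolean array of the grid's shape selecting the structure;
    ``bin_width`` (Gy) sets the dose resolution; bins carry their left edge.
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    values = np.asarray(grid.values if hasattr(grid, "values") else grid, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != values.shape:
        raise ValidationError("mask shape must match the dose grid shape")
    doses = values[mask]
    if doses.size == 0:
        raise ValidationError("empty structure mask")
    idx = np.floor(doses / bin_width).astype(int)
    counts = np.bincount(idx)
    occupied = counts > 0
    bin_doses = np.nonzero(occupied)[0] * bin_width
    return DVH(label, DVHForm.DIFFERENTIAL, bin_doses, counts[occupied])
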