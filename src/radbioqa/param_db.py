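"""Bundled radiobiological parameter tables and structure-name resolution.

A :class:`ParamTable` holds validated :class:`~radbioqa.rb_core.ResponseParams`
per organ for one treatment group.  Tables for the brain, head-neck, lung
and pelvis/prostate groups ship with the package as YAML files; users can
load their own files to override or extend individual organs.

DVH exports name structures in clinic-specific ways ("Rt. parotid",
"PTV7000", "penile_bulb"); :class:`StructureMapping` resolves those labels
onto table organs via ordered, case-insensitive regular-expression rules
(first match wins, unmatched labels are reported rather than dropped).
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .rb_core import ResponseParams, TissueClass, ValidationError

__all__ = [
    "SITES",
    "ParamTable",
    "StructureMapping",
    "load_site",
    "load_param_file",
    "write_param_file",
    "default_mapping",
    "match_structures",
]

#: Treatment groups with bundled tables.  pelvis and prostate share one
#: parameter group (they differ only in which target row applies).
SITES = ("brain", "head_neck", "lung", "pelvis", "prostate")

_SITE_FILES = {
    "brain": "brain.yaml",
    "head_neck": "head_neck.yaml",
    "lung": "lung.yaml",
    "pelvis": "pelvis_prostate.yaml",
    "prostate": "pelvis_prostate.yaml",
}


class OrganNotFoundError(KeyError):
    """Lookup of an organ absent from a parameter table."""


@dataclass(frozen=True)
class ParamTable:
    """Validated parameter sets for one treatment group."""

    site: str
    entries: tuple[ResponseParams, ...]
    provenance: Mapping[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [e.organ_label for e in self.entries]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise ValidationError(
                f"duplicate organ labels in {self.site!r} table: {sorted(dupes)}"
            )

    @property
    def organ_labels(self) -> tuple[str, ...]:
        return tuple(e.organ_label for e in self.entries)

    def lookup(self, organ_label: str) -> ResponseParams:
        """Return the parameter set for ``organ_label`` (exact, case-insensitive)."""
        for entry in self.entries:
            if entry.organ_label.lower() == organ_label.lower():
                return entry
        raise OrganNotFoundError(
            f"organ {organ_label!r} not in {self.site!r} table; available: "
            f"{', '.join(self.organ_labels)}"
        )

    def merged(self, override: "ParamTable") -> "ParamTable":
        """New table where ``override`` entries replace/extend this table's."""
        by_label = {e.organ_label.lower(): e for e in self.entries}
        for entry in override.entries:
            by_label[entry.organ_label.lower()] = entry
        provenance = dict(self.provenance)
        provenance.update(override.provenance)
        return ParamTable(self.site, tuple(by_label.values()), provenance)


def _entry_from_record(record: Mapping, where: str) -> ResponseParams:
    required = ("organ", "tissue_class", "d50_gy", "gamma", "alpha_beta_gy")
    for fieldname in required:
        if record.get(fieldname) is None:
            raise ValidationError(f"{where}: missing required field {fieldname!r}")
    tissue = TissueClass(record["tissue_class"])
    seriality = record.get("seriality")
    if tissue is TissueClass.NORMAL and seriality is None:
        raise ValidationError(
            f"{where}: normal tissue requires a seriality value"
        )
    try:
        return ResponseParams(
            organ_label=str(record["organ"]),
            tissue_class=tissue,
            d50=float(record["d50_gy"]),
            gamma_slope=float(record["gamma"]),
            alpha_beta=float(record["alpha_beta_gy"]),
            seriality=None if seriality is None else float(seriality),
            endpoint=str(record.get("endpoint", "")),
            alpha=None if record.get("alpha") is None else float(record["alpha"]),
        )
    except ValidationError as err:
        raise ValidationError(f"{where}: {err}") from None


def _table_from_mapping(doc: Mapping, origin: str) -> ParamTable:
    if not isinstance(doc, Mapping) or "entries" not in doc or "site" not in doc:
        raise ValidationError(
            f"{origin}: parameter file must contain 'site' and 'entries'"
        )
    entries = []
    provenance = {}
    for i, record in enumerate(doc["entries"]):
        where = f"{origin}, entry {i + 1} ({record.get('organ', '?')})"
        entry = _entry_from_record(record, where)
        entries.append(entry)
        if record.get("provenance"):
            provenance[entry.organ_label] = str(record["provenance"])
    return ParamTable(str(doc["site"]), tuple(entries), provenance)


def load_param_file(path) -> ParamTable:
    """Load and validate a YAML parameter file (see the bundled files for the
    schema: ``site`` plus a list of ``entries`` with fields ``organ``,
    ``tissue_class``, ``d50_gy``, ``gamma``, ``alpha``, ``alpha_beta_gy``,
    ``seriality``, ``endpoint``, ``provenance``)."""
    path = Path(path)
    with path.open() as fh:
        doc = yaml.safe_load(fh)
    return _table_from_mapping(doc, str(path))


def write_param_file(table: ParamTable, path) -> None:
    """Serialize a table back to the YAML schema (round-trips exactly)."""
    records = []
    for e in table.entries:
        records.append(
            {
                "organ": e.organ_label,
                "tissue_class": e.tissue_class.value,
                "d50_gy": e.d50,
                "gamma": e.gamma_slope,
                "alpha": e.alpha,
                "alpha_beta_gy": e.alpha_beta,
                "seriality": e.seriality,
                "endpoint": e.endpoint,
                "provenance": table.provenance.get(e.organ_label),
            }
        )
    doc = {"site": table.site, "entries": records}
    with Path(path).open("w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)


def load_site(site: str, override_path=None) -> ParamTable:
    """Load the bundled table for a treatment group, optionally overridden.

    ``override_path`` points to a user YAML file whose organs replace or
    extend the bundled ones (only the named organs change).
    """
    if site not in _SITE_FILES:
        raise ValidationError(
            f"unknown site {site!r}; available: {', '.join(SITES)}"
        )
    ref = resources.files("radbioqa.data") / "params" / _SITE_FILES[site]
    doc = yaml.safe_load(ref.read_text())
    table = _table_from_mapping(doc, _SITE_FILES[site])
    table = ParamTable(site, table.entries, table.provenance)
    if override_path is not None:
        table = table.merged(load_param_file(override_path))
    return table


def load_all_sites() -> dict[str, ParamTable]:
    """All bundled tables keyed by site (pelvis/prostate share rows)."""
    return {site: load_site(site) for site in SITES}


# ---------------------------------------------------------------------------
# structure-name resolution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StructureMapping:
    """Ordered (regex pattern -> organ label) rules; first match wins.

    Patterns are matched case-insensitively with ``re.search``, so clinic
    conventions like laterality prefixes ("Rt. optic nerve") and dose-level
    suffixes ("PTV7000") resolve to their table organ.
    """

    rules: tuple[tuple[str, str], ...]

    def resolve(self, label: str) -> str | None:
        for pattern, organ in self.rules:
            if re.search(pattern, label, flags=re.IGNORECASE):
                return organ
        return None


_DEFAULT_RULES: dict[str, tuple[tuple[str, str], ...]] = {
    "brain": (
        (r"brain\s*stem", "Brainstem"),
        (r"chiasm|optic", "Chiasm/optic nerve"),
        (r"spinal|cord", "Spinal cord"),
        (r"ptv|gtv|ctv", "PTV"),
        (r"brain", "Brain"),
    ),
    "head_neck": (
        (r"parotid", "Parotid gland"),
        (r"mandible|jaw", "Mandible"),
        (r"brachial", "Brachial plexus"),
        (r"spinal|cord", "Spinal cord"),
        (r"ptv\s*_?70|high", "PTV7000"),
        (r"ptv\s*_?54|low", "PTV5400"),
    ),
    "lung": (
        (r"esoph", "Esophagus"),
        (r"heart", "Heart"),
        (r"spinal|cord", "Spinal cord"),
        (r"ptv|gtv|itv", "PTV"),
        (r"lung", "Lung"),
    ),
    "pelvis": (
        (r"bladder", "Bladder"),
        (r"rectum", "Rectum"),
        (r"sigmoid", "Sigmoid"),
        (r"bowel", "Bowel"),
        (r"penile", "Penile bulb"),
        (r"femur|femoral", "Femur head"),
        (r"ptv|ctv", "PTV6000"),
    ),
    "prostate": (
        (r"bladder", "Bladder"),
        (r"rectum", "Rectum"),
        (r"sigmoid", "Sigmoid"),
        (r"penile", "Penile bulb"),
        (r"femur|femoral", "Femur head"),
        (r"ptv|ctv", "PTV7920"),
    ),
}


def default_mapping(site: str) -> StructureMapping:
    """Bundled mapping covering common clinic naming for a treatment group."""
    if site not in _DEFAULT_RULES:
        raise ValidationError(
            f"no default structure mapping for site {site!r}"
        )
    return StructureMapping(_DEFAULT_RULES[site])


def match_structures(
    dvh_labels: Sequence[str],
    mapping: StructureMapping,
    table: ParamTable,
) -> tuple[dict[str, ResponseParams], list[str]]:
    """Resolve DVH structure labels to parameter sets.

    Returns ``(matched, unmatched)``: a deterministic label -> params map
    plus the labels no rule (or no table organ) covered.  Unmatched labels
    are reported, never silently dropped.
    """
    matched: dict[str, ResponseParams] = {}
    unmatched: list[str] = []
    for label in dvh_labels:
        organ = mapping.resolve(label)
        if organ is None:
            unmatched.append(label)
            continue
        try:
            matched[label] = table.lookup(organ)
        except OrganNotFoundError:
            unmatched.append(label)
    return matched, unmatched
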