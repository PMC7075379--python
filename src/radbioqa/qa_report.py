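"""Plan-level radiobiological evaluation, planned-vs-measured deltas, and
cohort aggregation.

The verification workflow: evaluate the treatment-planning-system DVH set
and the measurement-reconstructed DVH set with the same parameter table,
take per-structure and plan-level differences (measured minus planned —
the planning-system values are the reference), optionally attach gamma
pass rates, and aggregate a cohort into mean +/- sd summaries.  A positive
``delta_p_plus`` means the delivered plan achieves higher complication-free
tumour control than the computed plan.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import rb_core
from .dvh_io import DVHFile, as_differential
from .param_db import ParamTable, StructureMapping, default_mapping, match_structures
from .rb_core import (
    PlanMetrics,
    StructureMetric,
    TissueClass,
    ValidationError,
    eqd2,
)

__all__ = [
    "DeltaMetrics",
    "CohortSummary",
    "GammaDeltaCorrelation",
    "evaluate_plan",
    "compare_plans",
    "compare_plan_files",
    "summarize_cohort",
    "correlate_gamma_vs_delta",
]


@dataclass(frozen=True)
class StructureDelta:
    metric_kind: str
    planned: float
    measured: float

    @property
    def delta(self) -> float:
        return self.measured - self.planned


@dataclass(frozen=True)
class DeltaMetrics:
    """Measured-minus-planned differences for one plan pair.

    Plan-level probabilities are recomputed over the *common* structure set
    so the comparison stays paired; structures present on only one side are
    listed, never silently dropped.
    """

    per_structure: dict[str, StructureDelta]
    p_injury_planned: float
    p_injury_measured: float
    p_benefit_planned: float
    p_benefit_measured: float
    only_planned: tuple[str, ...] = ()
    only_measured: tuple[str, ...] = ()
    gamma_33_pass_pct: float | None = None
    gamma_22_pass_pct: float | None = None
    patient_id: str = ""

    @property
    def p_plus_planned(self) -> float:
        return self.p_benefit_planned - self.p_injury_planned

    @property
    def p_plus_measured(self) -> float:
        return self.p_benefit_measured - self.p_injury_measured

    @property
    def delta_p_injury(self) -> float:
        return self.p_injury_measured - self.p_injury_planned

    @property
    def delta_p_benefit(self) -> float:
        return self.p_benefit_measured - self.p_benefit_planned

    @property
    def delta_p_plus(self) -> float:
        return self.delta_p_benefit - self.delta_p_injury

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "per_structure": {
                label: {
                    "metric_kind": sd.metric_kind,
                    "planned": sd.planned,
                    "measured": sd.measured,
                    "delta": sd.delta,
                }
                for label, sd in self.per_structure.items()
            },
            "p_plus_planned": self.p_plus_planned,
            "p_plus_measured": self.p_plus_measured,
            "delta_p_injury": self.delta_p_injury,
            "delta_p_benefit": self.delta_p_benefit,
            "delta_p_plus": self.delta_p_plus,
            "only_planned": list(self.only_planned),
            "only_measured": list(self.only_measured),
            "gamma_33_pass_pct": self.gamma_33_pass_pct,
            "gamma_22_pass_pct": self.gamma_22_pass_pct,
        }


@dataclass(frozen=True)
class CohortSummary:
    """Mean +/- sample sd of P+ and gamma pass rates over a cohort.

    All P+ quantities are on the percent scale.  Standard deviations use
    the n-1 convention and are ``None`` (undefined), not 0, when n < 2.
    """

    site: str
    n: int
    mean_p_plus_measured: float
    sd_p_plus_measured: float | None
    mean_p_plus_planned: float
    sd_p_plus_planned: float | None
    mean_delta_p_plus: float
    sd_delta_p_plus: float | None
    mean_gamma_33: float | None = None
    sd_gamma_33: float | None = None
    mean_gamma_22: float | None = None
    sd_gamma_22: float | None = None


@dataclass(frozen=True)
class GammaDeltaCorrelation:
    """Least-squares fit of |delta P+| against the gamma pass rate."""

    slope: float
    intercept: float
    r_squared: float
    n: int


def evaluate_plan(
    dvhs: DVHFile,
    table: ParamTable,
    mapping: StructureMapping | None = None,
) -> PlanMetrics:
    """Score every matched structure and aggregate to plan level.

    Targets get TCP, organs at risk get relative-seriality NTCP; the plan's
    probability of injury pools all matched OARs, the probability of
    benefit pools all matched targets, and ``p_plus`` is their difference.
    Unmatched structure labels are carried in the result.  A plan with no
    matched target is rejected: P+ is undefined without one.
    """
    if mapping is None:
        mapping = default_mapping(table.site)
    matched, unmatched = match_structures(dvhs.structure_labels, mapping, table)
    schedule = dvhs.prescription.schedule
    per_structure: dict[str, StructureMetric] = {}
    tcps, ntcps = [], []
    for label, params in matched.items():
        dvh = as_differential(dvhs.structure(label))
        d2_mean = float(
            np.dot(eqd2(dvh.bin_doses, schedule, params.alpha_beta), dvh.volumes)
        )
        if params.tissue_class is TissueClass.TUMOR:
            value = rb_core.tcp(dvh, schedule, params)
            tcps.append(value)
            kind = "tcp"
        else:
            value = rb_core.ntcp(dvh, schedule, params)
            ntcps.append(value)
            kind = "ntcp"
        per_structure[label] = StructureMetric(
            metric_kind=kind,
            probability=value,
            mean_eqd2=d2_mean,
            endpoint=params.endpoint,
        )
    if not tcps:
        raise ValidationError(
            "no structure matched a target (tumour) entry; P+ is undefined "
            f"without a target (unmatched labels: {unmatched})"
        )
    return PlanMetrics(
        per_structure=per_structure,
        p_injury=rb_core.probability_injury(ntcps),
        p_benefit=rb_core.probability_benefit(tcps),
        unmatched=tuple(unmatched),
    )


def compare_plans(planned: PlanMetrics, measured: PlanMetrics) -> DeltaMetrics:
    """Measured-minus-planned deltas over the common structure set.

    Plan-level P_I/P_B/P+ are re-pooled from the per-structure values of
    the common subset on both sides, so a structure the measurement system
    could not reconstruct drops out of *both* plans.
    """
    common = [l for l in planned.per_structure if l in measured.per_structure]
    if not common:
        raise ValidationError("planned and measured plans share no structures")
    only_planned = tuple(l for l in planned.per_structure if l not in measured.per_structure)
    only_measured = tuple(l for l in measured.per_structure if l not in planned.per_structure)

    per_structure: dict[str, StructureDelta] = {}
    for label in common:
        p, m = planned.per_structure[label], measured.per_structure[label]
        if p.metric_kind != m.metric_kind:
            raise ValidationError(
                f"{label!r} scored as {p.metric_kind} in one plan and "
                f"{m.metric_kind} in the other"
            )
        per_structure[label] = StructureDelta(p.metric_kind, p.probability, m.probability)

    def pool(metrics: PlanMetrics) -> tuple[float, float]:
        tcps = [metrics.per_structure[l].probability for l in common
                if metrics.per_structure[l].metric_kind == "tcp"]
        ntcps = [metrics.per_structure[l].probability for l in common
                 if metrics.per_structure[l].metric_kind == "ntcp"]
        if not tcps:
            raise ValidationError("no common target structure; P+ is undefined")
        return rb_core.probability_injury(ntcps), rb_core.probability_benefit(tcps)

    pi_p, pb_p = pool(planned)
    pi_m, pb_m = pool(measured)
    return DeltaMetrics(
        per_structure=per_structure,
        p_injury_planned=pi_p,
        p_injury_measured=pi_m,
        p_benefit_planned=pb_p,
        p_benefit_measured=pb_m,
        only_planned=only_planned,
        only_measured=only_measured,
    )


def compare_plan_files(
    planned: DVHFile,
    measured: DVHFile,
    table: ParamTable,
    mapping: StructureMapping | None = None,
    gamma_33_pass_pct: float | None = None,
    gamma_22_pass_pct: float | None = None,
    patient_id: str = "",
) -> DeltaMetrics:
    """Convenience wrapper: evaluate both DVH files and compare them."""
    delta = compare_plans(
        evaluate_plan(planned, table, mapping),
        evaluate_plan(measured, table, mapping),
    )
    return dataclasses.replace(
        delta,
        gamma_33_pass_pct=gamma_33_pass_pct,
        gamma_22_pass_pct=gamma_22_pass_pct,
        patient_id=patient_id,
    )


def _mean_sd(values: list[float]) -> tuple[float, float | None]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else None
    return mean, sd


def summarize_cohort(deltas: list[DeltaMetrics], site: str) -> CohortSummary:
    """Aggregate per-patient deltas into a cohort mean +/- sd table.

    P+ values are reported on the percent scale.  Gamma pass rates are
    summarised over the patients that carry them.
    """
    if not deltas:
        raise ValidationError("empty cohort")
    pm, sm = _mean_sd([100.0 * d.p_plus_measured for d in deltas])
    pp, sp = _mean_sd([100.0 * d.p_plus_planned for d in deltas])
    dm, ds = _mean_sd([100.0 * d.delta_p_plus for d in deltas])
    g33 = [d.gamma_33_pass_pct for d in deltas if d.gamma_33_pass_pct is not None]
    g22 = [d.gamma_22_pass_pct for d in deltas if d.gamma_22_pass_pct is not None]
    mg33, sg33 = _mean_sd(g33) if g33 else (None, None)
    mg22, sg22 = _mean_sd(g22) if g22 else (None, None)
    return CohortSummary(
        site=site,
        n=len(deltas),
        mean_p_plus_measured=pm,
        sd_p_plus_measured=sm,
        mean_p_plus_planned=pp,
        sd_p_plus_planned=sp,
        mean_delta_p_plus=dm,
        sd_delta_p_plus=ds,
        mean_gamma_33=mg33,
        sd_gamma_33=sg33,
        mean_gamma_22=mg22,
        sd_gamma_22=sg22,
    )


def correlate_gamma_vs_delta(
    gamma_pass_pct: list[float], delta_p_plus: list[float]
) -> GammaDeltaCorrelation:
    """Fit |delta P+| against the gamma pass rate and report R^2.

    R^2 is the square of the Pearson correlation of the fitted pair.
    Requires n >= 3 and non-constant pass rates (a constant regressor has
    no defined correlation).
    """
    x = np.asarray(gamma_pass_pct, dtype=float)
    y = np.abs(np.asarray(delta_p_plus, dtype=float))
    if x.size != y.size:
        raise ValidationError("gamma and delta sequences differ in length")
    if x.size < 3:
        raise ValidationError("correlation requires at least 3 patients")
    if np.ptp(x) == 0:
        raise ValidationError(
            "gamma pass rates are constant; correlation undefined"
        )
    fit = stats.linregress(x, y)
    r2 = fit.rvalue**2
    if math.isnan(r2):
        raise ValidationError("correlation undefined (zero variance in |delta P+|)")
    return GammaDeltaCorrelation(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(r2),
        n=int(x.size),
    )
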