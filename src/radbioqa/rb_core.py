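"""Dose-response modelling core: Poisson voxel response, EQD2, TCP, NTCP, P+.

The models implemented here are the standard probabilistic dose-response
machinery used to score radiotherapy treatment plans:

* a Poisson-model voxel response probability ``P(D)`` parametrised by the
  50%-response dose ``D50`` and the maximum normalized dose-response
  gradient ``gamma_slope`` (often written :math:`\\gamma`, not to be
  confused with the gamma *index* of dose comparison — see
  :mod:`radbioqa.gamma3d`);
* the linear-quadratic equivalent dose at 2 Gy per fraction (EQD2), which
  maps a total dose delivered at an arbitrary dose per fraction onto the
  2 Gy/fraction reference schedule via the tissue's :math:`\\alpha/\\beta`
  ratio;
* tumour control probability (TCP) for heterogeneous dose distributions as
  the volume-weighted product of voxel responses over differential DVH bins;
* normal tissue complication probability (NTCP) under the relative-seriality
  model, whose seriality parameter ``s`` interpolates between parallel
  (``s -> 0``) and serial (``s -> 1`` and beyond) organ architecture;
* plan-level aggregation: overall probability of injury ``P_I`` over organs
  at risk, overall probability of benefit ``P_B`` over targets, and the
  complication-free tumour control probability ``P+ = P_B - P_I``.

All probability accumulation is done in log space so that plans with many
DVH bins or extreme doses neither underflow nor overflow.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TissueClass",
    "DVHForm",
    "ResponseParams",
    "FractionSchedule",
    "DVH",
    "PlanMetrics",
    "StructureMetric",
    "eqd2",
    "voxel_response",
    "tcp",
    "ntcp",
    "probability_injury",
    "probability_benefit",
    "p_plus",
    "max_normalized_gradient",
]

#: Clamp applied to the inner exponent of the Poisson response before
#: exponentiation; +/-700 keeps exp() inside double range (exp(709) ~ 1e308).
EXP_CLAMP = 700.0

_LNLN2 = math.log(math.log(2.0))  # ln ln 2 ~ -0.3665
_E = math.e


class TissueClass(str, enum.Enum):
    """Whether a structure is scored as a target (TCP) or an OAR (NTCP)."""

    TUMOR = "tumor"
    NORMAL = "normal"


class DVHForm(str, enum.Enum):
    """Differential (fractional volume per bin) vs cumulative (V >= D)."""

    DIFFERENTIAL = "differential"
    CUMULATIVE = "cumulative"


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


@dataclass(frozen=True)
class ResponseParams:
    """Radiobiological parameter set for one organ / endpoint.

    Parameters
    ----------
    organ_label:
        Canonical organ name, e.g. ``"Lung"`` or ``"PTV7000"``.
    tissue_class:
        ``TissueClass.TUMOR`` entries are scored with TCP, ``NORMAL`` with
        the relative-seriality NTCP model.
    d50:
        Dose (Gy, EQD2) inducing the endpoint in 50% of patients.
    gamma_slope:
        Maximum normalized dose-response gradient (dimensionless).
    alpha_beta:
        Linear-quadratic alpha/beta ratio (Gy) used for the EQD2 correction.
    seriality:
        Relative-seriality parameter ``s`` (> 0); required for normal
        tissue, must be absent for tumours (TCP has no seriality).
    endpoint:
        Clinical endpoint the parameters were fitted to.
    alpha:
        Provenance-only column carried by published parameter compilations;
        not used by any computation here.
    """

    organ_label: str
    tissue_class: TissueClass
    d50: float
    gamma_slope: float
    alpha_beta: float
    seriality: float | None = None
    endpoint: str = ""
    alpha: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "tissue_class", TissueClass(self.tissue_class))
        for name in ("d50", "gamma_slope", "alpha_beta"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise ValidationError(
                    f"{self.organ_label!r}: {name} must be strictly positive, got {value!r}"
                )
        if self.tissue_class is TissueClass.TUMOR:
            if self.seriality is not None:
                raise ValidationError(
                    f"{self.organ_label!r}: tumour parameters must not carry a "
                    "seriality value (TCP has no s)"
                )
        elif self.seriality is not None and not (
            np.isfinite(self.seriality) and self.seriality > 0
        ):
            raise ValidationError(
                f"{self.organ_label!r}: seriality must be strictly positive, "
                f"got {self.seriality!r}"
            )


@dataclass(frozen=True)
class FractionSchedule:
    """Fractionation context: the plan's total number of fractions."""

    n_fractions: int

    def __post_init__(self) -> None:
        if int(self.n_fractions) != self.n_fractions or self.n_fractions < 1:
            raise ValidationError(
                f"n_fractions must be a positive integer, got {self.n_fractions!r}"
            )
        object.__setattr__(self, "n_fractions", int(self.n_fractions))

    def dose_per_fraction(self, total_dose):
        """Dose per fraction ``x = D / n`` for a bin of total dose ``D`` (Gy)."""
        return np.asarray(total_dose, dtype=float) / self.n_fractions


@dataclass(frozen=True)
class DVH:
    """Dose-volume histogram of one structure.

    ``bin_doses`` are strictly increasing total doses in Gy.  In
    differential form ``volumes[i]`` is the fractional subvolume receiving
    ``bin_doses[i]`` (left-edge bin convention; normalized to sum to 1 on
    construction).  In cumulative form ``volumes[i]`` is the volume fraction
    receiving at least ``bin_doses[i]`` (non-increasing, ``volumes[0] <= 1``).
    """

    structure_label: str
    form: DVHForm
    bin_doses: np.ndarray
    volumes: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "form", DVHForm(self.form))
        doses = np.asarray(self.bin_doses, dtype=float)
        vols = np.asarray(self.volumes, dtype=float)
        label = self.structure_label
        if doses.ndim != 1 or vols.shape != doses.shape or doses.size == 0:
            raise ValidationError(
                f"{label!r}: bin_doses and volumes must be equal-length 1-D arrays"
            )
        if not np.all(np.isfinite(doses)) or not np.all(np.isfinite(vols)):
            raise ValidationError(f"{label!r}: non-finite dose or volume values")
        if doses[0] < 0:
            raise ValidationError(f"{label!r}: negative dose bins")
        if doses.size > 1 and not np.all(np.diff(doses) > 0):
            raise ValidationError(f"{label!r}: bin doses must be strictly increasing")
        if np.any(vols < 0):
            raise ValidationError(f"{label!r}: negative volumes")
        if self.form is DVHForm.DIFFERENTIAL:
            total = vols.sum()
            if total <= 0:
                raise ValidationError(f"{label!r}: differential volumes sum to zero")
            if abs(total - 1.0) > 1e-12:  # idempotent: re-wrapping never reshuffles bits
                vols = vols / total
        else:
            if vols[0] > 1 + 1e-9:
                raise ValidationError(f"{label!r}: cumulative volume exceeds 1")
            if vols.size > 1 and np.any(np.diff(vols) > 1e-12):
                raise ValidationError(
                    f"{label!r}: cumulative volumes must be non-increasing"
                )
        doses.setflags(write=False)
        vols.setflags(write=False)
        object.__setattr__(self, "bin_doses", doses)
        object.__setattr__(self, "volumes", vols)

    @property
    def mean_dose(self) -> float:
        """Volume-weighted mean dose (Gy); requires differential form."""
        if self.form is not DVHForm.DIFFERENTIAL:
            raise ValidationError(
                "mean_dose requires a differential DVH; convert first"
            )
        return float(np.dot(self.bin_doses, self.volumes))


@dataclass(frozen=True)
class StructureMetric:
    """Per-structure outcome: TCP for targets, NTCP for organs at risk."""

    metric_kind: str  # "tcp" | "ntcp"
    probability: float
    mean_eqd2: float
    endpoint: str = ""


@dataclass(frozen=True)
class PlanMetrics:
    """Radiobiological scores of one evaluated plan.

    ``p_plus = p_benefit - p_injury`` holds by construction.
    """

    per_structure: dict[str, StructureMetric]
    p_injury: float
    p_benefit: float
    unmatched: tuple[str, ...] = field(default_factory=tuple)

    @property
    def p_plus(self) -> float:
        return self.p_benefit - self.p_injury


# ---------------------------------------------------------------------------
# scalar / vectorised model equations
# ---------------------------------------------------------------------------

def eqd2(total_dose, schedule: FractionSchedule, alpha_beta: float):
    """Equivalent dose at 2 Gy per fraction.

    ``EQD2 = D * (x + a/b) / (2 + a/b)`` with ``x = D / n_fractions`` the
    dose per fraction.  At exactly 2 Gy per fraction this is the identity.

    Accepts scalars or arrays of total dose (Gy).
    """
    dose = np.asarray(total_dose, dtype=float)
    if np.any(dose < 0):
        raise ValidationError("total_dose must be non-negative")
    if not alpha_beta > 0:
        raise ValidationError(f"alpha_beta must be positive, got {alpha_beta!r}")
    x = schedule.dose_per_fraction(dose)
    out = dose * (x + alpha_beta) / (2.0 + alpha_beta)
    return float(out) if np.isscalar(total_dose) else out


def _log_response(eqd2_dose, params: ResponseParams):
    """log P(D) of the Poisson response, clamped against overflow."""
    d = np.asarray(eqd2_dose, dtype=float)
    inner = _E * params.gamma_slope - (d / params.d50) * (
        _E * params.gamma_slope - _LNLN2
    )
    return -np.exp(np.clip(inner, -EXP_CLAMP, EXP_CLAMP))


def voxel_response(eqd2_dose, params: ResponseParams):
    """Poisson voxel response probability at a uniform EQD2 dose.

    ``P(D) = exp(-exp(e*g - (D/D50) * (e*g - ln ln 2)))`` with ``g`` the
    maximum normalized dose-response gradient.  ``P(D50) = 0.5`` exactly,
    ``P`` is strictly increasing in dose, and the inner exponent is clamped
    to +/-700 so that extreme doses saturate at 0 or 1 instead of
    overflowing.
    """
    d = np.asarray(eqd2_dose, dtype=float)
    if np.any(d < 0):
        raise ValidationError("eqd2_dose must be non-negative")
    out = np.exp(_log_response(d, params))
    return float(out) if np.isscalar(eqd2_dose) else out


def _differential_or_raise(dvh: DVH) -> DVH:
    if dvh.form is not DVHForm.DIFFERENTIAL:
        raise ValidationError(
            f"{dvh.structure_label!r}: a differential DVH is required; convert "
            "with dvh_io.cumulative_to_differential first"
        )
    return dvh


def tcp(dvh: DVH, schedule: FractionSchedule, params: ResponseParams) -> float:
    """Tumour control probability over a differential DVH.

    ``TCP = prod_i P(EQD2_i)^{dv_i}``, accumulated as
    ``exp(sum_i dv_i * log P_i)`` so many-bin plans cannot underflow.
    """
    if params.tissue_class is not TissueClass.TUMOR:
        raise ValidationError(
            f"{params.organ_label!r}: tcp requires tumour parameters"
        )
    dvh = _differential_or_raise(dvh)
    d2 = eqd2(dvh.bin_doses, schedule, params.alpha_beta)
    log_p = _log_response(d2, params)
    return float(np.exp(np.dot(dvh.volumes, log_p)))


def ntcp(dvh: DVH, schedule: FractionSchedule, params: ResponseParams) -> float:
    """Relative-seriality NTCP over a differential DVH.

    ``NTCP = (1 - prod_i [1 - P_i^s]^{dv_i})^(1/s)``.  For a uniformly
    irradiated whole organ (one bin, dv = 1) this reduces algebraically to
    the voxel response for every s.
    """
    if params.tissue_class is not TissueClass.NORMAL:
        raise ValidationError(
            f"{params.organ_label!r}: ntcp requires normal-tissue parameters"
        )
    s = params.seriality
    if s is None:
        raise ValidationError(
            f"{params.organ_label!r}: seriality is required for NTCP"
        )
    dvh = _differential_or_raise(dvh)
    d2 = eqd2(dvh.bin_doses, schedule, params.alpha_beta)
    log_p = _log_response(d2, params)          # log P_i <= 0
    log_ps = s * log_p                         # log P_i^s
    occupied = dvh.volumes > 0
    if np.any(log_ps[occupied] == 0.0):
        return 1.0                             # some subvolume responds surely
    # log(1 - P^s) via log1p(-exp(.)) keeps full precision for tiny P^s
    log_one_minus_ps = np.log1p(-np.exp(log_ps[occupied]))
    log_q = np.dot(dvh.volumes[occupied], log_one_minus_ps)
    if log_q == 0.0:
        return 0.0
    # NTCP = (1 - Q)^(1/s) with Q = exp(log_q)
    one_minus_q = -np.expm1(log_q)
    if one_minus_q <= 0.0:
        return 0.0
    return float(np.exp(np.log(one_minus_q) / s))


def _validated_probabilities(values: Sequence[float], what: str) -> np.ndarray:
    arr = np.asarray(list(values), dtype=float)
    if arr.size and (np.any(arr < 0) or np.any(arr > 1) or not np.all(np.isfinite(arr))):
        raise ValidationError(f"{what} values must lie in [0, 1]")
    return arr


def probability_injury(ntcp_values: Sequence[float]) -> float:
    """Overall probability of injury over organs at risk.

    ``P_I = 1 - prod_j (1 - NTCP_j)``; an empty sequence yields 0 (no
    organ at risk means no modelled injury).
    """
    arr = _validated_probabilities(ntcp_values, "NTCP")
    if arr.size == 0:
        return 0.0
    return float(-np.expm1(np.sum(np.log1p(-arr)))) if np.all(arr < 1) else 1.0


def probability_benefit(tcp_values: Sequence[float]) -> float:
    """Overall probability of benefit ``P_B = prod_j TCP_j`` over targets.

    The empty product is 1; plan-level evaluation rejects plans without a
    target before this convention can matter.
    """
    arr = _validated_probabilities(tcp_values, "TCP")
    return float(np.prod(arr)) if arr.size else 1.0


def p_plus(p_benefit: float, p_injury: float) -> float:
    """Complication-free tumour control probability ``P+ = P_B - P_I``.

    The exact expression ``P_B - P_{B and I}`` is approximated by treating
    benefit and injury as disjoint contributions; the result lies in
    [-1, 1].
    """
    for name, value in (("p_benefit", p_benefit), ("p_injury", p_injury)):
        if not (0.0 <= value <= 1.0):
            raise ValidationError(f"{name} must lie in [0, 1], got {value!r}")
    return p_benefit - p_injury


def max_normalized_gradient(
    params: ResponseParams, n_points: int = 200_001, d_max: float | None = None
) -> float:
    """Numerically recover the maximum normalized dose-response gradient.

    The normalized gradient of the dose-response curve is ``D * dP/dD``;
    its defining value — the slope parameter of the model — is attained at
    the steepest point of ``P(D)``.  This routine differentiates
    :func:`voxel_response` with central differences on a fine dose grid,
    locates the dose of maximum slope, and returns ``D * dP/dD`` there.
    Used as a consistency check that the implemented response curve really
    carries ``gamma_slope`` as its slope parameter.
    """
    if d_max is None:
        d_max = 4.0 * params.d50
    d = np.linspace(0.0, d_max, n_points)
    p = voxel_response(d, params)
    dp = np.gradient(p, d)
    i = int(np.argmax(dp))
    return float(d[i] * dp[i])
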