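"""Closed-form binary-exposure PAF estimators from summary statistics.

Three estimators are provided:

* Levin's formula, ``pi*(RR-1)/(1+pi*(RR-1))`` — exact only when the
  exposure–disease association is unconfounded (RR_U == RR_C) and there is
  no effect modification across confounder strata.
* Miettinen's case-prevalence form, ``pi_c*(RR_C-1)/RR_C`` — exact under
  confounding whenever the causal RR is constant across confounder strata
  (and, with the exposed-only causal RR, exact even under effect
  modification).
* The three-variable re-expression
  ``[pi*RR_U/(1+pi*(RR_U-1))]*(RR_C-1)/RR_C``, obtained from the
  case-prevalence form by Bayes' rule — usable when only population
  prevalence and the two relative risks are published.

The library cannot verify that a supplied RR is causal; a provenance tag on
the result records which the caller claimed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

from .errors import DomainError

__all__ = [
    "Formula",
    "PafResult",
    "SummaryInputs",
    "levin",
    "miettinen_pc",
    "miettinen_three",
    "case_prevalence_from_summary",
]


class Formula(str, Enum):
    LEVIN = "levin"
    LEVIN_UNADJUSTED = "levin_unadjusted"
    MIETTINEN_PC = "miettinen_pc"
    MIETTINEN_THREE = "miettinen_three"
    DEFINITION = "definition"
    EFFECT_MODIFICATION_BINARY = "eq10"
    EFFECT_MODIFICATION_GENERAL = "eq11"
    LEVIN_GENERAL = "levin_general"
    MIETTINEN_GENERAL = "miettinen_general"
    MIETTINEN_CASE_DENSITY = "miettinen_case_density"


@dataclass(frozen=True)
class PafResult:
    """A PAF estimate together with the formula and inputs that produced it."""

    estimate: float
    formula: Formula
    inputs: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.estimate < 1.0:
            raise DomainError(f"PAF estimate must be < 1, got {self.estimate!r}")

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "formula": self.formula.value,
            "inputs": dict(self.inputs),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def __float__(self) -> float:
        return self.estimate


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise DomainError(f"{name} must be in [0, 1], got {value!r}")


def _check_rr(name: str, value: float) -> None:
    if not value > 0.0:
        raise DomainError(f"{name} must be positive, got {value!r}")


def levin(pi: float, rr: float, *, rr_is_causal: bool = True) -> PafResult:
    """Levin's formula pi*(RR-1)/(1+pi*(RR-1)).

    ``rr_is_causal`` only sets the provenance tag: the caller decides
    whether ``rr`` is the causal RR (the usual usage) or the unadjusted RR
    (the discouraged variant whose sign can be wrong under confounding).
    """
    _check_prob("pi", pi)
    _check_rr("rr", rr)
    excess = pi * (rr - 1.0)
    tag = Formula.LEVIN if rr_is_causal else Formula.LEVIN_UNADJUSTED
    return PafResult(excess / (1.0 + excess), tag, {"pi": pi, "rr": rr})


def miettinen_pc(pi_c: float, rr_c: float) -> PafResult:
    """Miettinen's case-prevalence form pi_c*(RR_C-1)/RR_C."""
    _check_prob("pi_c", pi_c)
    _check_rr("rr_c", rr_c)
    return PafResult(
        pi_c * (rr_c - 1.0) / rr_c,
        Formula.MIETTINEN_PC,
        {"pi_c": pi_c, "rr_c": rr_c},
    )


def case_prevalence_from_summary(pi: float, rr_u: float) -> float:
    """pi_c from (pi, RR_U) by Bayes' rule: pi*RR_U/(1+pi*(RR_U-1))."""
    _check_prob("pi", pi)
    _check_rr("rr_u", rr_u)
    return pi * rr_u / (1.0 + pi * (rr_u - 1.0))


def miettinen_three(pi: float, rr_u: float, rr_c: float) -> PafResult:
    """Three-variable Miettinen form [pi*RR_U/(1+pi*(RR_U-1))]*(RR_C-1)/RR_C.

    Reduces to :func:`levin` when ``rr_u == rr_c`` (no confounding in risk
    ratio).  Exact for the definition PAF whenever the causal RR is
    constant across confounder strata.
    """
    _check_rr("rr_c", rr_c)
    pi_c = case_prevalence_from_summary(pi, rr_u)
    return PafResult(
        pi_c * (rr_c - 1.0) / rr_c,
        Formula.MIETTINEN_THREE,
        {"pi": pi, "rr_u": rr_u, "rr_c": rr_c},
    )


@dataclass(frozen=True)
class SummaryInputs:
    """Summary statistics for binary-exposure PAF estimation.

    At least one formula-sufficient set must be present: ``{pi, rr_c}`` for
    Levin, ``{pi_c, rr_c}`` for Miettinen's case-prevalence form, or
    ``{pi, rr_u, rr_c}`` for the three-variable form.  When ``pi_c`` is
    supplied alongside (``pi``, ``rr_u``) the two are cross-checked; a
    mismatch beyond 1e-6 (typically rounded published inputs) warns but the
    explicit value wins.
    """

    pi: float | None = None
    rr_u: float | None = None
    rr_c: float | None = None
    pi_c: float | None = None

    def __post_init__(self):
        if self.pi is not None:
            _check_prob("pi", self.pi)
        if self.pi_c is not None:
            _check_prob("pi_c", self.pi_c)
        if self.rr_u is not None:
            _check_rr("rr_u", self.rr_u)
        if self.rr_c is not None:
            _check_rr("rr_c", self.rr_c)
        if self.rr_c is None or (self.pi is None and self.pi_c is None):
            raise DomainError(
                "need rr_c together with pi (Levin / three-variable) "
                "or pi_c (Miettinen)"
            )
        if self.pi_c is not None and self.pi is not None and self.rr_u is not None:
            implied = case_prevalence_from_summary(self.pi, self.rr_u)
            if abs(implied - self.pi_c) > 1e-6:
                warnings.warn(
                    f"supplied pi_c={self.pi_c:g} differs from the value "
                    f"{implied:.6g} implied by (pi, rr_u); using the supplied "
                    "value (published inputs are often rounded)",
                    stacklevel=2,
                )

    @property
    def confounding_ratio(self) -> float | None:
        """C = RR_C / RR_U when both relative risks are present."""
        if self.rr_u is None or self.rr_c is None:
            return None
        return self.rr_c / self.rr_u

    def estimate_levin(self) -> PafResult:
        if self.pi is None:
            raise DomainError("Levin's formula needs pi")
        return levin(self.pi, self.rr_c)

    def estimate_miettinen(self) -> PafResult:
        """Best available Miettinen estimate: pi_c form if pi_c is supplied,
        otherwise the three-variable form (needs rr_u)."""
        if self.pi_c is not None:
            return miettinen_pc(self.pi_c, self.rr_c)
        if self.rr_u is None:
            raise DomainError(
                "Miettinen's formula needs pi_c, or rr_u to derive it from pi"
            )
        return miettinen_three(self.pi, self.rr_u, self.rr_c)
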