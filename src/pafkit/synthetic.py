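"""Seeded generators of stratified populations and exposure profiles.

Confounding is generated by the same mechanism as the packaged worked
example: a confounder shifts both the baseline disease risk and the
probability of exposure across strata, so that the unadjusted RR drifts
away from the causal RR.  Generators cover

* deterministic populations built from an explicit :class:`PopulationSpec`;
* random specs (Dirichlet stratum weights, uniform baselines and RRs) for
  property testing — every generated population satisfies the
  :class:`~pafkit.population.StratifiedPopulation` invariants;
* an analytic sweep that, for a fixed target exposure prevalence and causal
  RR, solves (by bisection over the exposure split between two strata) for
  populations realising requested confounding ratios C = RR_C/RR_U;
* smooth continuous exposure profiles (lognormal-shaped density,
  log-linear relative risks) for testing the quadrature estimators.

Randomness is isolated in this module; all other modules are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import DomainError, InfeasibleConfoundingError
from .general import ExposureProfile
from .population import StratifiedPopulation, StratumCell

__all__ = [
    "PopulationSpec",
    "make_population",
    "random_spec",
    "table1_spec",
    "sweep_confounding",
    "make_continuous_profile",
]

# keep headroom so risk * RR stays a valid probability in random draws
MAX_RISK = 0.95


@dataclass(frozen=True)
class PopulationSpec:
    """Generative description of a confounder-stratified binary-exposure
    population.

    Cell proportions are ``stratum_weight * exposure probability``;
    exposed-cell risks are ``baseline_risk * stratum_rr``.  A scalar
    ``stratum_rrs`` (or equal per-stratum values) means no effect
    modification, in which case the marginal causal RR and the causal RR
    among the exposed both equal that scalar.
    """

    stratum_weights: tuple[float, ...]
    baseline_risks: tuple[float, ...]
    stratum_rrs: tuple[float, ...]
    exposure_prevalence_by_stratum: tuple[float, ...]
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        w = tuple(float(x) for x in self.stratum_weights)
        b = tuple(float(x) for x in self.baseline_risks)
        r = (
            tuple(float(x) for x in self.stratum_rrs)
            if isinstance(self.stratum_rrs, Sequence)
            else (float(self.stratum_rrs),) * len(w)
        )
        if len(r) == 1 and len(w) > 1:
            r = r * len(w)
        p = tuple(float(x) for x in self.exposure_prevalence_by_stratum)
        n = len(w)
        if n < 1:
            raise DomainError("need at least one stratum")
        if not (len(b) == len(r) == len(p) == n):
            raise DomainError("per-stratum field lengths disagree")
        if abs(sum(w) - 1.0) > 1e-9:
            raise DomainError(f"stratum weights sum to {sum(w)!r}, not 1")
        for name, vals, lo, hi in (
            ("stratum weight", w, 0.0, 1.0),
            ("baseline risk", b, 0.0, 1.0),
            ("exposure prevalence", p, 0.0, 1.0),
        ):
            for v in vals:
                if not lo <= v <= hi:
                    raise DomainError(f"{name} {v!r} outside [{lo}, {hi}]")
        for bi, ri in zip(b, r):
            if ri < 0:
                raise DomainError(f"stratum RR must be non-negative, got {ri!r}")
            if bi * ri > 1.0 + 1e-12:
                raise DomainError(
                    f"baseline risk {bi} times stratum RR {ri} exceeds 1"
                )
        labels = self.labels or tuple(f"stratum_{i}" for i in range(n))
        if len(labels) != n:
            raise DomainError("labels length disagrees with stratum count")
        object.__setattr__(self, "stratum_weights", w)
        object.__setattr__(self, "baseline_risks", b)
        object.__setattr__(self, "stratum_rrs", r)
        object.__setattr__(self, "exposure_prevalence_by_stratum", p)
        object.__setattr__(self, "labels", tuple(labels))

    @property
    def has_effect_modification(self) -> bool:
        return len(set(self.stratum_rrs)) > 1


def make_population(spec: PopulationSpec) -> StratifiedPopulation:
    """Materialise the joint cell table a spec describes."""
    cells = []
    for label, w, b, rr, p in zip(
        spec.labels,
        spec.stratum_weights,
        spec.baseline_risks,
        spec.stratum_rrs,
        spec.exposure_prevalence_by_stratum,
    ):
        cells.append(StratumCell(label, 0, w * (1.0 - p), b))
        if p > 0:
            cells.append(StratumCell(label, 1, w * p, min(b * rr, 1.0)))
    return StratifiedPopulation(cells, normalize=True)


def table1_spec() -> PopulationSpec:
    """Spec reproducing the packaged ``table1`` example population."""
    return PopulationSpec(
        stratum_weights=(0.8, 0.2),
        baseline_risks=(0.1, 0.2),
        stratum_rrs=(1.5, 1.5),
        exposure_prevalence_by_stratum=(0.375, 0.75),
        labels=("high_activity", "low_activity"),
    )


def random_spec(
    seed: int,
    *,
    n_strata: int = 3,
    effect_modification: bool = True,
    rr_range: tuple[float, float] = (0.5, 3.0),
) -> PopulationSpec:
    """Draw a valid random spec; deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    if n_strata < 1:
        raise DomainError("need at least one stratum")
    w = rng.dirichlet(np.full(n_strata, 2.0))
    rr_lo, rr_hi = rr_range
    if effect_modification:
        rrs = rng.uniform(rr_lo, rr_hi, size=n_strata)
    else:
        rrs = np.full(n_strata, rng.uniform(rr_lo, rr_hi))
    # baseline risks leave headroom so baseline * RR stays a probability
    caps = np.minimum(MAX_RISK, MAX_RISK / np.maximum(rrs, 1.0))
    baselines = rng.uniform(0.01, 1.0, size=n_strata) * caps
    p = rng.uniform(0.05, 0.95, size=n_strata)
    return PopulationSpec(
        stratum_weights=tuple(w),
        baseline_risks=tuple(baselines),
        stratum_rrs=tuple(rrs),
        exposure_prevalence_by_stratum=tuple(p),
    )


def _two_stratum_confounding(
    p1: float,
    pi_target: float,
    rr_c: float,
    weights: tuple[float, float],
    baselines: tuple[float, float],
) -> tuple[PopulationSpec, float]:
    """Spec and realised C for exposure probability ``p1`` in stratum 1."""
    w1, w2 = weights
    b1, b2 = baselines
    p2 = (pi_target - w1 * p1) / w2
    spec = PopulationSpec(
        stratum_weights=weights,
        baseline_risks=baselines,
        stratum_rrs=(rr_c, rr_c),
        exposure_prevalence_by_stratum=(p1, p2),
    )
    pop = make_population(spec)
    c = rr_c / pop.unadjusted_rr()
    return spec, c


def sweep_confounding(
    pi_target: float,
    rr_c: float,
    c_values: Sequence[float],
    *,
    weights: tuple[float, float] = (0.8, 0.2),
    baseline_risks: tuple[float, float] = (0.1, 0.2),
    tol: float = 1e-8,
) -> list[StratifiedPopulation]:
    """Two-stratum populations realising each requested confounding ratio.

    The overall exposure prevalence and the (constant) causal RR are held
    fixed; confounding is varied by re-distributing exposure between a
    low-baseline-risk and a high-baseline-risk stratum.  The realised
    C = RR_C/RR_U is a monotone function of the split, so each target is
    found by bisection; targets outside the achievable range raise
    :class:`~pafkit.errors.InfeasibleConfoundingError` reporting that range.
    """
    if not 0.0 < pi_target < 1.0:
        raise DomainError("pi_target must be in (0, 1)")
    if not rr_c > 0:
        raise DomainError("rr_c must be positive")
    if baseline_risks[0] == baseline_risks[1]:
        raise DomainError(
            "equal baseline risks cannot generate confounding; C is fixed at 1"
        )
    w1, w2 = weights
    # feasible exposure split keeping both stratum prevalences in [0, 1]
    p1_lo = max(0.0, (pi_target - w2) / w1)
    p1_hi = min(1.0, pi_target / w1)
    c_lo = _two_stratum_confounding(p1_lo, pi_target, rr_c, weights, baseline_risks)[1]
    c_hi = _two_stratum_confounding(p1_hi, pi_target, rr_c, weights, baseline_risks)[1]
    feasible = (min(c_lo, c_hi), max(c_lo, c_hi))

    pops = []
    for target in c_values:
        if not feasible[0] - tol <= target <= feasible[1] + tol:
            raise InfeasibleConfoundingError(target, feasible)

        def gap(p1, target=target):
            return (
                _two_stratum_confounding(
                    p1, pi_target, rr_c, weights, baseline_risks
                )[1]
                - target
            )

        p1 = brentq(gap, p1_lo, p1_hi, xtol=1e-13)
        spec, realised = _two_stratum_confounding(
            p1, pi_target, rr_c, weights, baseline_risks
        )
        if abs(realised - target) > 1e-6:
            raise InfeasibleConfoundingError(target, feasible)
        pops.append(make_population(spec))
    return pops


def make_continuous_profile(
    *,
    median: float = 1.0,
    sigma: float = 0.5,
    rr_slope: float = 0.4,
    confounding_slope: float = 0.0,
    x_max: float = 5.0,
    n: int = 201,
) -> ExposureProfile:
    """Smooth continuous exposure profile for quadrature testing.

    The density is a lognormal shape (location ``log(median)``, log-scale
    ``sigma``) on an even grid over [0, x_max] with MREV 0; relative risks
    are log-linear, ``RR_C(x) = exp(rr_slope * x)`` and
    ``RR_U(x) = RR_C(x) / C(x)`` with confounding function
    ``C(x) = exp(confounding_slope * x)``.  ``confounding_slope = 0`` gives
    RR_U ≡ RR_C, under which Levin's generalised formula is unbiased.
    """
    if n < 3:
        raise DomainError("need at least three grid nodes")
    if median <= 0 or sigma <= 0 or x_max <= 0:
        raise DomainError("median, sigma and x_max must be positive")
    grid = np.linspace(0.0, x_max, n)
    density = np.zeros_like(grid)
    pos = grid > 0
    density[pos] = np.exp(
        -((np.log(grid[pos]) - np.log(median)) ** 2) / (2.0 * sigma**2)
    ) / (grid[pos] * sigma * np.sqrt(2.0 * np.pi))
    # normalize the truncated lognormal shape up front so the profile
    # constructor sees a proper density
    density /= np.trapezoid(density, grid)
    rr_c = np.exp(rr_slope * grid)
    rr_u = rr_c / np.exp(confounding_slope * grid)
    return ExposureProfile(
        kind="continuous",
        grid=grid,
        density=density,
        rr_c=rr_c,
        rr_u=rr_u,
        mrev=0.0,
    )
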