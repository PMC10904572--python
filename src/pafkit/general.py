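"""Levin and Miettinen PAF estimators for multi-category and continuous exposures.

The exposure is described by an :class:`ExposureProfile`: a grid of
exposure values carrying the population distribution (probability masses
for a multi-category exposure, density values at quadrature nodes for a
continuous one), the causal relative-risk function RR_C(x) relative to the
minimum-risk exposure value (MREV), and optionally the unadjusted
relative-risk function RR_U(x).

Estimators (expectations are mass-weighted sums or composite-trapezoid
quadrature on the supplied grid):

* Levin:      PAF_L = (E[RR_C(X)] - 1) / E[RR_C(X)]
* Miettinen:  PAF_M = E[RR_U(X)*(RR_C(X)-1)/RR_C(X)] / E[RR_U(X)]
* Case-density Miettinen: PAF_M = E_{X|Y=1}[(RR_C(X)-1)/RR_C(X)],
  when the profile's density slot carries the exposure distribution
  among disease cases.

The two Miettinen forms agree when the case density is derived from the
population density by Bayes' rule, pi_c(x) ∝ RR_U(x)*pi(x); Levin's form
agrees with both when RR_U ≡ RR_C (no confounding).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd

from .core import Formula, PafResult
from .errors import InvalidProfileError

__all__ = [
    "ExposureProfile",
    "levin_general",
    "miettinen_general",
    "miettinen_case_density",
]

_RR_AT_MREV_TOL = 1e-9
_DENSITY_NORM_WARN = 1e-3
_GRID_RR_RATIO_WARN = 1.5


@dataclass(frozen=True)
class ExposureProfile:
    """Gridded exposure distribution with relative-risk functions.

    Parameters
    ----------
    kind
        ``"multicategory"`` (grid holds category codes, density holds
        probability masses summing to 1) or ``"continuous"`` (grid holds
        sorted quadrature nodes, density holds density values whose
        trapezoid integral is renormalized to 1).
    grid, density, rr_c, rr_u
        Equal-length arrays; ``rr_u`` is optional (required only by the
        three-variable Miettinen estimator).
    mrev
        The exposure value treated as reference; must coincide with a grid
        node, and both RR functions must equal 1 there.
    """

    kind: Literal["multicategory", "continuous"]
    grid: np.ndarray
    density: np.ndarray
    rr_c: np.ndarray
    rr_u: np.ndarray | None = None
    mrev: float = 0.0

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=float)
        density = np.asarray(self.density, dtype=float)
        rr_c = np.asarray(self.rr_c, dtype=float)
        rr_u = None if self.rr_u is None else np.asarray(self.rr_u, dtype=float)
        if self.kind not in ("multicategory", "continuous"):
            raise InvalidProfileError(f"unknown profile kind {self.kind!r}")
        n = grid.size
        if n < 2:
            raise InvalidProfileError("profile needs at least two grid points")
        for name, arr in (("density", density), ("rr_c", rr_c)):
            if arr.size != n:
                raise InvalidProfileError(f"{name} length {arr.size} != grid length {n}")
        if rr_u is not None and rr_u.size != n:
            raise InvalidProfileError(f"rr_u length {rr_u.size} != grid length {n}")
        if np.any(np.diff(grid) <= 0):
            raise InvalidProfileError("grid must be strictly increasing")
        if np.any(density < 0):
            raise InvalidProfileError("density values must be non-negative")
        if np.any(rr_c < 0) or (rr_u is not None and np.any(rr_u < 0)):
            raise InvalidProfileError("relative risks must be non-negative")

        idx = np.flatnonzero(np.isclose(grid, self.mrev, rtol=0, atol=1e-12))
        if idx.size == 0:
            raise InvalidProfileError(
                f"MREV {self.mrev!r} does not coincide with a grid node"
            )
        i0 = int(idx[0])
        if abs(rr_c[i0] - 1.0) > _RR_AT_MREV_TOL:
            raise InvalidProfileError(
                f"rr_c must equal 1 at the MREV, got {rr_c[i0]!r}"
            )
        if rr_u is not None and abs(rr_u[i0] - 1.0) > _RR_AT_MREV_TOL:
            raise InvalidProfileError(
                f"rr_u must equal 1 at the MREV, got {rr_u[i0]!r}"
            )

        if self.kind == "multicategory":
            total = density.sum()
            if abs(total - 1.0) > 1e-9:
                raise InvalidProfileError(
                    f"category masses sum to {total!r}, not 1"
                )
        else:
            total = np.trapezoid(density, grid)
            if total <= 0:
                raise InvalidProfileError("density integrates to zero")
            if abs(total - 1.0) > _DENSITY_NORM_WARN:
                warnings.warn(
                    f"density integrates to {total:.6g}; renormalizing to 1",
                    stacklevel=2,
                )
            density = density / total

        if self.kind == "continuous":
            pos = density > 0
            keep = pos[1:] & pos[:-1]
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = rr_c[1:][keep] / rr_c[:-1][keep]
            ratio = ratio[np.isfinite(ratio) & (ratio > 0)]
            if ratio.size and np.max(np.maximum(ratio, 1.0 / ratio)) > _GRID_RR_RATIO_WARN:
                warnings.warn(
                    "adjacent-node RR_C ratio exceeds 1.5; the grid may be too "
                    "coarse for accurate quadrature",
                    stacklevel=2,
                )

        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "density", density)
        object.__setattr__(self, "rr_c", rr_c)
        object.__setattr__(self, "rr_u", rr_u)

    @property
    def mrev_index(self) -> int:
        return int(np.flatnonzero(np.isclose(self.grid, self.mrev, rtol=0, atol=1e-12))[0])

    def expect(self, values: np.ndarray) -> float:
        """E[f(X)] of per-node values under the profile's distribution."""
        values = np.asarray(values, dtype=float)
        if self.kind == "multicategory":
            return float(np.sum(self.density * values))
        return float(np.trapezoid(self.density * values, self.grid))

    def case_profile(self) -> "ExposureProfile":
        """Exposure distribution among cases, pi_c(x) ∝ RR_U(x)*pi(x)."""
        if self.rr_u is None:
            raise InvalidProfileError(
                "deriving the case density requires rr_u"
            )
        raw = self.rr_u * self.density
        if self.kind == "multicategory":
            raw = raw / raw.sum()
        # continuous: the constructor renormalizes
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return replace(self, density=raw, rr_u=None)

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, *, kind: str, mrev: float = 0.0
    ) -> "ExposureProfile":
        required = {"x", "density", "rr_c"}
        missing = required - set(df.columns)
        if missing:
            raise InvalidProfileError(
                f"profile table missing columns: {sorted(missing)}"
            )
        return cls(
            kind=kind,
            grid=df["x"].to_numpy(dtype=float),
            density=df["density"].to_numpy(dtype=float),
            rr_c=df["rr_c"].to_numpy(dtype=float),
            rr_u=df["rr_u"].to_numpy(dtype=float) if "rr_u" in df.columns else None,
            mrev=mrev,
        )

    def to_dataframe(self) -> pd.DataFrame:
        data = {"x": self.grid, "density": self.density, "rr_c": self.rr_c}
        if self.rr_u is not None:
            data["rr_u"] = self.rr_u
        return pd.DataFrame(data)

    @classmethod
    def from_csv(cls, path, *, kind: str, mrev: float = 0.0) -> "ExposureProfile":
        """Read a profile table: columns ``x,density,rr_c[,rr_u]``."""
        return cls.from_dataframe(pd.read_csv(path), kind=kind, mrev=mrev)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _shift_fraction(rr_c: np.ndarray, density: np.ndarray) -> np.ndarray:
    """(RR_C-1)/RR_C per node; RR_C = 0 is only allowed off-support."""
    out = np.zeros_like(rr_c)
    zero = rr_c == 0
    if np.any(zero & (density > 0)):
        raise InvalidProfileError(
            "rr_c is zero at a grid node carrying probability mass"
        )
    nz = ~zero
    out[nz] = (rr_c[nz] - 1.0) / rr_c[nz]
    return out


def levin_general(profile: ExposureProfile) -> PafResult:
    """Generalised Levin: (E[RR_C(X)] − 1) / E[RR_C(X)]."""
    m = profile.expect(profile.rr_c)
    if m <= 0:
        raise InvalidProfileError("E[RR_C(X)] must be positive")
    return PafResult(
        (m - 1.0) / m,
        Formula.LEVIN_GENERAL,
        {"mean_rr_c": m, "kind": profile.kind},
    )


def miettinen_general(profile: ExposureProfile) -> PafResult:
    """Generalised three-variable Miettinen form.

    E[RR_U(X)*(RR_C(X)-1)/RR_C(X)] / E[RR_U(X)]; with a multi-category
    profile the expectations are mass-weighted sums, with a continuous one
    they are trapezoid quadratures on the supplied grid.
    """
    if profile.rr_u is None:
        raise InvalidProfileError("miettinen_general requires rr_u")
    frac = _shift_fraction(profile.rr_c, profile.density)
    num = profile.expect(profile.rr_u * frac)
    den = profile.expect(profile.rr_u)
    if den <= 0:
        raise InvalidProfileError("E[RR_U(X)] must be positive")
    return PafResult(
        num / den,
        Formula.MIETTINEN_GENERAL,
        {"kind": profile.kind},
    )


def miettinen_case_density(profile_c: ExposureProfile) -> PafResult:
    """Case-density Miettinen form: E_{X|Y=1}[(RR_C(X)-1)/RR_C(X)].

    ``profile_c`` must carry the exposure distribution *among disease
    cases* in its density slot (see :meth:`ExposureProfile.case_profile`).
    """
    frac = _shift_fraction(profile_c.rr_c, profile_c.density)
    return PafResult(
        profile_c.expect(frac),
        Formula.MIETTINEN_CASE_DENSITY,
        {"kind": profile_c.kind},
    )
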