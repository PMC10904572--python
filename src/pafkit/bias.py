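"""Bias of Levin's formula as a function of the confounding ratio.

With a binary exposure and no effect modification on the relative-risk
scale, the true PAF is the three-variable Miettinen form, and the ratio of
Levin's formula to the truth has the closed form

    PAF_L / PAF = C * (1 + pi*(RR_U - 1)) / (1 + pi*(C*RR_U - 1)),

where C = RR_C / RR_U is the confounding ratio (C = 1 means no confounding
in risk ratio).  This module evaluates that relative bias, the absolute
bias PAF_L − PAF, their analytic limits for extreme C, and the analogous
curves for the "unadjusted" Levin variant that plugs RR_U in place of
RR_C.  Curves over a C grid can be rendered as a four-panel figure
(absolute/relative bias, with and without the RR_C >= 1 restriction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import levin, miettinen_three
from .errors import DomainError

__all__ = [
    "BiasLimits",
    "BiasProfile",
    "relative_bias",
    "absolute_bias",
    "bias_limits",
    "bias_curves",
    "plot_bias",
    "default_c_grid",
]


def _check(pi: float, rr_u: float) -> None:
    if not 0.0 < pi <= 1.0:
        raise DomainError(
            f"pi must be in (0, 1] (pi = 0 makes PAF zero and the bias "
            f"ratio undefined), got {pi!r}"
        )
    if not rr_u > 0.0:
        raise DomainError(f"rr_u must be positive, got {rr_u!r}")


def relative_bias(pi: float, rr_u: float, c) -> float | np.ndarray:
    """PAF_L / PAF at confounding ratio ``c`` (vectorised over ``c``).

    Evaluated from the closed form, which is the continuous extension of
    the ratio levin(pi, C*RR_U) / miettinen_three(pi, RR_U, C*RR_U) and so
    remains finite at C = 1/RR_U where both estimates vanish.
    """
    _check(pi, rr_u)
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise DomainError("confounding ratio c must be positive")
    out = (1.0 + pi * (rr_u - 1.0)) / (1.0 + pi * (c * rr_u - 1.0)) * c
    return float(out) if out.ndim == 0 else out


def absolute_bias(pi: float, rr_u: float, c) -> float | np.ndarray:
    """PAF_L − PAF at confounding ratio ``c`` (vectorised over ``c``)."""
    _check(pi, rr_u)
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise DomainError("confounding ratio c must be positive")
    rr_c = c * rr_u
    # single-fraction form of levin(pi, RR_C) - miettinen_three(pi, RR_U, RR_C):
    # the numerator bracket vanishes identically (bitwise) when RR_C == RR_U,
    # so the bias is exactly 0 at C = 1
    bracket = (1.0 + pi * (rr_u - 1.0)) * rr_c - rr_u * (1.0 + pi * (rr_c - 1.0))
    out = (
        pi
        * (rr_c - 1.0)
        * bracket
        / ((1.0 + pi * (rr_c - 1.0)) * (1.0 + pi * (rr_u - 1.0)) * rr_c)
    )
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class BiasLimits:
    """Analytic limiting values of Levin's bias for fixed (pi, RR_U).

    Attributes
    ----------
    rel_limit_c_inf
        Supremum of the relative bias as C -> infinity:
        ``1 + (1-pi)/(pi*RR_U)``.
    abs_limit_c_inf
        Limit of the absolute bias as C -> infinity:
        ``1 - pi*RR_U/(1+pi*(RR_U-1))``.
    rel_value_at_c_inv_rru
        Continuous-extension value of the relative bias at C = 1/RR_U
        (where RR_C = 1 and both PAFs vanish):
        ``(1+pi*(RR_U-1))/RR_U``.
    """

    rel_limit_c_inf: float
    abs_limit_c_inf: float
    rel_value_at_c_inv_rru: float


def bias_limits(pi: float, rr_u: float) -> BiasLimits:
    """Closed-form limits of the bias functions; never grid extrapolation."""
    _check(pi, rr_u)
    return BiasLimits(
        rel_limit_c_inf=1.0 + (1.0 - pi) / (pi * rr_u),
        abs_limit_c_inf=1.0 - pi * rr_u / (1.0 + pi * (rr_u - 1.0)),
        rel_value_at_c_inv_rru=(1.0 + pi * (rr_u - 1.0)) / rr_u,
    )


def default_c_grid(c_min: float = 0.2, c_max: float = 5.0, n: int = 200) -> np.ndarray:
    """Log-spaced confounding-ratio grid (C acts multiplicatively)."""
    if not 0 < c_min < c_max:
        raise DomainError("need 0 < c_min < c_max")
    return np.geomspace(c_min, c_max, n)


@dataclass(frozen=True)
class BiasProfile:
    """Bias curves of Levin's formula over a grid of confounding ratios.

    The "adjusted" curves use the causal RR (RR_C = C*RR_U) in Levin's
    formula; the "unadjusted" curves plug RR_U itself, so the estimate is
    constant in C while the true PAF moves — its relative bias is negative
    wherever RR_C < 1 (i.e. C < 1/RR_U), flipping the sign of the putative
    PAF.
    """

    pi: float
    rr_u: float
    c_grid: np.ndarray
    relative_bias: np.ndarray
    absolute_bias: np.ndarray
    relative_bias_unadj: np.ndarray
    absolute_bias_unadj: np.ndarray
    limits: BiasLimits

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "C": self.c_grid,
                "rel_bias_adj": self.relative_bias,
                "abs_bias_adj": self.absolute_bias,
                "rel_bias_unadj": self.relative_bias_unadj,
                "abs_bias_unadj": self.absolute_bias_unadj,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def bias_curves(pi: float, rr_u: float, c_grid=None) -> BiasProfile:
    """Evaluate adjusted and unadjusted Levin bias over a C grid."""
    _check(pi, rr_u)
    c = default_c_grid() if c_grid is None else np.asarray(c_grid, dtype=float)
    if np.any(c <= 0) or np.any(np.diff(c) <= 0):
        raise DomainError("c_grid must be positive and strictly increasing")
    rel = relative_bias(pi, rr_u, c)
    abs_ = absolute_bias(pi, rr_u, c)
    levin_u = levin(pi, rr_u, rr_is_causal=False).estimate
    true_paf = np.array(
        [miettinen_three(pi, rr_u, ci * rr_u).estimate for ci in c]
    )
    with np.errstate(divide="ignore"):
        rel_u = np.where(true_paf != 0.0, levin_u / true_paf, np.inf)
    abs_u = levin_u - true_paf
    return BiasProfile(
        pi=pi,
        rr_u=rr_u,
        c_grid=c,
        relative_bias=np.atleast_1d(rel),
        absolute_bias=np.atleast_1d(abs_),
        relative_bias_unadj=rel_u,
        absolute_bias_unadj=abs_u,
        limits=bias_limits(pi, rr_u),
    )


def plot_bias(profile: BiasProfile, path=None):
    """Four-panel bias figure: absolute/relative bias, with and without
    the restriction RR_C >= 1 (i.e. C >= 1/RR_U).

    Adjusted Levin in blue, unadjusted in red; horizontal lines mark the
    analytic limits.  Returns the matplotlib figure; saves to ``path`` if
    given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    c = profile.c_grid
    lim = profile.limits
    restricted = c >= 1.0 / profile.rr_u
    fig, axes = plt.subplots(2, 2, figsize=(10, 8), sharex=True)

    panels = [
        (axes[0, 0], "A: absolute bias, RR_C ≥ 1", "abs", restricted),
        (axes[0, 1], "B: absolute bias", "abs", slice(None)),
        (axes[1, 0], "C: relative bias, RR_C ≥ 1", "rel", restricted),
        (axes[1, 1], "D: relative bias", "rel", slice(None)),
    ]
    for ax, title, kind, mask in panels:
        if kind == "abs":
            adj, unadj = profile.absolute_bias, profile.absolute_bias_unadj
            ax.axhline(lim.abs_limit_c_inf, color="blue", ls=":", lw=1,
                       label="limit C→∞")
            ax.axhline(0.0, color="grey", lw=0.5)
        else:
            adj, unadj = profile.relative_bias, profile.relative_bias_unadj
            ax.axhline(lim.rel_limit_c_inf, color="blue", ls=":", lw=1,
                       label="limit C→∞")
            ax.axhline(lim.rel_value_at_c_inv_rru, color="blue", ls="--", lw=0.8,
                       label="value at C=1/RR_U")
            ax.axhline(1.0, color="grey", lw=0.5)
        finite = np.isfinite(unadj)
        ax.plot(c[mask], adj[mask], color="blue", label="adjusted (RR_C)")
        m = mask & finite if isinstance(mask, np.ndarray) else finite
        ax.plot(c[m], unadj[m], color="red", label="unadjusted (RR_U)")
        ax.set_title(title, fontsize=10)
        ax.set_xscale("log")
        ax.set_xlabel("confounding ratio C")
    axes[0, 0].legend(fontsize=8)
    fig.suptitle(
        f"Bias of Levin's formula ($\\pi$={profile.pi:g}, $RR_U$={profile.rr_u:g})"
    )
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
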