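"""Confounder-stratified populations and ground-truth attributable fractions.

A :class:`StratifiedPopulation` is a full joint table of
(confounder stratum, exposure level, population proportion, disease risk)
cells.  Because the joint distribution is completely specified, the
population attributable fraction can be computed directly from its
definition,

    PAF = (P(Y=1) - P(Y0=1)) / P(Y=1),

by standardizing stratum-specific reference risks over the confounder
distribution (conditional exchangeability).  Every closed-form estimator in
:mod:`pafkit.core`, :mod:`pafkit.bias` and :mod:`pafkit.general` is tested
against this oracle.

Exposure levels are integer codes with 0 fixed as the reference (the
minimum-risk exposure value).  A stratum may omit a non-reference level —
it then simply contributes no exposed mass — but every stratum must contain
a reference cell, otherwise counterfactual risks are undefined.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping

import pandas as pd

from .errors import (
    InvalidPopulationError,
    MissingReferenceCellError,
    ZeroRiskError,
)

__all__ = [
    "StratumCell",
    "StratifiedPopulation",
    "PopulationSummaries",
    "round_sig",
]

PROPORTION_TOL = 1e-9


def round_sig(x: float, digits: int = 3) -> float:
    """Round ``x`` to ``digits`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, digits - 1 - math.floor(math.log10(abs(x))))


@dataclass(frozen=True)
class StratumCell:
    """One (confounder stratum, exposure level) cell of the joint table.

    Parameters
    ----------
    stratum
        Opaque confounder-stratum label.
    exposure
        Non-negative integer exposure code; 0 is the reference level.
    proportion
        Fraction of the total population in this cell.
    risk
        Probability of disease in this cell.
    """

    stratum: Hashable
    exposure: int
    proportion: float
    risk: float

    def __post_init__(self):
        if not isinstance(self.exposure, int) or self.exposure < 0:
            raise InvalidPopulationError(
                f"exposure code must be a non-negative integer, got {self.exposure!r}"
            )
        if not 0.0 <= self.proportion <= 1.0:
            raise InvalidPopulationError(
                f"cell proportion must be in [0, 1], got {self.proportion!r} "
                f"(stratum {self.stratum!r}, exposure {self.exposure})"
            )
        if not 0.0 <= self.risk <= 1.0:
            raise InvalidPopulationError(
                f"cell risk must be in [0, 1], got {self.risk!r} "
                f"(stratum {self.stratum!r}, exposure {self.exposure})"
            )


@dataclass(frozen=True)
class PopulationSummaries:
    """All scalar summaries of a population the estimators consume.

    ``pi``, ``pi_c`` and ``rr_e`` are defined for binary exposures only and
    are ``None`` otherwise.  ``paf`` is always the definition PAF
    (observed minus counterfactual risk, over observed risk); it may be
    negative for a protective exposure and is never clamped.
    """

    observed_risk: float
    counterfactual_risk: float
    paf: float
    pi: float | None
    pi_c: float | None
    rr_u: float | None
    rr_c_marginal: float | None
    rr_e: float | None
    stratum_rrs: Mapping[Hashable, float]

    def to_dict(self) -> dict:
        d = {
            "observed_risk": self.observed_risk,
            "counterfactual_risk": self.counterfactual_risk,
            "paf": self.paf,
            "pi": self.pi,
            "pi_c": self.pi_c,
            "rr_u": self.rr_u,
            "rr_c_marginal": self.rr_c_marginal,
            "rr_e": self.rr_e,
            "stratum_rrs": {str(k): v for k, v in self.stratum_rrs.items()},
        }
        d["rounded"] = {
            k: (round_sig(v, 3) if isinstance(v, float) else v)
            for k, v in d.items()
            if k != "stratum_rrs" and v is not None
        }
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


class StratifiedPopulation:
    """Fully specified joint population over confounder strata and exposure.

    Parameters
    ----------
    cells
        Iterable of :class:`StratumCell` (or tuples accepted by it).
    normalize
        If True, rescale proportions to sum to 1 (intended for synthetic
        use); by default a sum off by more than 1e-9 is a construction
        error, since silent renormalization hides data-entry mistakes.
    """

    def __init__(self, cells: Iterable[StratumCell], *, normalize: bool = False):
        cells = [
            c if isinstance(c, StratumCell) else StratumCell(*c) for c in cells
        ]
        if not cells:
            raise InvalidPopulationError("population has no cells")
        total = sum(c.proportion for c in cells)
        if normalize:
            if total <= 0:
                raise InvalidPopulationError("total proportion is not positive")
            cells = [
                StratumCell(c.stratum, c.exposure, c.proportion / total, c.risk)
                for c in cells
            ]
        elif abs(total - 1.0) > PROPORTION_TOL:
            raise InvalidPopulationError(
                f"cell proportions sum to {total!r}, not 1 "
                "(pass normalize=True to rescale synthetic inputs)"
            )
        seen = set()
        for c in cells:
            key = (c.stratum, c.exposure)
            if key in seen:
                raise InvalidPopulationError(f"duplicate cell {key!r}")
            seen.add(key)
        self._cells = tuple(cells)
        self._by_key = {(c.stratum, c.exposure): c for c in cells}
        # preserve first-appearance order of strata
        self._strata = list(dict.fromkeys(c.stratum for c in cells))
        for s in self._strata:
            if (s, 0) not in self._by_key:
                raise MissingReferenceCellError(s, 0)

    # -- structure ---------------------------------------------------------

    @property
    def cells(self) -> tuple[StratumCell, ...]:
        return self._cells

    @property
    def strata(self) -> list[Hashable]:
        return list(self._strata)

    @property
    def n_confounder_strata(self) -> int:
        return len(self._strata)

    @property
    def exposure_levels(self) -> list[int]:
        return sorted({c.exposure for c in self._cells})

    @property
    def is_binary(self) -> bool:
        return set(self.exposure_levels) <= {0, 1}

    def stratum_proportion(self, stratum: Hashable) -> float:
        """Marginal P(C = stratum)."""
        return sum(c.proportion for c in self._cells if c.stratum == stratum)

    def _risk(self, stratum: Hashable, level: int) -> float:
        try:
            return self._by_key[(stratum, level)].risk
        except KeyError:
            raise MissingReferenceCellError(stratum, level) from None

    # -- risks and PAF -----------------------------------------------------

    def observed_risk(self) -> float:
        """P(Y=1): proportion-weighted average of cell risks."""
        return sum(c.proportion * c.risk for c in self._cells)

    def counterfactual_risk(self, target_level: int = 0) -> float:
        """P(Y_target = 1) under conditional exchangeability.

        Each cell keeps its population mass but takes the risk of the cell
        at ``target_level`` in the same confounder stratum.
        """
        return sum(
            c.proportion * self._risk(c.stratum, target_level)
            for c in self._cells
        )

    def paf(self) -> float:
        """Definition PAF: (P(Y=1) − P(Y0=1)) / P(Y=1)."""
        obs = self.observed_risk()
        if obs <= 0:
            raise ZeroRiskError("observed risk is zero; PAF undefined")
        return (obs - self.counterfactual_risk(0)) / obs

    # -- relative risks ----------------------------------------------------

    def stratum_rrs(self, level: int = 1) -> dict[Hashable, float]:
        """Per-stratum causal RR: risk at ``level`` over risk at 0."""
        out = {}
        for s in self._strata:
            if (s, level) not in self._by_key:
                continue
            ref = self._risk(s, 0)
            if ref <= 0:
                raise ZeroRiskError(
                    f"reference risk is zero in stratum {s!r}; RR undefined"
                )
            out[s] = self._risk(s, level) / ref
        return out

    def marginal_causal_rr(self, level: int = 1) -> float:
        """P(Y_level=1) / P(Y0=1), standardizing over the confounder marginal.

        Requires every stratum to carry cells at both ``level`` and 0.
        """
        num = den = 0.0
        for s in self._strata:
            w = self.stratum_proportion(s)
            num += w * self._risk(s, level)
            den += w * self._risk(s, 0)
        if den <= 0:
            raise ZeroRiskError("counterfactual reference risk is zero")
        return num / den

    def causal_rr_exposed(self) -> float:
        """Causal RR restricted to the exposed: P(Y1=1|X=1)/P(Y0=1|X=1).

        Standardizes over the confounder distribution *among the exposed*;
        binary exposure only.
        """
        if not self.is_binary:
            raise InvalidPopulationError(
                "causal RR among the exposed requires a binary exposure"
            )
        num = den = mass = 0.0
        for c in self._cells:
            if c.exposure != 1:
                continue
            mass += c.proportion
            num += c.proportion * self._risk(c.stratum, 1)
            den += c.proportion * self._risk(c.stratum, 0)
        if mass <= 0:
            raise InvalidPopulationError("no exposed individuals")
        if den <= 0:
            raise ZeroRiskError("reference risk among the exposed is zero")
        return num / den

    def unadjusted_rr(self, level: int = 1) -> float:
        """Observed risk ratio P(Y=1|X=level)/P(Y=1|X=0), confounding included."""
        def group(lv: int) -> float:
            mass = sum(c.proportion for c in self._cells if c.exposure == lv)
            if mass <= 0:
                raise InvalidPopulationError(
                    f"no population mass at exposure level {lv}"
                )
            return (
                sum(c.proportion * c.risk for c in self._cells if c.exposure == lv)
                / mass
            )

        ref = group(0)
        if ref <= 0:
            raise ZeroRiskError("observed risk among the unexposed is zero")
        return group(level) / ref

    # -- prevalences -------------------------------------------------------

    def exposure_prevalence(self) -> float:
        """pi = P(X != 0): total mass away from the reference level."""
        return sum(c.proportion for c in self._cells if c.exposure != 0)

    def case_prevalence(self) -> float:
        """pi_c = P(X=1 | Y=1): exposure prevalence among disease cases."""
        obs = self.observed_risk()
        exposed_cases = sum(
            c.proportion * c.risk for c in self._cells if c.exposure != 0
        )
        if exposed_cases == 0:
            return 0.0
        if obs <= 0:
            raise ZeroRiskError("observed risk is zero; pi_c undefined")
        return exposed_cases / obs

    # -- effect-modification identity --------------------------------------

    def paf_effect_modification(self) -> float:
        """PAF as a case-weighted average over confounder strata.

        Binary exposures use the exposed-case fraction per stratum times
        (RR_C(c) − 1)/RR_C(c); multi-level exposures use the double
        expectation over the case-conditional joint of (C, X).  Both are
        exact identities and agree with :meth:`paf` to floating precision.
        """
        obs = self.observed_risk()
        if obs <= 0:
            raise ZeroRiskError("observed risk is zero; PAF undefined")
        total = 0.0
        for s in self._strata:
            stratum_cells = [c for c in self._cells if c.stratum == s]
            case_mass = sum(c.proportion * c.risk for c in stratum_cells)
            if case_mass <= 0:
                continue
            ref = self._risk(s, 0)
            inner = 0.0
            for c in stratum_cells:
                if c.exposure == 0:
                    continue
                if ref <= 0:
                    raise ZeroRiskError(
                        f"reference risk is zero in stratum {s!r} with exposed cases"
                    )
                rr = c.risk / ref
                # P(X=x | C=s, Y=1) * (RR_C(x,s)-1)/RR_C(x,s)
                inner += (c.proportion * c.risk / case_mass) * (rr - 1.0) / rr
            total += (case_mass / obs) * inner
        return total

    # -- summary bundle ----------------------------------------------------

    def summaries(self) -> PopulationSummaries:
        binary = self.is_binary and self.exposure_prevalence() > 0
        return PopulationSummaries(
            observed_risk=self.observed_risk(),
            counterfactual_risk=self.counterfactual_risk(0),
            paf=self.paf(),
            pi=self.exposure_prevalence() if self.is_binary else None,
            pi_c=self.case_prevalence() if self.is_binary else None,
            rr_u=self.unadjusted_rr(1) if binary else None,
            rr_c_marginal=self.marginal_causal_rr(1)
            if binary and all((s, 1) in self._by_key for s in self._strata)
            else None,
            rr_e=self.causal_rr_exposed() if binary else None,
            stratum_rrs=self.stratum_rrs(1) if binary else {},
        )

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, *, normalize: bool = False
    ) -> "StratifiedPopulation":
        required = {"stratum", "exposure", "proportion", "risk"}
        missing = required - set(df.columns)
        if missing:
            raise InvalidPopulationError(
                f"population table missing columns: {sorted(missing)}"
            )
        cells = [
            StratumCell(
                str(row.stratum),
                int(row.exposure),
                float(row.proportion),
                float(row.risk),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(cells, normalize=normalize)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": [c.stratum for c in self._cells],
                "exposure": [c.exposure for c in self._cells],
                "proportion": [c.proportion for c in self._cells],
                "risk": [c.risk for c in self._cells],
            }
        )

    @classmethod
    def from_csv(cls, path, *, normalize: bool = False) -> "StratifiedPopulation":
        """Read a population table: columns ``stratum,exposure,proportion,risk``."""
        df = pd.read_csv(path)
        return cls.from_dataframe(df, normalize=normalize)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def __repr__(self) -> str:
        return (
            f"StratifiedPopulation(n_strata={self.n_confounder_strata}, "
            f"levels={self.exposure_levels}, cells={len(self._cells)})"
        )


def load_fixture(name: str) -> StratifiedPopulation:
    """Load a packaged example population (``table1`` or ``table1_em``)."""
    from importlib.resources import files

    path = files("pafkit.data").joinpath(f"{name}.csv")
    with path.open("r") as fh:
        return StratifiedPopulation.from_csv(fh)
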