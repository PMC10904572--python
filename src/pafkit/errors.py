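"""Exception hierarchy shared across pafkit modules."""


class PafkitError(Exception):
    """Base class for all pafkit data/domain errors."""


class DomainError(PafkitError, ValueError):
    """An input is outside the mathematical domain of a formula."""


class InvalidPopulationError(PafkitError, ValueError):
    """A stratified population table violates its invariants."""


class MissingReferenceCellError(InvalidPopulationError):
    """A confounder stratum lacks the cell needed to form a counterfactual."""

    def __init__(self, stratum, level):
        self.stratum = stratum
        self.level = level
        super().__init__(
            f"stratum {stratum!r} has no cell at exposure level {level}; "
            "counterfactual risk is undefined"
        )


class ZeroRiskError(PafkitError, ZeroDivisionError):
    """Observed or counterfactual risk is zero where a ratio is required."""


class InvalidProfileError(PafkitError, ValueError):
    """An exposure profile (grid/density/RR functions) violates its invariants."""


class InfeasibleConfoundingError(PafkitError, ValueError):
    """A requested confounding ratio cannot be realised by the generator."""

    def __init__(self, target, feasible_range):
        self.target = target
        self.feasible_range = feasible_range
        lo, hi = feasible_range
        super().__init__(
            f"confounding ratio C={target:g} is infeasible for this geometry; "
            f"achievable range is [{lo:.6g}, {hi:.6g}]"
        )
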