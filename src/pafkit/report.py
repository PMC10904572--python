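"""One-shot report reproducing the packaged worked examples end-to-end.

Runs the whole pipeline on the two shipped populations — a two-stratum
binary-exposure population with a constant stratum causal RR, and the same
population with effect modification (a larger RR in the high-baseline-risk
stratum) — and tabulates every summary next to the Levin and Miettinen
estimates computed from those summaries.  The report is deterministic:
regenerating it yields byte-identical output.
"""

from __future__ import annotations

import json

from .core import levin, miettinen_pc, miettinen_three
from .population import StratifiedPopulation, load_fixture, round_sig

__all__ = ["worked_example_rows", "render_markdown", "render_json"]

_COLUMNS = [
    ("observed_risk", "P(Y=1)"),
    ("counterfactual_risk", "P(Y0=1)"),
    ("paf", "PAF (definition)"),
    ("pi", "pi"),
    ("pi_c", "pi_c"),
    ("rr_c_marginal", "RR_C (marginal)"),
    ("rr_e", "RR_C (exposed)"),
    ("rr_u", "RR_U"),
    ("levin", "Levin"),
    ("miettinen_three", "Miettinen (3-variable)"),
    ("miettinen_pc_exposed", "Miettinen (pi_c, RR_e)"),
    ("paf_eq_em", "PAF (case-weighted identity)"),
]


def _example_row(pop: StratifiedPopulation) -> dict[str, float]:
    s = pop.summaries()
    return {
        "observed_risk": s.observed_risk,
        "counterfactual_risk": s.counterfactual_risk,
        "paf": s.paf,
        "pi": s.pi,
        "pi_c": s.pi_c,
        "rr_c_marginal": s.rr_c_marginal,
        "rr_e": s.rr_e,
        "rr_u": s.rr_u,
        "levin": levin(s.pi, s.rr_c_marginal).estimate,
        "miettinen_three": miettinen_three(s.pi, s.rr_u, s.rr_c_marginal).estimate,
        "miettinen_pc_exposed": miettinen_pc(s.pi_c, s.rr_e).estimate,
        "paf_eq_em": pop.paf_effect_modification(),
    }


def worked_example_rows() -> dict[str, dict[str, float]]:
    """Full-precision summary/estimate rows for both packaged populations."""
    return {
        "table1": _example_row(load_fixture("table1")),
        "table1_em": _example_row(load_fixture("table1_em")),
    }


def render_json(rows: dict[str, dict[str, float]] | None = None) -> str:
    rows = worked_example_rows() if rows is None else rows
    out = {
        name: {
            "full_precision": row,
            "rounded": {k: round_sig(v, 3) for k, v in row.items()},
        }
        for name, row in rows.items()
    }
    return json.dumps(out, indent=2, sort_keys=True)


def render_markdown(rows: dict[str, dict[str, float]] | None = None) -> str:
    """Markdown table, one row per quantity, one column per population;
    values rounded to 3 significant figures with full precision alongside."""
    rows = worked_example_rows() if rows is None else rows
    names = list(rows)
    lines = [
        "# Worked example: Levin vs Miettinen under confounding",
        "",
        "| Quantity | " + " | ".join(names) + " |",
        "|---" * (len(names) + 1) + "|",
    ]
    for key, label in _COLUMNS:
        vals = [
            f"{round_sig(rows[n][key], 3):g} ({rows[n][key]:.12g})" for n in names
        ]
        lines.append(f"| {label} | " + " | ".join(vals) + " |")
    lines += [
        "",
        "With a constant stratum causal RR (first column) the Miettinen",
        "forms recover the definition PAF exactly while Levin's formula",
        "underestimates it; under effect modification (second column) the",
        "three-variable form with the marginal causal RR is also biased,",
        "and only the case-prevalence form with the causal RR among the",
        "exposed recovers the definition PAF.",
        "",
    ]
    return "\n".join(lines)
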