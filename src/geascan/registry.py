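"""Climate-adjusted provenancing: projections and donor-meadow matching.

Future conditions at each meadow are projected by adding a constant
annual rate of change to the current value over the horizon (a
deliberately simple extrapolation that ignores confounding or mitigating
factors).  A donor meadow for a recipient x variable x horizon cell is a
meadow whose *current* value already meets or exceeds the projected
condition — i.e., whose standing genotypes show contemporary adaptation
at least as extreme as the recipient's future.  The default rule picks
the smallest sufficient donor ("min_above"); a "nearest" rule is also
provided.  A comparison report against a published registry surfaces
cells where the printed donor cannot be reproduced by any rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

DEFAULT_BASE_YEAR = 2024
DEFAULT_RATES = {"AvTemp": 0.2, "MaxTemp": 0.2}
DEFAULT_HORIZONS = (2030, 2040, 2050)
#: Comparison tolerance absorbing 2-decimal display rounding.
DEFAULT_TOL = 0.005


def round_display(value: float, ndigits: int = 2) -> float:
    """Half-up decimal rounding for display (23.425 -> 23.43)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def project(current: float, rate: float, base_year: int, target_year: int) -> float:
    """Projected value: current + rate * (target_year - base_year)."""
    if target_year < base_year:
        raise ValueError("target_year must not precede base_year")
    return current + rate * (target_year - base_year)


def find_donor(
    env_table: pd.DataFrame,
    variable: str,
    target_value: float,
    rule: str = "min_above",
    exclude: str | None = None,
    tol: float = DEFAULT_TOL,
) -> str | None:
    """Donor meadow whose current value meets the projected condition.

    ``rule="min_above"``: among meadows with current >= target (within
    ``tol``), the one with the smallest current value, ties alphabetical;
    ``None`` if no meadow qualifies.  ``rule="nearest"``: the meadow
    minimising |current - target|, ties preferring the above-target
    meadow, then alphabetical.
    """
    if variable not in env_table.columns:
        raise KeyError(f"unknown environmental variable: {variable}")
    values = env_table[variable]
    if exclude is not None:
        values = values.drop(index=exclude, errors="ignore")
    if rule == "min_above":
        above = values[values >= target_value - tol]
        if above.empty:
            return None
        return sorted(above.items(), key=lambda kv: (kv[1], kv[0]))[0][0]
    if rule == "nearest":
        ranked = sorted(
            values.items(),
            key=lambda kv: (abs(kv[1] - target_value), kv[1] < target_value, kv[0]),
        )
        return ranked[0][0]
    raise ValueError("rule must be 'min_above' or 'nearest'")


@dataclass
class RegistryTable:
    """Projection grid with matched donors plus the rule that produced it."""

    grid: pd.DataFrame  # meadow, variable, current, rate, horizon, projected, donor
    rule: str
    base_year: int

    def cell(self, meadow: str, variable: str, horizon: int) -> pd.Series:
        g = self.grid
        sel = g[(g.meadow == meadow) & (g.variable == variable) & (g.horizon == horizon)]
        if sel.empty:
            raise KeyError((meadow, variable, horizon))
        return sel.iloc[0]


def build_registry(
    env_table: pd.DataFrame,
    variables: list[str] | None = None,
    rates: dict[str, float] | None = None,
    base_year: int = DEFAULT_BASE_YEAR,
    horizons=DEFAULT_HORIZONS,
    rule: str = "min_above",
    allow_self: bool = False,
    tol: float = DEFAULT_TOL,
) -> RegistryTable:
    """Full meadow x variable x horizon grid of projections and donors."""
    variables = list(DEFAULT_RATES) if variables is None else list(variables)
    rates = dict(DEFAULT_RATES) if rates is None else rates
    missing = [v for v in variables if v not in rates]
    if missing:
        raise ValueError(f"no rate given for variables: {missing}")
    if any(h < base_year for h in horizons):
        raise ValueError("horizons must not precede the base year")
    rows = []
    for variable in variables:
        for meadow in env_table.index:
            current = float(env_table.loc[meadow, variable])
            for horizon in horizons:
                proj = project(current, rates[variable], base_year, horizon)
                donor = find_donor(
                    env_table,
                    variable,
                    proj,
                    rule=rule,
                    exclude=None if allow_self else meadow,
                    tol=tol,
                )
                rows.append(
                    {
                        "meadow": meadow,
                        "variable": variable,
                        "current": current,
                        "rate": rates[variable],
                        "horizon": int(horizon),
                        "projected": proj,
                        "projected_display": round_display(proj),
                        "donor": donor,
                    }
                )
    return RegistryTable(grid=pd.DataFrame(rows), rule=rule, base_year=base_year)


@dataclass
class RegistryComparison:
    """Cell-by-cell comparison of a built registry against a published one."""

    agree: list[dict] = field(default_factory=list)
    printed_violates_rule: list[dict] = field(default_factory=list)
    rule_ambiguous: list[dict] = field(default_factory=list)
    projection_mismatch: list[dict] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return (
            len(self.agree)
            + len(self.printed_violates_rule)
            + len(self.rule_ambiguous)
        )

    def summary(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "n_agree": len(self.agree),
            "n_printed_violates_rule": len(self.printed_violates_rule),
            "n_rule_ambiguous": len(self.rule_ambiguous),
            "n_projection_mismatch": len(self.projection_mismatch),
        }


def compare_registry(
    registry: RegistryTable,
    published: pd.DataFrame,
    env_table: pd.DataFrame,
    tol: float = DEFAULT_TOL,
) -> RegistryComparison:
    """Classify every published donor cell against the built registry.

    * ``agree`` — published donor (or NA) equals the built donor.
    * ``printed_violates_rule`` — the published donor's current value is
      below the projected condition, so no ``>=`` rule can emit it.
    * ``rule_ambiguous`` — the published donor satisfies the ``>=`` rule
      but differs from the deterministic choice of the built rule.
    * ``projection_mismatch`` — printed projected value differs from the
      computed one after display rounding (reported separately).
    """
    comp = RegistryComparison()
    for _, row in published.iterrows():
        meadow, variable = row["meadow"], row["variable"]
        for horizon in DEFAULT_HORIZONS:
            cell = registry.cell(meadow, variable, horizon)
            printed_proj = float(row[f"proj_{horizon}"])
            if abs(cell["projected_display"] - printed_proj) > 1e-9:
                comp.projection_mismatch.append(
                    {
                        "meadow": meadow,
                        "variable": variable,
                        "horizon": horizon,
                        "printed": printed_proj,
                        "computed": cell["projected_display"],
                    }
                )
            printed_donor = row[f"donor_{horizon}"]
            printed_donor = None if printed_donor in ("NA", "", None) else printed_donor
            built_donor = cell["donor"]
            record = {
                "meadow": meadow,
                "variable": variable,
                "horizon": horizon,
                "printed_donor": printed_donor,
                "built_donor": built_donor,
                "projected": float(cell["projected"]),
            }
            if printed_donor == built_donor:
                comp.agree.append(record)
            elif printed_donor is None or (
                float(env_table.loc[printed_donor, variable])
                < float(cell["projected"]) - tol
            ):
                comp.printed_violates_rule.append(record)
            else:
                comp.rule_ambiguous.append(record)
    return comp
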