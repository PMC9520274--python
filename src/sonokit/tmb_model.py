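"""Ligand budget arithmetic for targeted microbubbles (TMBs).

A TMB carries antibodies through a biotin-streptavidin bridge: a fraction
of the shell lipids are biotinylated, each biotin-lipid is assumed to bind
one streptavidin, and each streptavidin presents two antibody molecules.
The shell area convention is pi * d^2 (i.e. 4 pi r^2), and lipid count =
shell area / lipid headgroup area.

Counts are order-of-magnitude estimates and therefore reported as floats.
``significant_figures_mode`` reproduces the customary one-significant-figure
chain of intermediate roundings (1e7 lipids -> 5e5 biotin -> 5e5
streptavidin -> 10e5 antibodies) used when quoting such budgets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["ShellBudget", "LigandCounts", "lipids_per_shell", "ligand_counts",
           "effective_binding_rate"]


@dataclass(frozen=True)
class ShellBudget:
    """Geometry and stoichiometry inputs for the ligand budget."""

    diameter: float = 1.5e-6  # m
    headgroup_area: float = 0.6e-18  # m^2 (DSPC headgroup ~0.6 nm^2)
    biotin_mole_fraction: float = 0.05
    streptavidin_per_biotin: float = 1.0
    antibody_per_streptavidin: float = 2.0

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.headgroup_area <= 0:
            raise ValueError("diameter and headgroup_area must be > 0")
        if not 0.0 <= self.biotin_mole_fraction <= 1.0:
            raise ValueError("biotin_mole_fraction must be in [0, 1]")
        if self.streptavidin_per_biotin < 0 or self.antibody_per_streptavidin < 0:
            raise ValueError("stoichiometric ratios must be >= 0")


@dataclass(frozen=True)
class LigandCounts:
    lipids: float
    biotin_lipids: float
    streptavidin: float
    antibodies: float
    significant_figures_mode: bool = False


def _round_1sf(x: float) -> float:
    """Round to one significant figure (0 stays 0)."""
    if x == 0.0:
        return 0.0
    exp = math.floor(math.log10(abs(x)))
    return round(x / 10**exp) * 10.0**exp


def lipids_per_shell(budget: ShellBudget, rounded: bool = False) -> float:
    """Number of lipid molecules in the monolayer shell.

    Uses the pi * d^2 area convention: for d = 1.5 um and a = 0.6 nm^2 the
    exact value is 1.178e7, quoted as ~1e7 in rounded mode.
    """
    exact = math.pi * budget.diameter**2 / budget.headgroup_area
    return _round_1sf(exact) if rounded else exact


def ligand_counts(budget: ShellBudget, rounded: bool = False) -> LigandCounts:
    """Chain the budget: lipids -> biotin-lipids -> streptavidin -> antibodies.

    In rounded mode each intermediate is rounded to one significant figure
    before the next step, reproducing the conventional quoted chain
    1e7 -> 5e5 -> 5e5 -> 10e5 (the final antibody count is left as
    2 x streptavidin, i.e. 10e5 rather than 1e6-style re-rounding).
    """
    lipids = lipids_per_shell(budget, rounded=rounded)
    biotin = budget.biotin_mole_fraction * lipids
    if rounded:
        biotin = _round_1sf(biotin)
    strep = budget.streptavidin_per_biotin * biotin
    if rounded:
        strep = _round_1sf(strep)
    antibodies = budget.antibody_per_streptavidin * strep
    return LigandCounts(
        lipids=lipids,
        biotin_lipids=biotin,
        streptavidin=strep,
        antibodies=antibodies,
        significant_figures_mode=rounded,
    )


def effective_binding_rate(bound_per_cell: float, offered_per_cell: float) -> float:
    """Percentage of offered TMBs that end up bound per cell:
    100 * bound / offered."""
    if offered_per_cell <= 0:
        raise ValueError("offered_per_cell must be > 0")
    if bound_per_cell < 0:
        raise ValueError("bound_per_cell must be >= 0")
    if bound_per_cell > offered_per_cell:
        raise ValueError("bound_per_cell cannot exceed offered_per_cell")
    return 100.0 * bound_per_cell / offered_per_cell
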