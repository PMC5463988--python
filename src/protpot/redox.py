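"""Lipid-protein redox mass balance.

An electron-bookkeeping estimate: if the carbon-weighted mean oxidation state
of the combined lipid + protein pool is the same in cancer cells as in
hypoxic normal cells, and the protein pool's Z_C rises (hypoxia ~ -0.03 to
cancer ~ +0.03 relative to normal), how much must the lipid:protein weight
ratio (L:P) grow for the extra lipid -- strongly reduced carbon -- to absorb
the electrons released by oxidizing the proteome?  The balance is linear in
the unknown ratio and solved in closed form.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .composition import (
    ElementalFormula,
    formula_from_composition,
    read_composition_table,
    zc,
)

__all__ = [
    "ATOMIC_WEIGHTS", "MacromoleculePool", "RedoxScenario", "RedoxResult",
    "molar_mass", "carbon_per_gram", "mixture_zc", "solve_lipid_protein_ratio",
    "TRIACYLGLYCEROL", "mean_human_protein_formula", "LP_RATIO_PRESETS",
]

#: Standard atomic weights (IUPAC 2021 conventional values).
ATOMIC_WEIGHTS = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "S": 32.06}

#: 1-palmitoyl-2,3-dioleoyl-glycerol, a representative triacylglycerol.
TRIACYLGLYCEROL = ElementalFormula.from_string("C55H102O6")

#: Lipid:protein weight ratios usable as scenario baselines: hypoxic mouse
#: cells (0.19) and two normal-cell alternatives (0.15 mouse, 0.16 E. coli).
LP_RATIO_PRESETS = {"hypoxia": 0.19, "normal_mouse": 0.15, "normal_ecoli": 0.16}


def molar_mass(formula: ElementalFormula) -> float:
    """Gram molar mass from standard atomic weights (charge ignored)."""
    vec = formula.as_vector()
    return sum(vec[i] * ATOMIC_WEIGHTS[el] for i, el in enumerate("CHNOS"))


def carbon_per_gram(formula: ElementalFormula) -> float:
    """Moles of carbon per gram of the substance; intensive (scale-invariant)."""
    mass = molar_mass(formula)
    if mass <= 0:
        raise ValueError("formula has zero molar mass")
    return formula.c / mass


@dataclass(frozen=True)
class MacromoleculePool:
    """A mass of material with a single (possibly averaged) formula."""

    label: str
    formula: ElementalFormula
    mass: float  # grams

    def __post_init__(self) -> None:
        if self.formula.c <= 0:
            raise ValueError(f"pool {self.label!r}: formula needs carbon")
        if self.mass <= 0:
            raise ValueError(f"pool {self.label!r}: mass must be positive")

    @property
    def mol_carbon(self) -> float:
        return self.mass * carbon_per_gram(self.formula)


def mixture_zc(pools: Sequence[MacromoleculePool]) -> float:
    """Carbon-abundance-weighted mean Z_C of several pools.

    Equals the Z_C of the element-wise combined formula.
    """
    if not pools:
        raise ValueError("need at least one pool")
    total_c = sum(p.mol_carbon for p in pools)
    if total_c <= 0:
        raise ValueError("zero total carbon")
    return sum(p.mol_carbon * zc(p.formula) for p in pools) / total_c


def mean_human_protein_formula() -> ElementalFormula:
    """Average protein formula from the packaged synthetic stand-in for the
    mean human-proteome amino-acid composition (see the data file header)."""
    ref = importlib.resources.files("protpot") / "data" / "human_proteome_mean_aa_synthetic.csv"
    with importlib.resources.as_file(ref) as path:
        rec = read_composition_table(path)[0]
    return formula_from_composition(rec.composition)


@dataclass(frozen=True)
class RedoxScenario:
    """Inputs of the balance.

    ``dzc_hypoxia`` and ``dzc_cancer`` are protein Z_C shifts relative to the
    normal (baseline) proteome; the lipid composition is held fixed.
    """

    lipid_formula: ElementalFormula = TRIACYLGLYCEROL
    protein_formula: ElementalFormula = field(default_factory=mean_human_protein_formula)
    lp_ratio_hypoxia: float = LP_RATIO_PRESETS["hypoxia"]
    dzc_hypoxia: float = -0.03
    dzc_cancer: float = +0.03

    def __post_init__(self) -> None:
        if self.lp_ratio_hypoxia <= 0:
            raise ValueError("L:P ratio must be positive")
        if abs(self.dzc_hypoxia) >= 1 or abs(self.dzc_cancer) >= 1:
            raise ValueError("|delta Z_C| must be < 1")


@dataclass(frozen=True)
class RedoxResult:
    """Solved cancer L:P ratio with the electron ledger."""

    lp_ratio_cancer: float
    percent_change: float
    electrons_per_g_protein: float  # mol e- released by protein oxidation
    mixture_zc_value: float
    zc_protein_normal: float
    zc_lipid: float


def solve_lipid_protein_ratio(scenario: RedoxScenario) -> RedoxResult:
    """Closed-form solve of the carbon-oxidation-state conservation.

    With 1 g protein and r grams lipid per gram protein, equate the
    carbon-weighted mixture Z_C of (cancer proteins + r_cancer lipid) to that
    of (hypoxia proteins + r_hypoxia lipid) and solve for r_cancer.
    """
    zp0 = zc(scenario.protein_formula)
    zl = zc(scenario.lipid_formula)
    zp_h = zp0 + scenario.dzc_hypoxia
    zp_c = zp0 + scenario.dzc_cancer
    cp = carbon_per_gram(scenario.protein_formula)
    cl = carbon_per_gram(scenario.lipid_formula)

    r_h = scenario.lp_ratio_hypoxia
    mix = (cp * zp_h + r_h * cl * zl) / (cp + r_h * cl)
    if abs(zp_c - zl) < 1e-12 or abs(mix - zl) < 1e-12:
        raise ValueError(
            "degenerate balance: lipid and cancer-protein oxidation states "
            "coincide, no finite lipid amount conserves the mixture Z_C"
        )
    r_c = cp * (zp_c - mix) / (cl * (mix - zl))
    if r_c <= 0:
        raise ValueError("no positive lipid:protein ratio satisfies the balance")
    return RedoxResult(
        lp_ratio_cancer=float(r_c),
        percent_change=float(100.0 * (r_c - r_h) / r_h),
        electrons_per_g_protein=float(cp * (zp_c - zp_h)),
        mixture_zc_value=float(mix),
        zc_protein_normal=float(zp0),
        zc_lipid=float(zl),
    )
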