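"""Standard Gibbs energies, ionization, and chemical affinity of formation.

The thermodynamic model evaluates, at a fixed reference condition (310.15 K,
1 bar), the per-residue chemical affinity of the reaction forming a protein
from the QEC+ basis species::

    A* = A / (2.303 R T)
       = log K + n̄_Cys log a_Cys + n̄_Glu log a_Glu + n̄_Gln log a_Gln
         + n̄_H2O log a_H2O + n̄_O2 log f_O2 - z̄ pH - log a_residue

where the overbar coefficients are the basis-reaction stoichiometry divided by
sequence length, log K comes from group-additivity standard Gibbs energies,
O2 enters as a gas-phase fugacity and H2O as a liquid-standard-state activity.
A* is an affine function of (log f_O2, log a_H2O) with slopes (n̄_O2, n̄_H2O),
which downstream code exploits to evaluate whole grids cheaply.

Ionization is a Henderson-Hasselbalch pKa surrogate: each ionizable group
contributes a fractional charge and a Gibbs correction of +/- 2.303 R T pKa
weighted by that fraction.  Disabling it reproduces the non-ionized model.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .composition import (
    AA3,
    AminoAcidComposition,
    BasisCoefficients,
    BasisSet,
    ElementalFormula,
    ProteinRecord,
    QEC_PLUS,
    formula_from_composition,
    project_onto_basis,
    residue_formula,
)

R_GAS = 8.314462618  # J / (mol K)
T_REFERENCE = 310.15  # K, 37 degrees C
P_REFERENCE = 1.0  # bar
LN10 = np.log(10.0)


def decadic_rt(temperature: float = T_REFERENCE) -> float:
    """2.303 R T in J/mol."""
    return LN10 * R_GAS * temperature


# ---------------------------------------------------------------------------
# Thermodynamic parameter table
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ("species", "kind", "formula", "G0_Jmol", "source")
_VALID_KINDS = {"basis", "residue", "terminus"}


@dataclass(frozen=True)
class ThermoTable:
    """Standard Gibbs energies (J/mol) at a fixed temperature and pressure.

    Holds one entry per basis species, one per amino-acid residue group, and
    one chain-terminus group (composition H2O).
    """

    basis_energies: Mapping[str, float]
    residue_energies: Mapping[str, float]
    terminus_energy: float
    temperature: float = T_REFERENCE
    pressure: float = P_REFERENCE

    def __post_init__(self) -> None:
        missing = set(AA3) - set(self.residue_energies)
        if missing:
            raise ValueError(f"thermo table missing residue groups: {sorted(missing)}")

    def g_basis(self, species: str) -> float:
        try:
            return float(self.basis_energies[species])
        except KeyError:
            raise KeyError(f"basis species {species!r} not in thermo table") from None

    def g_residue(self, aa3: str) -> float:
        try:
            return float(self.residue_energies[aa3])
        except KeyError:
            raise KeyError(f"residue group {aa3!r} not in thermo table") from None


def load_thermo_table(path: str | Path) -> ThermoTable:
    """Read and validate the delimited thermo-table format.

    Columns: ``species, kind (basis|residue|terminus), formula, G0_Jmol,
    source``.  Residue formulas are checked against the built-in residue
    compositions; every residue group must appear exactly once.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"thermo table missing columns: {sorted(missing)}")
    bad_kinds = set(df["kind"]) - _VALID_KINDS
    if bad_kinds:
        raise ValueError(f"invalid kind values: {sorted(bad_kinds)}")
    if not np.isfinite(df["G0_Jmol"]).all():
        raise ValueError("non-finite G0_Jmol entry")

    basis = {}
    for _, row in df[df["kind"] == "basis"].iterrows():
        basis[row["species"]] = float(row["G0_Jmol"])

    residues = {}
    for _, row in df[df["kind"] == "residue"].iterrows():
        aa = row["species"]
        if aa in residues:
            raise ValueError(f"duplicate residue group {aa!r}")
        if aa in AA3:
            expected = residue_formula(aa)
            got = ElementalFormula.from_string(str(row["formula"]))
            if np.max(np.abs(expected.as_vector() - got.as_vector())) > 1e-9:
                raise ValueError(
                    f"residue {aa!r} formula {row['formula']!r} does not match "
                    f"the polypeptide residue composition {expected.to_string()!r}"
                )
        residues[aa] = float(row["G0_Jmol"])

    term = df[df["kind"] == "terminus"]
    if len(term) != 1:
        raise ValueError("thermo table must contain exactly one terminus group")
    return ThermoTable(
        basis_energies=basis,
        residue_energies=residues,
        terminus_energy=float(term["G0_Jmol"].iloc[0]),
    )


def default_thermo_table() -> ThermoTable:
    """The packaged estimated table for 310.15 K, 1 bar (see its header)."""
    ref = importlib.resources.files("protpot") / "data" / "thermo_qec_310K.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_thermo_table(path)


def uniform_thermo_table(value: float = 0.0) -> ThermoTable:
    """A table with every energy set to ``value`` (useful for identities)."""
    return ThermoTable(
        basis_energies={sp: value for sp in ("Cys", "Glu", "Gln", "H2O", "O2", "H+")},
        residue_energies={aa: value for aa in AA3},
        terminus_energy=value,
    )


# ---------------------------------------------------------------------------
# Ionization (Henderson-Hasselbalch surrogate)
# ---------------------------------------------------------------------------

#: Default side-chain and terminus pKa values at the reference temperature.
DEFAULT_PKA: Mapping[str, float] = {
    "Asp": 3.65, "Glu": 4.25, "His": 6.00, "Cys": 8.30, "Tyr": 10.07,
    "Lys": 10.53, "Arg": 12.48, "Nterm": 8.00, "Cterm": 3.55,
}

_ACIDIC_GROUPS = ("Asp", "Glu", "Cys", "Tyr", "Cterm")  # deprotonate to -1
_BASIC_GROUPS = ("His", "Lys", "Arg", "Nterm")  # protonate to +1


@dataclass(frozen=True)
class IonizationModel:
    """pKa-based ionization of side chains and chain termini."""

    pka: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PKA))
    enabled: bool = True

    def __post_init__(self) -> None:
        if any(not np.isfinite(v) for v in self.pka.values()):
            raise ValueError("non-finite pKa")

    def alpha(self, group: str, pH: float) -> float:
        """Fractional ionization of ``group``: deprotonated fraction for
        acidic groups, protonated fraction for basic groups."""
        pka = self.pka[group]
        if group in _ACIDIC_GROUPS:
            return 1.0 / (1.0 + 10.0 ** (pka - pH))
        if group in _BASIC_GROUPS:
            return 1.0 / (1.0 + 10.0 ** (pH - pka))
        raise KeyError(f"unknown ionizable group {group!r}")


DISABLED_IONIZATION = IonizationModel(enabled=False)


@dataclass(frozen=True)
class IonizationState:
    """Total charge and its per-group breakdown for one protein."""

    z_total: float
    z_per_residue: float
    group_charges: Mapping[str, float]


def _ionizable_counts(comp: AminoAcidComposition) -> dict[str, float]:
    counts = {g: comp.count(g) for g in ("Asp", "Glu", "His", "Cys", "Tyr", "Lys", "Arg")}
    counts["Nterm"] = comp.chains
    counts["Cterm"] = comp.chains
    return counts


def ionization_state(
    comp: AminoAcidComposition,
    pH: float = 7.0,
    model: IonizationModel | None = None,
) -> IonizationState:
    """Average protein charge from the pKa model (zero when disabled)."""
    model = model if model is not None else IonizationModel()
    if not model.enabled:
        return IonizationState(0.0, 0.0, {})
    charges: dict[str, float] = {}
    for group, count in _ionizable_counts(comp).items():
        if count == 0:
            continue
        sign = -1.0 if group in _ACIDIC_GROUPS else +1.0
        charges[group] = sign * model.alpha(group, pH) * count
    z = float(sum(charges.values()))
    return IonizationState(z, z / comp.length, charges)


def _ionization_gibbs(
    comp: AminoAcidComposition, pH: float, model: IonizationModel, temperature: float
) -> float:
    """Gibbs correction for forming the ionized protein from the non-ionized
    one, Σ_g α_g * (±2.303 R T pKa_g) per group occurrence (J/mol).

    Deprotonation of an acidic group HA -> A- + H+ costs +2.303RT*pKa;
    protonation of a basic group B + H+ -> BH+ releases -2.303RT*pKa.
    """
    if not model.enabled:
        return 0.0
    rt = decadic_rt(temperature)
    total = 0.0
    for group, count in _ionizable_counts(comp).items():
        if count == 0:
            continue
        alpha = model.alpha(group, pH)
        sign = +1.0 if group in _ACIDIC_GROUPS else -1.0
        total += count * alpha * sign * rt * model.pka[group]
    return total


# ---------------------------------------------------------------------------
# Group-additivity Gibbs energy, logK, affinity
# ---------------------------------------------------------------------------

def _as_composition(protein: ProteinRecord | AminoAcidComposition) -> AminoAcidComposition:
    return protein.composition if isinstance(protein, ProteinRecord) else protein


def gibbs_per_residue(
    comp: AminoAcidComposition | ProteinRecord,
    table: ThermoTable,
    ionization: IonizationModel | None = None,
    pH: float = 7.0,
    terminal: bool = True,
) -> float:
    """Standard Gibbs energy of the (optionally ionized) protein per residue.

    Group additivity: Σ counts * G°(residue group) + chains * G°(terminus)
    plus the pKa ionization correction, divided by sequence length (J/mol).
    """
    comp = _as_composition(comp)
    ionization = ionization if ionization is not None else DISABLED_IONIZATION
    total = 0.0
    for aa, count in comp.counts.items():
        total += count * table.g_residue(aa)
    if terminal:
        total += comp.chains * table.terminus_energy
    total += _ionization_gibbs(comp, pH, ionization, table.temperature)
    return total / comp.length


def logK_per_residue(
    protein: ProteinRecord | AminoAcidComposition,
    basis: BasisSet = QEC_PLUS,
    table: ThermoTable | None = None,
    ionization: IonizationModel | None = None,
    pH: float = 7.0,
    terminal: bool = True,
) -> tuple[float, BasisCoefficients, float]:
    """Per-residue log K of the basis-species formation reaction.

    Returns ``(logK, coefficients, z_total)`` where the coefficients are the
    projection of the ionized elemental formula onto the basis (total, not
    per-residue) and logK = -ΔG°r / (2.303 R T length).
    """
    comp = _as_composition(protein)
    table = table if table is not None else default_thermo_table()
    ionization = ionization if ionization is not None else DISABLED_IONIZATION
    z = ionization_state(comp, pH, ionization).z_total if ionization.enabled else 0.0

    formula = formula_from_composition(comp, terminal_water=terminal).ionized(z)
    coefs = project_onto_basis(formula, basis, length=comp.length)

    g_protein = gibbs_per_residue(comp, table, ionization, pH, terminal) * comp.length
    g_basis = sum(c * table.g_basis(sp) for sp, c in coefs.as_dict().items())
    dg_reaction = g_protein - g_basis
    logk = -dg_reaction / (decadic_rt(table.temperature) * comp.length)
    return float(logk), coefs, float(z)


@dataclass(frozen=True)
class ThermoConditions:
    """Activities, fugacity and pH at which affinities are evaluated.

    Defaults: basis-species activities matched to mean human plasma
    concentrations (10^-3.6 Cys, 10^-4.5 Glu, 10^-3.2 Gln), pH 7, unit
    residue activity, 310.15 K.
    """

    log_fO2: float = -66.0
    log_aH2O: float = 0.0
    pH: float = 7.0
    log_a_basis: Mapping[str, float] = field(
        default_factory=lambda: {"Cys": -3.6, "Glu": -4.5, "Gln": -3.2}
    )
    log_a_residue: float = 0.0
    temperature: float = T_REFERENCE

    def log_activity(self, species: str) -> float:
        """log activity/fugacity of one basis species under these conditions."""
        if species == "H2O":
            return self.log_aH2O
        if species == "O2":
            return self.log_fO2
        if species == "H+":
            return -self.pH
        try:
            return float(self.log_a_basis[species])
        except KeyError:
            raise KeyError(f"no activity configured for basis species {species!r}") from None


DEFAULT_CONDITIONS = ThermoConditions()


@dataclass(frozen=True)
class AffinityValue:
    """Dimensionless per-residue affinity A/(2.303RT) with its audit trail.

    ``terms`` holds each additive contribution (logK, one per basis species,
    and the residue-activity term); they sum to ``a_star``.
    """

    a_star: float
    terms: Mapping[str, float]
    nbar: Mapping[str, float]
    z_per_residue: float

    def reconstruct(self) -> float:
        return float(sum(self.terms.values()))


def affinity_per_residue(
    protein: ProteinRecord | AminoAcidComposition,
    conditions: ThermoConditions = DEFAULT_CONDITIONS,
    basis: BasisSet = QEC_PLUS,
    table: ThermoTable | None = None,
    ionization: IonizationModel | None = None,
    terminal: bool = True,
) -> AffinityValue:
    """Evaluate A* = logK - logQ for one protein at one condition point."""
    table = table if table is not None else default_thermo_table()
    logk, coefs, _z = logK_per_residue(protein, basis, table, ionization,
                                       conditions.pH, terminal)
    nbar = coefs.per_residue
    terms: dict[str, float] = {"logK": logk}
    for sp, coef in nbar.items():
        terms[sp] = coef * conditions.log_activity(sp)
    terms["residue"] = -conditions.log_a_residue
    a_star = float(sum(terms.values()))
    return AffinityValue(a_star=a_star, terms=terms, nbar=nbar,
                         z_per_residue=nbar.get("H+", 0.0))


# ---------------------------------------------------------------------------
# Grids
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """A log f_O2 (x) by log a_H2O (y) evaluation grid."""

    x_min: float = -72.0
    x_max: float = -60.0
    nx: int = 129
    y_min: float = -4.0
    y_max: float = 2.0
    ny: int = 129

    def __post_init__(self) -> None:
        if self.nx < 2 or self.ny < 2:
            raise ValueError("grid needs at least 2 points per axis")
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError("grid axes must be strictly increasing")

    @property
    def x(self) -> np.ndarray:
        return np.linspace(self.x_min, self.x_max, self.nx)

    @property
    def y(self) -> np.ndarray:
        return np.linspace(self.y_min, self.y_max, self.ny)


DEFAULT_GRID = GridSpec()


def affinity_grid(
    proteins: Sequence[ProteinRecord | AminoAcidComposition],
    grid: GridSpec = DEFAULT_GRID,
    conditions: ThermoConditions = DEFAULT_CONDITIONS,
    basis: BasisSet = QEC_PLUS,
    table: ThermoTable | None = None,
    ionization: IonizationModel | None = None,
    terminal: bool = True,
) -> np.ndarray:
    """Per-protein A* over the grid, shape (n_proteins, ny, nx).

    Exploits that each protein's surface is affine in the two log variables:
    A*(x, y) = const + n̄_O2 x + n̄_H2O y.
    """
    proteins = list(proteins)
    if not proteins:
        raise ValueError("empty protein collection")
    table = table if table is not None else default_thermo_table()
    const = np.empty(len(proteins))
    slope_x = np.empty(len(proteins))
    slope_y = np.empty(len(proteins))
    for i, prot in enumerate(proteins):
        av = affinity_per_residue(prot, conditions, basis, table, ionization, terminal)
        slope_x[i] = av.nbar["O2"]
        slope_y[i] = av.nbar["H2O"]
        const[i] = av.a_star - slope_x[i] * conditions.log_fO2 - slope_y[i] * conditions.log_aH2O
    xx = grid.x[np.newaxis, np.newaxis, :]
    yy = grid.y[np.newaxis, :, np.newaxis]
    return (
        const[:, np.newaxis, np.newaxis]
        + slope_x[:, np.newaxis, np.newaxis] * xx
        + slope_y[:, np.newaxis, np.newaxis] * yy
    )
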