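"""Elemental composition of proteins and stoichiometric basis-species projection.

A protein's primary sequence fixes its elemental formula C_c H_h N_n O_o S_s^z.
Two intensive descriptors are derived from it:

* the average oxidation state of carbon,  Z_C = (-h + 3n + 2o + 2s + z) / c,
  which is independent of the choice of basis species and invariant to
  protonation (h and z change together); and
* the stoichiometric coefficients of the reaction forming the protein from a
  set of basis species (by default glutamine, glutamic acid, cysteine, H2O and
  O2 -- the "QEC" basis -- optionally extended with the proton, "QEC+").
  Dividing the coefficients by sequence length gives per-residue demands, in
  particular the water demand per residue (n̄_H2O) and oxygen demand (n̄_O2).

The projection is a linear solve over the element (and charge) balance, so any
full-rank basis is supported with one code path.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("protpot")

ELEMENTS = ("C", "H", "N", "O", "S")

#: Fixed column order of the composition-table dialect.
AA3 = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
)

AA1_TO_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}
AA3_TO_AA1 = {v: k for k, v in AA1_TO_AA3.items()}

#: One-letter codes that are legal in FASTA but have no defined composition
#: here; residues carrying them are dropped with a logged count.
NONSTANDARD_CODES = set("BZXUO*")


@dataclass(frozen=True)
class ElementalFormula:
    """Element counts C,H,N,O,S plus formal charge z.

    Counts may be fractional (averaged pools); they must be finite and, for
    any protein or residue-equivalent formula, carbon must be positive.
    """

    c: float = 0.0
    h: float = 0.0
    n: float = 0.0
    o: float = 0.0
    s: float = 0.0
    z: float = 0.0

    def __post_init__(self) -> None:
        for name in ("c", "h", "n", "o", "s", "z"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite element count: {name}")

    def as_vector(self) -> np.ndarray:
        """(c, h, n, o, s, z) as a float vector."""
        return np.array([self.c, self.h, self.n, self.o, self.s, self.z], float)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        return ElementalFormula(*(self.as_vector() + other.as_vector()))

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        return ElementalFormula(*(self.as_vector() - other.as_vector()))

    def __mul__(self, k: float) -> "ElementalFormula":
        return ElementalFormula(*(self.as_vector() * k))

    __rmul__ = __mul__

    def ionized(self, z: float) -> "ElementalFormula":
        """Formula after gaining ``z`` protons: C_c H_(h+z) ... ^z."""
        return replace(self, h=self.h + z, z=self.z + z)

    @classmethod
    def from_string(cls, text: str) -> "ElementalFormula":
        """Parse a plain formula string such as ``C55H102O6`` or ``C2H4NO2-1``.

        A trailing ``+k``/``-k`` is read as the formal charge.
        """
        m = re.fullmatch(r"((?:[A-Z][a-z]?\d*\.?\d*)+)([+-]\d+(?:\.\d+)?)?", text.strip())
        if not m:
            raise ValueError(f"unparseable formula: {text!r}")
        counts = dict.fromkeys(ELEMENTS, 0.0)
        for sym, num in re.findall(r"([A-Z][a-z]?)(\d*\.?\d*)", m.group(1)):
            if sym not in counts:
                raise ValueError(f"unsupported element {sym!r} in {text!r}")
            counts[sym] += float(num) if num else 1.0
        charge = float(m.group(2)) if m.group(2) else 0.0
        return cls(counts["C"], counts["H"], counts["N"], counts["O"], counts["S"], charge)

    def to_string(self) -> str:
        parts = []
        for sym, val in zip(ELEMENTS, self.as_vector()[:5]):
            if val == 0:
                continue
            num = f"{val:g}" if val != 1 else ""
            parts.append(f"{sym}{num}")
        out = "".join(parts)
        if self.z:
            out += f"{self.z:+g}"
        return out


WATER = ElementalFormula(h=2, o=1)

#: Free (non-ionized) amino-acid formulas, keyed by three-letter code.
AMINO_ACID_FORMULAS: Mapping[str, ElementalFormula] = {
    "Ala": ElementalFormula(3, 7, 1, 2, 0),
    "Arg": ElementalFormula(6, 14, 4, 2, 0),
    "Asn": ElementalFormula(4, 8, 2, 3, 0),
    "Asp": ElementalFormula(4, 7, 1, 4, 0),
    "Cys": ElementalFormula(3, 7, 1, 2, 1),
    "Gln": ElementalFormula(5, 10, 2, 3, 0),
    "Glu": ElementalFormula(5, 9, 1, 4, 0),
    "Gly": ElementalFormula(2, 5, 1, 2, 0),
    "His": ElementalFormula(6, 9, 3, 2, 0),
    "Ile": ElementalFormula(6, 13, 1, 2, 0),
    "Leu": ElementalFormula(6, 13, 1, 2, 0),
    "Lys": ElementalFormula(6, 14, 2, 2, 0),
    "Met": ElementalFormula(5, 11, 1, 2, 1),
    "Phe": ElementalFormula(9, 11, 1, 2, 0),
    "Pro": ElementalFormula(5, 9, 1, 2, 0),
    "Ser": ElementalFormula(3, 7, 1, 3, 0),
    "Thr": ElementalFormula(4, 9, 1, 3, 0),
    "Trp": ElementalFormula(11, 12, 2, 2, 0),
    "Tyr": ElementalFormula(9, 11, 1, 3, 0),
    "Val": ElementalFormula(5, 11, 1, 2, 0),
}


def residue_formula(aa3: str) -> ElementalFormula:
    """Formula of the amino-acid residue in a polypeptide (free AA minus H2O)."""
    return AMINO_ACID_FORMULAS[aa3] - WATER


@dataclass(frozen=True)
class AminoAcidComposition:
    """Counts of the 20 standard amino acids plus the number of chains.

    Counts may be fractional, supporting averaged (mean-proteome) compositions.
    """

    counts: Mapping[str, float]
    chains: float = 1

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(AA3)
        if unknown:
            raise ValueError(f"unknown amino acids: {sorted(unknown)}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative amino-acid count")
        if self.chains < 1:
            raise ValueError("chains must be >= 1")
        if self.length <= 0:
            raise ValueError("composition has zero length")

    @property
    def length(self) -> float:
        return float(sum(self.counts.values()))

    def count(self, aa3: str) -> float:
        return float(self.counts.get(aa3, 0.0))

    @classmethod
    def from_sequence(cls, sequence: str, chains: int = 1) -> "AminoAcidComposition":
        """Build a composition from a one-letter sequence.

        Whitespace is ignored; nonstandard codes (B, Z, X, U, O, *) are dropped
        with a logged count; any other character is an error.
        """
        seq = "".join(sequence.split()).upper()
        if not seq:
            raise ValueError("empty sequence")
        counts: dict[str, float] = {}
        dropped = 0
        for ch in seq:
            aa = AA1_TO_AA3.get(ch)
            if aa is None:
                if ch in NONSTANDARD_CODES:
                    dropped += 1
                    continue
                raise ValueError(f"invalid residue code {ch!r}")
            counts[aa] = counts.get(aa, 0.0) + 1.0
        if dropped:
            logger.warning("dropped %d nonstandard residues from sequence", dropped)
        if not counts:
            raise ValueError("sequence contains no standard residues")
        return cls(counts=counts, chains=chains)

    def scaled(self, k: float) -> "AminoAcidComposition":
        return AminoAcidComposition(
            {aa: v * k for aa, v in self.counts.items()}, chains=self.chains * k
        )


@dataclass(frozen=True)
class ProteinRecord:
    """A protein accession with its amino-acid composition."""

    id: str
    composition: AminoAcidComposition
    organism: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("empty protein id")


# ---------------------------------------------------------------------------
# Formula construction and Z_C
# ---------------------------------------------------------------------------

def formula_from_composition(
    comp: AminoAcidComposition, terminal_water: bool = True
) -> ElementalFormula:
    """Non-ionized elemental formula of a polypeptide.

    Sum of residue formulas plus, when ``terminal_water`` is true, one H2O per
    chain for the terminal -H and -OH groups.
    """
    vec = np.zeros(6)
    for aa, cnt in comp.counts.items():
        vec += cnt * residue_formula(aa).as_vector()
    if terminal_water:
        vec += comp.chains * WATER.as_vector()
    return ElementalFormula(*vec)


def formula_from_sequence(
    sequence: str, chains: int = 1, terminal_water: bool = True
) -> ElementalFormula:
    """Elemental formula straight from a one-letter sequence."""
    comp = AminoAcidComposition.from_sequence(sequence, chains=chains)
    return formula_from_composition(comp, terminal_water=terminal_water)


def zc(formula: ElementalFormula) -> float:
    """Average oxidation state of carbon, (-h + 3n + 2o + 2s + z)/c."""
    if formula.c <= 0:
        raise ValueError("Z_C requires a formula with carbon (c > 0)")
    return (-formula.h + 3 * formula.n + 2 * formula.o + 2 * formula.s + formula.z) / formula.c


# ---------------------------------------------------------------------------
# Basis sets and projection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BasisSet:
    """An ordered set of basis species with a full-rank stoichiometric matrix."""

    name: str
    species: tuple[str, ...]
    formulas: tuple[ElementalFormula, ...]

    def __post_init__(self) -> None:
        if len(self.species) != len(self.formulas):
            raise ValueError("species/formula length mismatch")

    @property
    def includes_proton(self) -> bool:
        return "H+" in self.species

    def matrix(self) -> np.ndarray:
        """Element+charge stoichiometric matrix, one column per species."""
        return np.column_stack([f.as_vector() for f in self.formulas])

    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix()))


PROTON = ElementalFormula(h=1, z=1)

QEC = BasisSet(
    "QEC",
    ("Cys", "Glu", "Gln", "H2O", "O2"),
    (
        AMINO_ACID_FORMULAS["Cys"],
        AMINO_ACID_FORMULAS["Glu"],
        AMINO_ACID_FORMULAS["Gln"],
        WATER,
        ElementalFormula(o=2),
    ),
)

QEC_PLUS = BasisSet(
    "QEC+",
    QEC.species + ("H+",),
    QEC.formulas + (PROTON,),
)

INORGANIC = BasisSet(
    "inorganic",
    ("CO2", "NH3", "H2S", "H2O", "O2"),
    (
        ElementalFormula(c=1, o=2),
        ElementalFormula(h=3, n=1),
        ElementalFormula(h=2, s=1),
        WATER,
        ElementalFormula(o=2),
    ),
)

BASIS_SETS: Mapping[str, BasisSet] = {"QEC": QEC, "QEC+": QEC_PLUS, "inorganic": INORGANIC}


@dataclass(frozen=True)
class BasisCoefficients:
    """Stoichiometric coefficients of the basis-species formation reaction.

    ``coefficients[i]`` multiplies ``basis.species[i]``; ``per_residue`` holds
    the same values divided by sequence length (the overbar quantities).
    """

    basis: BasisSet
    coefficients: np.ndarray
    length: float

    def coeff(self, species: str) -> float:
        return float(self.coefficients[self.basis.species.index(species)])

    @property
    def n_H2O(self) -> float:
        return self.coeff("H2O")

    @property
    def n_O2(self) -> float:
        return self.coeff("O2")

    @property
    def z_H(self) -> float:
        return self.coeff("H+") if self.basis.includes_proton else 0.0

    @property
    def per_residue(self) -> dict[str, float]:
        return {sp: float(v) / self.length for sp, v in zip(self.basis.species, self.coefficients)}

    def as_dict(self) -> dict[str, float]:
        return {sp: float(v) for sp, v in zip(self.basis.species, self.coefficients)}


def project_onto_basis(
    formula: ElementalFormula,
    basis: BasisSet = QEC_PLUS,
    length: float = 1,
    tol: float = 1e-9,
) -> BasisCoefficients:
    """Solve the element (and charge) balance for the basis-species reaction.

    For a proton-bearing basis the solve covers all five elements plus charge;
    without the proton the target formula must be charge-neutral.  The
    residual of the balance is checked against ``tol`` per element.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    mat = basis.matrix()
    target = formula.as_vector()
    if not basis.includes_proton:
        if abs(formula.z) > tol:
            raise ValueError(
                f"basis {basis.name!r} has no proton; cannot represent charge {formula.z}"
            )
        mat = mat[:5]
        target = target[:5]
    if mat.shape[0] != mat.shape[1]:
        raise ValueError(
            f"basis {basis.name!r} is not square over the balance ({mat.shape[1]} species, "
            f"{mat.shape[0]} constraints)"
        )
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        raise ValueError(
            f"basis {basis.name!r} is rank-deficient (rank {rank} < {mat.shape[1]}); "
            "projection is not unique"
        )
    coeffs = np.linalg.solve(mat, target)
    residual = mat @ coeffs - target
    if np.max(np.abs(residual)) > tol:
        raise ValueError(f"projection residual {np.max(np.abs(residual)):.2e} exceeds {tol}")
    return BasisCoefficients(basis=basis, coefficients=coeffs, length=float(length))


# ---------------------------------------------------------------------------
# Per-protein metrics
# ---------------------------------------------------------------------------

def compute_metrics(
    proteins: Iterable[ProteinRecord],
    basis: BasisSet = QEC,
    terminal_water: bool = True,
) -> pd.DataFrame:
    """Per-protein table of Z_C, n̄_H2O, n̄_O2 and length.

    Z_C is computed on the non-ionized formula; the per-residue basis demands
    are those of the same formula.  Row order follows the input.
    """
    rows = []
    for rec in proteins:
        f = formula_from_composition(rec.composition, terminal_water=terminal_water)
        coefs = project_onto_basis(f, basis, length=rec.composition.length)
        pr = coefs.per_residue
        rows.append(
            {
                "id": rec.id,
                "Zc": zc(f),
                "nH2O": pr["H2O"],
                "nO2": pr["O2"],
                "length": rec.composition.length,
            }
        )
    if not rows:
        raise ValueError("no proteins given")
    return pd.DataFrame(rows).set_index("id")


def basis_correlation_report(
    proteins: Sequence[ProteinRecord],
    basis_a: BasisSet = QEC,
    basis_b: BasisSet = INORGANIC,
    method: str = "spearman",
) -> dict[str, dict[str, float]]:
    """Correlation of n̄_O2 and n̄_H2O with Z_C under two alternative bases.

    Used to compare the QEC basis (n̄_O2 tracks oxidation state, n̄_H2O nearly
    decorrelated) with an inorganic basis.  Degenerate (constant) metrics give
    NaN correlations.
    """
    if len(proteins) < 3:
        raise ValueError("need at least 3 proteins")
    import warnings

    report: dict[str, dict[str, float]] = {}
    for basis in (basis_a, basis_b):
        tab = compute_metrics(proteins, basis=basis)
        with warnings.catch_warnings():
            # constant metrics are a legal degenerate input; reported as NaN
            warnings.simplefilter("ignore")
            report[basis.name] = {
                "corr_nO2_Zc": float(tab["nO2"].corr(tab["Zc"], method=method)),
                "corr_nH2O_Zc": float(tab["nH2O"].corr(tab["Zc"], method=method)),
            }
    return report


# ---------------------------------------------------------------------------
# File formats: FASTA and composition tables
# ---------------------------------------------------------------------------

_UNIPROT_HEADER = re.compile(r"^(?:sp|tr)\|([^|]+)\|")


def _accession_from_header(header: str) -> str:
    m = _UNIPROT_HEADER.match(header)
    return m.group(1) if m else header.split()[0]


def read_fasta(path: str | Path, organism: str = "") -> list[ProteinRecord]:
    """Read protein records from a FASTA file (gzip transparently supported).

    UniProt-style headers (``sp|ACC|NAME``) yield the accession as the id.
    """
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    records = []
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            comp = AminoAcidComposition.from_sequence(str(rec.seq))
            records.append(
                ProteinRecord(id=_accession_from_header(rec.id), composition=comp,
                              organism=organism)
            )
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


COMPOSITION_COLUMNS = ("id", "organism", "chains") + AA3


def write_composition_table(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write the fixed-dialect composition table (CSV, column order fixed)."""
    rows = []
    for rec in records:
        row: dict[str, object] = {"id": rec.id, "organism": rec.organism,
                                  "chains": rec.composition.chains}
        for aa in AA3:
            row[aa] = rec.composition.count(aa)
        rows.append(row)
    pd.DataFrame(rows, columns=list(COMPOSITION_COLUMNS)).to_csv(path, index=False)


def read_composition_table(path: str | Path) -> list[ProteinRecord]:
    """Read a composition table written by :func:`write_composition_table`.

    Comma- and tab-separated files are both accepted.
    """
    path = Path(path)
    with path.open() as fh:
        first = next((ln for ln in fh if not ln.startswith("#")), "")
    sep = "\t" if "\t" in first else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = set(COMPOSITION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"composition table missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        counts = {aa: float(row[aa]) for aa in AA3 if float(row[aa]) != 0.0}
        comp = AminoAcidComposition(counts=counts, chains=float(row["chains"]))
        records.append(ProteinRecord(id=str(row["id"]), composition=comp,
                                     organism=str(row["organism"]) if pd.notna(row["organism"]) else ""))
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate protein id in table: {rec.id}")
        seen.add(rec.id)
    return records


def records_as_mapping(records: Iterable[ProteinRecord]) -> dict[str, ProteinRecord]:
    return {rec.id: rec for rec in records}
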