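"""Synthetic data, configuration, manifests and machine-readable logging.

The synthetic generator emulates one differential-expression experiment: two
groups of proteins (up- and down-expressed) whose amino-acid frequencies are
exponential tilts of a human-proteome-like baseline along the per-residue
carbon oxidation state (tilt ``beta``) and water demand (tilt ``gamma``)::

    f_i  ∝  baseline_i * exp(beta * Zc_i + gamma * nH2O_i)

Positive ``beta`` pushes a group toward oxidized residues, positive ``gamma``
toward water-demanding ones.  Tilts can be calibrated numerically so the
expected between-group difference hits a target (e.g. ΔZ_C ≈ -0.03 for a
hypoxia-like experiment).  Lengths are log-normal (median ~375 residues);
all randomness is driven by one integer seed.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .composition import (
    AA3,
    AminoAcidComposition,
    ProteinRecord,
    QEC,
    ElementalFormula,
    project_onto_basis,
    read_composition_table,
    residue_formula,
    write_composition_table,
    zc,
)
from .diffexpr import ExpressionDataset

logger = logging.getLogger("protpot")

__all__ = [
    "SyntheticSpec", "DatasetManifest", "ManifestEntry", "JsonLogWriter",
    "baseline_frequencies", "residue_zc_values", "residue_nh2o_values",
    "tilted_frequencies", "expected_zc", "expected_nh2o",
    "calibrate_beta", "calibrate_gamma", "preset_spec",
    "generate_synthetic_proteome", "generate_synthetic_experiment",
    "write_dataset_table", "read_manifest", "write_manifest",
]


# ---------------------------------------------------------------------------
# Residue-level reference vectors
# ---------------------------------------------------------------------------

def residue_zc_values() -> dict[str, float]:
    """Z_C of each polypeptide residue formula."""
    return {aa: zc(residue_formula(aa)) for aa in AA3}


def residue_nh2o_values() -> dict[str, float]:
    """Water demand of each residue formula under the QEC basis."""
    return {aa: project_onto_basis(residue_formula(aa), QEC).n_H2O for aa in AA3}


def baseline_frequencies() -> dict[str, float]:
    """Human-proteome-like residue frequencies (from the packaged synthetic
    mean composition), normalized to sum to one."""
    ref = importlib.resources.files("protpot") / "data" / "human_proteome_mean_aa_synthetic.csv"
    with importlib.resources.as_file(ref) as path:
        rec = read_composition_table(path)[0]
    total = rec.composition.length
    return {aa: rec.composition.count(aa) / total for aa in AA3}


# ---------------------------------------------------------------------------
# Tilts and their calibration
# ---------------------------------------------------------------------------

def tilted_frequencies(
    baseline: Mapping[str, float], beta: float = 0.0, gamma: float = 0.0
) -> dict[str, float]:
    """Exponentially tilted frequencies along residue Z_C and n̄_H2O."""
    z = residue_zc_values()
    w = residue_nh2o_values()
    raw = {aa: baseline[aa] * np.exp(beta * z[aa] + gamma * w[aa]) for aa in AA3}
    total = sum(raw.values())
    if not np.isfinite(total) or total <= 0:
        raise ValueError("tilt produced invalid frequencies")
    return {aa: v / total for aa, v in raw.items()}


def expected_zc(freqs: Mapping[str, float]) -> float:
    """Expected protein Z_C under residue frequencies (carbon-weighted mean
    of residue Z_C; terminal groups excluded)."""
    z = residue_zc_values()
    num = sum(freqs[aa] * residue_formula(aa).c * z[aa] for aa in AA3)
    den = sum(freqs[aa] * residue_formula(aa).c for aa in AA3)
    return num / den


def expected_nh2o(freqs: Mapping[str, float]) -> float:
    """Expected per-residue water demand (terminal groups excluded)."""
    w = residue_nh2o_values()
    return sum(freqs[aa] * w[aa] for aa in AA3)


def _calibrate(target_shift: float, baseline: Mapping[str, float], which: str) -> float:
    expect = expected_zc if which == "beta" else expected_nh2o
    base_val = expect(baseline)

    def objective(t: float) -> float:
        f = tilted_frequencies(baseline, beta=t) if which == "beta" \
            else tilted_frequencies(baseline, gamma=t)
        return expect(f) - base_val - target_shift

    if target_shift == 0:
        return 0.0
    lo, hi = -20.0, 20.0
    return float(brentq(objective, lo, hi, xtol=1e-10))


def calibrate_beta(target_delta_zc: float, baseline: Mapping[str, float] | None = None) -> float:
    """Tilt beta whose expected Z_C shift from baseline equals the target."""
    return _calibrate(target_delta_zc, baseline or baseline_frequencies(), "beta")


def calibrate_gamma(target_delta_nh2o: float, baseline: Mapping[str, float] | None = None) -> float:
    """Tilt gamma whose expected n̄_H2O shift from baseline equals the target."""
    return _calibrate(target_delta_nh2o, baseline or baseline_frequencies(), "gamma")


# ---------------------------------------------------------------------------
# Synthetic experiments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSpec:
    """Controls for one synthetic differential-expression experiment.

    Tilts apply per group; the seed fixes all randomness.  Lengths are
    log-normal with the given median and log-space sigma, floored at 20
    residues.
    """

    seed: int
    n_up: int = 100
    n_down: int = 100
    length_median: float = 375.0
    length_sigma: float = 0.5
    baseline: Mapping[str, float] = field(default_factory=baseline_frequencies)
    beta_up: float = 0.0
    gamma_up: float = 0.0
    beta_down: float = 0.0
    gamma_down: float = 0.0
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_up < 1 or self.n_down < 1:
            raise ValueError("group sizes must be >= 1")
        total = sum(self.baseline.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"baseline frequencies sum to {total}, not 1")


def preset_spec(preset: str, seed: int, n_up: int = 100, n_down: int = 100) -> SyntheticSpec:
    """Named study-condition presets.

    ``hypoxia``: up group tilted to ΔZ_C ≈ -0.03; ``cancer``: +0.03;
    ``hyperosmotic``: up group tilted to Δn̄_H2O ≈ -0.02; ``null``: no tilt.
    """
    base = baseline_frequencies()
    kwargs: dict[str, float] = {}
    if preset == "hypoxia":
        kwargs["beta_up"] = calibrate_beta(-0.03, base)
    elif preset == "cancer":
        kwargs["beta_up"] = calibrate_beta(+0.03, base)
    elif preset == "hyperosmotic":
        kwargs["gamma_up"] = calibrate_gamma(-0.02, base)
    elif preset != "null":
        raise ValueError(f"unknown preset {preset!r}")
    return SyntheticSpec(seed=seed, n_up=n_up, n_down=n_down, baseline=base,
                         name=f"{preset}_seed{seed}", **kwargs)


def _sample_group(
    rng: np.random.Generator, prefix: str, count: int,
    freqs: Mapping[str, float], spec: SyntheticSpec,
) -> list[ProteinRecord]:
    probs = np.array([freqs[aa] for aa in AA3])
    lengths = np.maximum(
        20, np.rint(rng.lognormal(np.log(spec.length_median), spec.length_sigma, count))
    ).astype(int)
    records = []
    for i, length in enumerate(lengths):
        counts = rng.multinomial(length, probs)
        comp = AminoAcidComposition(
            {aa: float(c) for aa, c in zip(AA3, counts) if c > 0}, chains=1
        )
        records.append(ProteinRecord(id=f"{prefix}{i + 1:04d}", composition=comp,
                                     organism="synthetic"))
    return records


def generate_synthetic_proteome(spec: SyntheticSpec) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Sample both groups' proteins; returns (records, metrics-ready table).

    Up-group IDs are ``UP0001..``, down-group ``DN0001..``; reproducible from
    the seed alone.
    """
    rng = np.random.default_rng(spec.seed)
    up_freqs = tilted_frequencies(spec.baseline, spec.beta_up, spec.gamma_up)
    down_freqs = tilted_frequencies(spec.baseline, spec.beta_down, spec.gamma_down)
    records = _sample_group(rng, "UP", spec.n_up, up_freqs, spec)
    records += _sample_group(rng, "DN", spec.n_down, down_freqs, spec)
    rows = [{"id": r.id, "organism": r.organism, "chains": r.composition.chains,
             **{aa: r.composition.count(aa) for aa in AA3}} for r in records]
    return records, pd.DataFrame(rows)


def generate_synthetic_experiment(
    spec: SyntheticSpec,
) -> tuple[ExpressionDataset, list[ProteinRecord], dict]:
    """One end-to-end consumable experiment: dataset + proteome + manifest entry."""
    records, _table = generate_synthetic_proteome(spec)
    dataset = ExpressionDataset(
        name=spec.name,
        up_ids=tuple(r.id for r in records if r.id.startswith("UP")),
        down_ids=tuple(r.id for r in records if r.id.startswith("DN")),
        description=(
            f"synthetic experiment (beta_up={spec.beta_up:.4g}, "
            f"gamma_up={spec.gamma_up:.4g}, seed={spec.seed})"
        ),
    )
    entry = {
        "name": spec.name, "description": dataset.description,
        "file": f"{spec.name}_dataset.csv", "source": "synthetic generator",
        "organism": "synthetic", "labels": ["down", "up"],
    }
    return dataset, records, entry


# ---------------------------------------------------------------------------
# Flat-file adapters, manifests, logs
# ---------------------------------------------------------------------------

def write_dataset_table(dataset: ExpressionDataset, path: str | Path) -> None:
    rows = [{"id": i, "direction": "up"} for i in dataset.up_ids]
    rows += [{"id": i, "direction": "down"} for i in dataset.down_ids]
    pd.DataFrame(rows, columns=["id", "direction"]).to_csv(path, index=False)


@dataclass(frozen=True)
class ManifestEntry:
    name: str
    file: str
    description: str = ""
    source: str = ""
    organism: str = ""
    labels: tuple[str, str] = ("down", "up")


@dataclass(frozen=True)
class DatasetManifest:
    """Bookkeeping for a suite of dataset tables."""

    entries: tuple[ManifestEntry, ...]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("duplicate dataset names in manifest")


def read_manifest(path: str | Path, check_files: bool = True) -> DatasetManifest:
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    entries = []
    for item in raw.get("datasets", []):
        entry = ManifestEntry(
            name=item["name"], file=item["file"],
            description=item.get("description", ""), source=item.get("source", ""),
            organism=item.get("organism", ""),
            labels=tuple(item.get("labels", ("down", "up"))),
        )
        if check_files and not (path.parent / entry.file).exists():
            raise FileNotFoundError(f"manifest entry {entry.name!r}: missing {entry.file}")
        entries.append(entry)
    return DatasetManifest(entries=tuple(entries))


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    payload = {"datasets": [
        {"name": e.name, "file": e.file, "description": e.description,
         "source": e.source, "organism": e.organism, "labels": list(e.labels)}
        for e in manifest.entries
    ]}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


class JsonLogWriter:
    """JSON-lines event log for auditable data cleaning."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self._fh = self.path.open("a")

    def event(self, kind: str, **fields) -> None:
        self._fh.write(json.dumps({"event": kind, **fields}, sort_keys=True) + "\n")
        self._fh.flush()

    def close(self) -> None:
        self._fh.close()

    def __enter__(self) -> "JsonLogWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()
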