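"""Weighted rank-difference potential diagrams over log f_O2 x log a_H2O.

At every grid node, the formation affinities of all proteins in a dataset are
ranked (ascending, midranks for ties) and summarized by the weighted rank
difference

    WRD = 2 * ( (n_down / n) * Σ r_up  -  (n_up / n) * Σ r_down ),

which is bounded by +/- n_up * n_down (equality iff the groups separate
completely in affinity rank), antisymmetric under swapping the groups, and --
being a rank statistic -- invariant under any strictly monotone transform of
the affinities.  The zero level of the WRD field is the "equipotential line"
where the two groups have rank-wise equal formation potential; diagrams for
several datasets are merged by the node-wise arithmetic mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata
from skimage import measure

from .composition import ProteinRecord
from .diffexpr import ComparisonResult, ExpressionDataset, resolve_ids
from .thermo import (
    DEFAULT_CONDITIONS,
    DEFAULT_GRID,
    GridSpec,
    IonizationModel,
    QEC_PLUS,
    ThermoConditions,
    ThermoTable,
    affinity_grid,
)

__all__ = [
    "GridSpec", "PotentialDiagram", "MergedDiagram", "ContourResult",
    "wrd", "wrd_at_point", "potential_diagram", "zero_contour_positions",
    "merge_diagrams", "group_and_summarize", "write_diagram", "read_diagram",
    "plot_diagram",
]


# ---------------------------------------------------------------------------
# The WRD statistic
# ---------------------------------------------------------------------------

def wrd(up_values: Sequence[float], down_values: Sequence[float]) -> float:
    """Weighted rank difference of two groups of affinities."""
    up = np.asarray(up_values, float)
    down = np.asarray(down_values, float)
    if up.size == 0 or down.size == 0:
        raise ValueError("both groups need at least one protein")
    n_up, n_down = up.size, down.size
    n = n_up + n_down
    ranks = rankdata(np.concatenate([up, down]), method="average")
    return float(2.0 * ((n_down / n) * ranks[:n_up].sum() - (n_up / n) * ranks[n_up:].sum()))


def wrd_at_point(
    affinities: Mapping[str, float],
    up_ids: Sequence[str],
    down_ids: Sequence[str],
) -> float:
    """WRD from a per-protein affinity mapping and the two ID groups.

    Every protein must belong to exactly one group.
    """
    overlap = set(up_ids) & set(down_ids)
    if overlap:
        raise ValueError(f"IDs in both groups: {sorted(overlap)[:5]}")
    return wrd([affinities[i] for i in up_ids], [affinities[i] for i in down_ids])


def _wrd_field(a_up: np.ndarray, a_down: np.ndarray) -> np.ndarray:
    """Node-wise WRD for stacked affinity grids (n_up, ny, nx), (n_down, ny, nx)."""
    n_up, n_down = a_up.shape[0], a_down.shape[0]
    n = n_up + n_down
    ranks = rankdata(np.concatenate([a_up, a_down], axis=0), method="average", axis=0)
    r_up = ranks[:n_up].sum(axis=0)
    r_down = ranks[n_up:].sum(axis=0)
    return 2.0 * ((n_down / n) * r_up - (n_up / n) * r_down)


# ---------------------------------------------------------------------------
# Diagrams
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PotentialDiagram:
    """WRD values on a grid for one dataset (field shape (ny, nx))."""

    grid: GridSpec
    field: np.ndarray
    name: str
    n_up: int
    n_down: int

    def __post_init__(self) -> None:
        if self.field.shape != (self.grid.ny, self.grid.nx):
            raise ValueError("field shape does not match grid")
        bound = self.n_up * self.n_down + 1e-9
        if np.max(np.abs(self.field)) > bound:
            raise ValueError("|WRD| exceeds n_up * n_down")


def potential_diagram(
    dataset: ExpressionDataset,
    proteome: Mapping[str, ProteinRecord],
    grid: GridSpec = DEFAULT_GRID,
    conditions: ThermoConditions = DEFAULT_CONDITIONS,
    basis=QEC_PLUS,
    table: ThermoTable | None = None,
    ionization: IonizationModel | None = None,
) -> PotentialDiagram:
    """Build the WRD field for one dataset.

    IDs are resolved against ``proteome`` (isoform fallback as in group
    comparisons); affinities come from the affine per-protein surfaces.
    """
    import pandas as pd

    index = pd.DataFrame(index=list(proteome))
    up, up_missing = resolve_ids(dataset.up_ids, index)
    down, down_missing = resolve_ids(dataset.down_ids, index)
    if not up or not down:
        raise ValueError(
            f"dataset {dataset.name!r}: unresolvable group "
            f"(missing up: {up_missing[:5]}, down: {down_missing[:5]})"
        )
    a_up = affinity_grid([proteome[i] for i in up], grid, conditions, basis, table, ionization)
    a_down = affinity_grid([proteome[i] for i in down], grid, conditions, basis, table, ionization)
    return PotentialDiagram(
        grid=grid, field=_wrd_field(a_up, a_down), name=dataset.name,
        n_up=len(up), n_down=len(down),
    )


# ---------------------------------------------------------------------------
# Equipotential (zero WRD) contours
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContourResult:
    """Zero-level contour of a WRD field.

    ``polylines`` are (k, 2) arrays of (x, y) data coordinates; ``position``
    is the mean contour coordinate along the requested axis (NaN when the
    field never crosses zero).
    """

    crossing: bool
    polylines: tuple[np.ndarray, ...]
    position: float
    axis: str


def zero_contour_positions(
    diagram: PotentialDiagram | "MergedDiagram", axis: str = "x"
) -> ContourResult:
    """Extract the equipotential line by marching squares and reduce it to a
    scalar position along ``axis`` ("x" = log f_O2, "y" = log a_H2O).

    A field of one sign yields a "no crossing" result (not an exception); a
    field that is exactly zero everywhere is a plateau and reports the axis
    midpoint.
    """
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    grid, field = diagram.grid, diagram.field
    fmin, fmax = float(field.min()), float(field.max())
    if fmin == 0.0 and fmax == 0.0:
        pos = (grid.x_min + grid.x_max) / 2 if axis == "x" else (grid.y_min + grid.y_max) / 2
        return ContourResult(True, (), pos, axis)
    if fmin > 0.0 or fmax < 0.0:
        return ContourResult(False, (), float("nan"), axis)
    dx = (grid.x_max - grid.x_min) / (grid.nx - 1)
    dy = (grid.y_max - grid.y_min) / (grid.ny - 1)
    polylines = []
    for rc in measure.find_contours(field, 0.0):
        xs = grid.x_min + rc[:, 1] * dx
        ys = grid.y_min + rc[:, 0] * dy
        polylines.append(np.column_stack([xs, ys]))
    if not polylines:
        return ContourResult(False, (), float("nan"), axis)
    verts = np.vstack(polylines)
    pos = float(verts[:, 0].mean()) if axis == "x" else float(verts[:, 1].mean())
    return ContourResult(True, tuple(polylines), pos, axis)


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MergedDiagram:
    """Node-wise mean WRD of several diagrams plus per-member equipotential
    positions and their median / quartiles (linear-interpolation rule)."""

    grid: GridSpec
    field: np.ndarray
    members: tuple[str, ...]
    positions: tuple[float, ...]
    median: float
    q1: float
    q3: float
    axis: str

    @property
    def name(self) -> str:
        return "+".join(self.members)


def merge_diagrams(
    diagrams: Sequence[PotentialDiagram], axis: str = "x"
) -> MergedDiagram:
    """Arithmetic mean of the WRD fields at all grid points.

    All member diagrams must share one grid.  Per-member equipotential
    positions along ``axis`` are summarized by median, Q1 and Q3 (members
    without a zero crossing are left out of the quantiles).
    """
    if not diagrams:
        raise ValueError("nothing to merge")
    grid = diagrams[0].grid
    for d in diagrams[1:]:
        if d.grid != grid:
            raise ValueError("cannot merge diagrams with different grids")
    field = np.mean([d.field for d in diagrams], axis=0)
    positions = tuple(zero_contour_positions(d, axis).position for d in diagrams)
    finite = [p for p in positions if np.isfinite(p)]
    if finite:
        q1, med, q3 = (float(v) for v in np.percentile(finite, [25, 50, 75]))
    else:
        q1 = med = q3 = float("nan")
    return MergedDiagram(
        grid=grid, field=field, members=tuple(d.name for d in diagrams),
        positions=positions, median=med, q1=q1, q3=q3, axis=axis,
    )


def group_and_summarize(
    results: Mapping[str, ComparisonResult],
    datasets: Mapping[str, ExpressionDataset],
    proteomes: Mapping[str, Mapping[str, ProteinRecord]] | Mapping[str, ProteinRecord],
    predicate: Callable[[ComparisonResult], bool],
    axis: str = "x",
    grid: GridSpec = DEFAULT_GRID,
    conditions: ThermoConditions = DEFAULT_CONDITIONS,
    table: ThermoTable | None = None,
    ionization: IonizationModel | None = None,
) -> tuple[MergedDiagram | None, tuple[str, ...]]:
    """Select datasets by a classification predicate and merge their diagrams.

    ``proteomes`` is either one shared proteome mapping or a per-dataset-name
    mapping of them.  Returns (merged diagram or None for an empty group,
    member names); membership order follows ``results``.
    """
    members = tuple(name for name, res in results.items() if predicate(res))
    if not members:
        return None, ()
    shared = bool(proteomes) and isinstance(next(iter(proteomes.values())), ProteinRecord)
    diagrams = []
    for name in members:
        prot = proteomes if shared else proteomes[name]
        diagrams.append(
            potential_diagram(datasets[name], prot, grid, conditions,
                              table=table, ionization=ionization)
        )
    return merge_diagrams(diagrams, axis=axis), members


# ---------------------------------------------------------------------------
# Serialization and plotting
# ---------------------------------------------------------------------------

def write_diagram(diagram: PotentialDiagram | MergedDiagram, prefix: str | Path) -> None:
    """Write ``<prefix>.txt`` (axes header + node values) and ``<prefix>.json``
    (metadata)."""
    prefix = Path(prefix)
    g = diagram.grid
    header = (
        f"# WRD field, rows = log a_H2O ({g.y_min} .. {g.y_max}, {g.ny}), "
        f"columns = log f_O2 ({g.x_min} .. {g.x_max}, {g.nx})"
    )
    np.savetxt(prefix.with_suffix(".txt"), diagram.field, header=header, fmt="%.8g")
    meta: dict[str, object] = {
        "grid": {"x_min": g.x_min, "x_max": g.x_max, "nx": g.nx,
                 "y_min": g.y_min, "y_max": g.y_max, "ny": g.ny},
    }
    if isinstance(diagram, MergedDiagram):
        meta.update(members=list(diagram.members), axis=diagram.axis,
                    positions=[None if not np.isfinite(p) else p for p in diagram.positions],
                    median=None if not np.isfinite(diagram.median) else diagram.median,
                    q1=None if not np.isfinite(diagram.q1) else diagram.q1,
                    q3=None if not np.isfinite(diagram.q3) else diagram.q3)
    else:
        meta.update(name=diagram.name, n_up=diagram.n_up, n_down=diagram.n_down)
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_diagram(prefix: str | Path) -> PotentialDiagram:
    """Read a single-dataset diagram written by :func:`write_diagram`."""
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    field = np.loadtxt(prefix.with_suffix(".txt"))
    return PotentialDiagram(
        grid=GridSpec(**meta["grid"]), field=field, name=meta["name"],
        n_up=meta["n_up"], n_down=meta["n_down"],
    )


def plot_diagram(diagram: PotentialDiagram | MergedDiagram, path: str | Path) -> None:
    """Schematic red/blue potential diagram with a white equipotential line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = diagram.grid
    vmax = max(float(np.max(np.abs(diagram.field))), 1e-12)
    fig, ax = plt.subplots(figsize=(4.2, 4.0))
    ax.imshow(diagram.field, origin="lower", cmap="RdBu_r", vmin=-vmax, vmax=vmax,
              extent=(g.x_min, g.x_max, g.y_min, g.y_max), aspect="auto")
    contour = zero_contour_positions(diagram)
    for line in contour.polylines:
        ax.plot(line[:, 0], line[:, 1], color="white", lw=2)
    ax.set_xlabel(r"$\log f_{\mathrm{O_2}}$")
    ax.set_ylabel(r"$\log a_{\mathrm{H_2O}}$")
    title = diagram.name if isinstance(diagram, PotentialDiagram) else \
        f"merged ({len(diagram.members)} datasets)"
    ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
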