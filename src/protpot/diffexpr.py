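"""Differential-expression datasets and group-comparison statistics.

A dataset is two lists of protein IDs: down-expressed (n1) and up-expressed
(n2) in some comparison (tumor vs normal, hypoxia vs control, ...).  After
joining to per-protein compositional metrics (Z_C and n̄_H2O), groups are
compared by the difference of means (up minus down), a two-sided Wilcoxon
rank-sum p-value, and the common language effect size (CLES): the percentage
of up/down pairings in which the up-expressed protein has the larger value,
ties counted half.

Cleaning rules on load: IDs are passed through an updates mapping (obsolete or
secondary accessions to current primary ones), IDs listed with opposite
expression directions are excluded from both groups, and duplicates within a
group are collapsed; all removals are counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .composition import ProteinRecord

__all__ = [
    "ExpressionDataset", "ComparisonResult", "ClassificationThresholds",
    "load_dataset", "wilcoxon_p", "cles", "compare_groups", "classify_dataset",
    "diagram_group_predicate", "summarize_datasets", "resolve_ids",
]

METRICS = ("Zc", "nH2O")


@dataclass(frozen=True)
class ExpressionDataset:
    """Up- and down-expressed protein ID lists for one study comparison."""

    name: str
    up_ids: tuple[str, ...]
    down_ids: tuple[str, ...]
    description: str = ""
    labels: tuple[str, str] = ("down", "up")
    cleaning: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.up_ids or not self.down_ids:
            raise ValueError(f"dataset {self.name!r}: empty group after cleaning")
        overlap = set(self.up_ids) & set(self.down_ids)
        if overlap:
            raise ValueError(f"dataset {self.name!r}: IDs in both groups: {sorted(overlap)[:5]}")

    @property
    def n1(self) -> int:
        """Number of down-expressed proteins."""
        return len(self.down_ids)

    @property
    def n2(self) -> int:
        """Number of up-expressed proteins."""
        return len(self.up_ids)


def _direction_from_row(row: pd.Series, idx: int) -> str:
    if "direction" in row.index and pd.notna(row.get("direction")):
        d = str(row["direction"]).strip().lower()
        if d not in ("up", "down"):
            raise ValueError(f"row {idx}: malformed direction {row['direction']!r}")
        return d
    if "log2_ratio" in row.index and pd.notna(row.get("log2_ratio")):
        ratio = float(row["log2_ratio"])
        if ratio == 0:
            raise ValueError(f"row {idx}: zero log2_ratio has no direction")
        return "up" if ratio > 0 else "down"
    raise ValueError(f"row {idx}: no direction or log2_ratio value")


def load_dataset(
    source: pd.DataFrame | str | Path,
    id_updates: Mapping[str, str] | pd.DataFrame | str | Path | None = None,
    name: str = "dataset",
    description: str = "",
) -> ExpressionDataset:
    """Load and clean one dataset table.

    ``source`` needs an ``id`` column and either a ``direction`` (up|down)
    or a ``log2_ratio`` column (sign gives the direction).  ``id_updates``
    maps old accessions to current primary ones (mapping, two-column table
    ``old,new``, or a path to one).
    """
    if not isinstance(source, pd.DataFrame):
        source = pd.read_csv(source, comment="#")
    if "id" not in source.columns:
        raise ValueError("dataset table needs an 'id' column")

    if id_updates is None:
        updates: Mapping[str, str] = {}
    elif isinstance(id_updates, Mapping):
        updates = id_updates
    else:
        if not isinstance(id_updates, pd.DataFrame):
            id_updates = pd.read_csv(id_updates, comment="#")
        updates = dict(zip(id_updates.iloc[:, 0].astype(str), id_updates.iloc[:, 1].astype(str)))

    by_dir: dict[str, list[str]] = {"up": [], "down": []}
    n_updated = 0
    for idx, row in source.iterrows():
        pid = str(row["id"]).strip()
        if pid in updates:
            pid = updates[pid]
            n_updated += 1
        by_dir[_direction_from_row(row, int(idx))].append(pid)

    up, down = set(by_dir["up"]), set(by_dir["down"])
    opposite = up & down
    n_dups = (len(by_dir["up"]) - len(up)) + (len(by_dir["down"]) - len(down))
    cleaning = {
        "ids_updated": n_updated,
        "duplicates_collapsed": n_dups,
        "opposite_direction_excluded": len(opposite),
    }
    return ExpressionDataset(
        name=name,
        description=description,
        up_ids=tuple(pid for pid in dict.fromkeys(by_dir["up"]) if pid not in opposite),
        down_ids=tuple(pid for pid in dict.fromkeys(by_dir["down"]) if pid not in opposite),
        cleaning=cleaning,
    )


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

_EXACT_MAX_N = 25


def wilcoxon_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when both groups have at most 25 members and there are
    no ties; otherwise the midrank normal approximation with continuity
    correction.  Identical constant samples give p = 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups need at least one value")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return 1.0
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (tie_free and x.size <= _EXACT_MAX_N and y.size <= _EXACT_MAX_N) \
        else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(min(res.pvalue, 1.0))


def cles(x: Sequence[float], y: Sequence[float]) -> float:
    """Common language effect size, percent of (x_i, y_j) pairs with
    x_i > y_j, counting ties half: 100 * (#{x>y} + 0.5 #{x=y}) / (|x||y|)."""
    x = np.asarray(x, float)[:, np.newaxis]
    y = np.asarray(y, float)[np.newaxis, :]
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups need at least one value")
    wins = np.count_nonzero(x > y) + 0.5 * np.count_nonzero(x == y)
    return 100.0 * wins / (x.size * y.size)


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

def resolve_ids(
    ids: Iterable[str], metrics: pd.DataFrame
) -> tuple[list[str], list[str]]:
    """Match IDs against a metrics table index.

    Isoform-suffixed accessions (``P12345-2``) are looked up as given first,
    then fall back to the parent accession.  Returns (resolved, missing);
    resolved entries are metrics-table index labels.
    """
    resolved, missing = [], []
    index = metrics.index
    for pid in ids:
        if pid in index:
            resolved.append(pid)
        elif "-" in pid and pid.rsplit("-", 1)[0] in index:
            resolved.append(pid.rsplit("-", 1)[0])
        else:
            missing.append(pid)
    return resolved, missing


@dataclass(frozen=True)
class ComparisonResult:
    """Group means, mean differences, Wilcoxon p and CLES for both metrics."""

    name: str
    n1: int
    n2: int
    mean_down: Mapping[str, float]
    mean_up: Mapping[str, float]
    delta: Mapping[str, float]
    p_value: Mapping[str, float]
    cles_pct: Mapping[str, float]
    dropped_up: int = 0
    dropped_down: int = 0

    def __post_init__(self) -> None:
        for m in METRICS:
            if not (0.0 <= self.cles_pct[m] <= 100.0):
                raise ValueError("CLES out of [0, 100]")
            if abs(self.delta[m] - (self.mean_up[m] - self.mean_down[m])) > 1e-12:
                raise ValueError("delta inconsistent with group means")


def compare_groups(
    dataset: ExpressionDataset, metrics: pd.DataFrame
) -> ComparisonResult:
    """Compare up- vs down-expressed groups on Z_C and n̄_H2O.

    ``metrics`` is a per-protein table indexed by ID with columns ``Zc`` and
    ``nH2O`` (as produced by :func:`protpot.composition.compute_metrics`).
    Unresolvable IDs are dropped and counted; a fully unresolvable group is
    an error listing the missing IDs.
    """
    up, up_missing = resolve_ids(dataset.up_ids, metrics)
    down, down_missing = resolve_ids(dataset.down_ids, metrics)
    for label, resolved, missing_ids in (("up", up, up_missing), ("down", down, down_missing)):
        if not resolved:
            raise ValueError(
                f"dataset {dataset.name!r}: no {label}-expressed ID matched the "
                f"composition data; missing: {missing_ids[:10]}"
            )
    mean_down, mean_up, delta, pvals, effect = {}, {}, {}, {}, {}
    for m in METRICS:
        xu = metrics.loc[up, m].to_numpy(float)
        xd = metrics.loc[down, m].to_numpy(float)
        mean_up[m] = float(xu.mean())
        mean_down[m] = float(xd.mean())
        delta[m] = mean_up[m] - mean_down[m]
        pvals[m] = wilcoxon_p(xu, xd)
        effect[m] = cles(xu, xd)
    return ComparisonResult(
        name=dataset.name, n1=len(down), n2=len(up),
        mean_down=mean_down, mean_up=mean_up, delta=delta,
        p_value=pvals, cles_pct=effect,
        dropped_up=len(up_missing), dropped_down=len(down_missing),
    )


@dataclass(frozen=True)
class ClassificationThresholds:
    """Cutoffs for "large" and "significant" mean differences."""

    delta: float = 0.01
    p: float = 0.05
    cles_low: float = 40.0
    cles_high: float = 60.0

    def __post_init__(self) -> None:
        if self.delta <= 0 or self.p <= 0:
            raise ValueError("thresholds must be positive")
        if abs((self.cles_high - 50.0) - (50.0 - self.cles_low)) > 1e-9:
            raise ValueError("CLES bounds must be symmetric about 50")


DEFAULT_THRESHOLDS = ClassificationThresholds()


def classify_dataset(
    result: ComparisonResult,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
) -> dict[str, dict[str, object]]:
    """Per-metric flags: |Δ| above threshold, p below 0.05, CLES outside
    [40, 60], and the sign of the mean difference."""
    out: dict[str, dict[str, object]] = {}
    for m in METRICS:
        out[m] = {
            "large": abs(result.delta[m]) > thresholds.delta,
            "significant": result.p_value[m] < thresholds.p,
            "strong_effect": not (thresholds.cles_low <= result.cles_pct[m] <= thresholds.cles_high),
            "direction": int(np.sign(result.delta[m])),
        }
    return out


def diagram_group_predicate(
    metric: str,
    sign: int,
    exclude_other: bool = True,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
):
    """Membership predicate for a merged-diagram group.

    Selects datasets whose mean difference on ``metric`` has the given sign
    and exceeds the Δ threshold; with ``exclude_other`` the other metric must
    be neither significant (low p) nor large in effect (CLES outside bounds).
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    other = METRICS[1] if metric == METRICS[0] else METRICS[0]

    def predicate(result: ComparisonResult) -> bool:
        primary = sign * result.delta[metric] > thresholds.delta
        if not primary:
            return False
        if not exclude_other:
            return True
        flags = classify_dataset(result, thresholds)[other]
        return not flags["significant"] and not flags["strong_effect"]

    return predicate


def summarize_datasets(
    datasets: Sequence[ExpressionDataset],
    metrics: pd.DataFrame | Mapping[str, pd.DataFrame],
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Long-form summary: one row per dataset per metric.

    ``metrics`` may be a single table or a per-dataset-name mapping (for
    multi-organism suites).  Per-dataset failures are reported in the second
    return value and do not abort the rest.
    """
    rows, errors = [], {}
    for ds in datasets:
        tab = metrics[ds.name] if isinstance(metrics, Mapping) else metrics
        try:
            res = compare_groups(ds, tab)
        except (ValueError, KeyError) as exc:
            errors[ds.name] = str(exc)
            continue
        flags = classify_dataset(res, thresholds)
        for m in METRICS:
            rows.append({
                "dataset": ds.name, "metric": m, "n1": res.n1, "n2": res.n2,
                "mean_down": res.mean_down[m], "mean_up": res.mean_up[m],
                "delta": res.delta[m], "p_value": res.p_value[m],
                "cles": res.cles_pct[m],
                "large": flags[m]["large"], "significant": flags[m]["significant"],
            })
    return pd.DataFrame(rows), errors
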