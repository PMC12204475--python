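"""Clone-level quantification.

All operations work on a clone count table: a clones-by-groups matrix of
non-negative integer cell counts (a plain :class:`pandas.DataFrame`, clone
labels as index, group labels as columns).  Groups may be samples, tissues,
transcriptomic clusters, or any per-cell metadata category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import DEFAULT_HOMEOSTASIS_BREAKS, DEFAULT_HOMEOSTASIS_LABELS
from .errors import CloneNotFound, DegenerateGroup, EmptyRepertoire


@dataclass(frozen=True)
class HomeostasisBins:
    """Right-closed clone-proportion bins on (0, 1].

    ``breaks`` are the strictly increasing upper bounds, ending at 1; a clone
    with per-group proportion p falls in the unique bin with
    ``lower < p <= upper``.
    """

    breaks: tuple[float, ...] = DEFAULT_HOMEOSTASIS_BREAKS
    labels: tuple[str, ...] = DEFAULT_HOMEOSTASIS_LABELS

    def __post_init__(self):
        if len(self.breaks) != len(self.labels):
            raise ValueError("breaks and labels must align")
        if list(self.breaks) != sorted(set(self.breaks)):
            raise ValueError("breaks must be strictly increasing")
        if self.breaks[-1] != 1.0:
            raise ValueError("last breakpoint must be 1")

    def assign(self, proportion: float) -> str:
        """Bin label for one clone proportion in (0, 1]."""
        for b, lab in zip(self.breaks, self.labels):
            if proportion <= b:
                return lab
        return self.labels[-1]


def count_clones(
    cells: pd.DataFrame,
    clone_labels: pd.Series,
    group_by: str | pd.Series = "sample_id",
) -> pd.DataFrame:
    """Exact clone-by-group contingency table of cell counts.

    Cells with a missing clone label are excluded.  Rows that are zero in
    every group are dropped; column sums equal each group's labelled cell
    count.
    """
    if isinstance(group_by, str):
        groups = cells[group_by]
    else:
        groups = group_by
    mask = clone_labels.notna()
    if not mask.any():
        raise EmptyRepertoire("no cells with clone labels")
    table = (
        pd.crosstab(clone_labels[mask], groups[mask])
        .sort_index()
        .sort_index(axis=1)
    )
    table = table.loc[table.sum(axis=1) > 0]
    table.index.name = "clone"
    table.columns.name = "group"
    return table.astype(int)


def clonal_homeostasis(
    counts: pd.DataFrame, bins: HomeostasisBins | None = None
) -> pd.DataFrame:
    """Per group, the fraction of the repertoire occupied by each size bin.

    Each clone's proportion of its group is assigned to a right-closed bin;
    the matrix entry is the summed proportion of clones in that bin, so rows
    sum to 1 for non-empty groups.
    """
    bins = bins or HomeostasisBins()
    out = pd.DataFrame(0.0, index=counts.columns, columns=list(bins.labels))
    for g in counts.columns:
        total = counts[g].sum()
        if total == 0:
            continue
        props = counts[g][counts[g] > 0] / total
        for p in props:
            out.loc[g, bins.assign(p)] += p
    out.index.name = "group"
    return out


def clonal_proportion(
    counts: pd.DataFrame,
    rank_splits: tuple[int, ...] = (10, 100, 1000, 10000, 30000, 100000),
) -> pd.DataFrame:
    """Occupied clonal space by clone-size rank.

    Per group, clones are ranked by count (descending, ties broken by clone
    label); rank bin b collects the total cell count of clones whose rank
    falls in ``(split_{b-1}, split_b]``.  Row sums equal group cell totals.
    """
    splits = list(rank_splits)
    if splits != sorted(set(splits)):
        raise ValueError("rank_splits must be strictly increasing")
    labels = []
    prev = 0
    for s in splits:
        labels.append(f"[{prev + 1}:{s}]")
        prev = s
    out = pd.DataFrame(0, index=counts.columns, columns=labels, dtype=int)
    for g in counts.columns:
        col = counts[g][counts[g] > 0]
        ordered = col.sort_index().sort_values(ascending=False, kind="mergesort")
        prev = 0
        for s, lab in zip(splits, labels):
            out.loc[g, lab] = int(ordered.iloc[prev:s].sum())
            prev = s
    out.index.name = "group"
    return out


def clonal_compare(
    counts: pd.DataFrame,
    top_n: int | None = 10,
    clones: list[str] | None = None,
    proportion: bool = True,
) -> pd.DataFrame:
    """Long-format table tracking selected clones across groups.

    Selection is either an explicit clone list or the union over groups of
    each group's ``top_n`` clones by proportion (ties broken by label).  The
    output contains every selected clone in every group, zeros included, so
    it can feed alluvial-style plots directly.
    """
    if clones is not None:
        missing = [c for c in clones if c not in counts.index]
        if len(missing) == len(clones):
            raise CloneNotFound(f"none of the requested clones found: {missing}")
        selected = [c for c in clones if c in counts.index]
    else:
        if top_n is None or top_n < 1:
            raise ValueError("top_n must be >= 1 or clones given")
        chosen: set[str] = set()
        for g in sorted(counts.columns):
            col = counts[g][counts[g] > 0]
            ordered = col.sort_index().sort_values(
                ascending=False, kind="mergesort"
            )
            chosen.update(ordered.index[:top_n])
        selected = sorted(chosen)
    rows = []
    totals = counts.sum(axis=0)
    for clone in selected:
        for g in counts.columns:
            value = counts.loc[clone, g]
            if proportion:
                value = value / totals[g] if totals[g] > 0 else 0.0
            rows.append({"clone": clone, "group": g, "value": value})
    return pd.DataFrame(rows, columns=["clone", "group", "value"])


def _morisita_horn(x: np.ndarray, y: np.ndarray) -> float:
    X, Y = x.sum(), y.sum()
    denom = (np.sum(x**2) / X**2 + np.sum(y**2) / Y**2) * X * Y
    return float(2.0 * np.sum(x * y) / denom)


def clonal_overlap(counts: pd.DataFrame, method: str = "morisita") -> pd.DataFrame:
    """Pairwise repertoire overlap between groups.

    ``raw`` counts shared clones; ``jaccard`` and ``overlap`` are set-based
    (intersection over union / over the smaller set); ``cosine`` operates on
    count vectors; ``morisita`` is the Morisita-Horn index, bounded [0, 1]
    and invariant to proportional rescaling of either repertoire.
    """
    if counts.shape[1] < 2:
        raise DegenerateGroup("overlap needs at least two groups")
    groups = list(counts.columns)
    for g in groups:
        if counts[g].sum() == 0:
            raise DegenerateGroup(f"group {g!r} has zero cells")
    out = pd.DataFrame(np.nan, index=groups, columns=groups)
    mat = counts.to_numpy(dtype=float)
    for i, gi in enumerate(groups):
        for j, gj in enumerate(groups):
            if j < i:
                continue
            x, y = mat[:, i], mat[:, j]
            sx, sy = x > 0, y > 0
            if method == "raw":
                val = float(np.sum(sx & sy))
            elif method == "jaccard":
                val = float(np.sum(sx & sy) / np.sum(sx | sy))
            elif method == "overlap":
                val = float(np.sum(sx & sy) / min(sx.sum(), sy.sum()))
            elif method == "cosine":
                val = float(
                    np.dot(x, y)
                    / (np.linalg.norm(x) * np.linalg.norm(y))
                )
            elif method == "morisita":
                val = _morisita_horn(x, y)
            else:
                raise ValueError(f"unknown overlap method {method!r}")
            out.loc[gi, gj] = val
            out.loc[gj, gi] = val
    return out
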