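"""Attach clone-level annotations to per-cell metadata.

The single-cell side of the toolkit is a plain barcode-indexed table: a list
of cell barcodes (e.g. the columns of an expression matrix) is left-joined
against the assembled clonotype table, yielding per-cell clone labels, clone
sizes and proportions, an expansion category, and a doublet flag — a table
that merges directly into any single-cell framework's cell metadata.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .clonal_metrics import HomeostasisBins
from .errors import DuplicateBarcode

logger = logging.getLogger(__name__)


def attach_clones(
    cell_barcodes,
    cells: pd.DataFrame,
    clone_labels: pd.Series,
    scope: str = "per-sample",
    breakpoints: HomeostasisBins | None = None,
    doublet_barcodes=None,
) -> pd.DataFrame:
    """Left-join clonotype annotations onto a barcode list.

    Parameters
    ----------
    cell_barcodes
        Unique barcodes of the cell-level assay (sample-prefixed, matching
        the clonotype table's ``barcode`` column).
    cells
        Assembled clonotype table (one row per receptor-bearing cell).
    clone_labels
        Per-cell clone labels aligned with ``cells`` (see
        :func:`airrtoolkit.repertoire_assembly.resolve_clone_ids`).
    scope
        ``"per-sample"`` computes each clone's frequency within its sample;
        ``"global"`` across all samples.
    breakpoints
        Clone-proportion bins for the size category; the same right-closed
        bins as clonal homeostasis.
    doublet_barcodes
        Optional iterable of barcodes flagged as TCR/BCR doublets.

    Returns
    -------
    pandas.DataFrame
        One row per input barcode — never more, never fewer — with columns
        ``barcode, sample_id, clone, clonal_frequency, clonal_proportion,
        clone_size_category, doublet_flag``.
    """
    barcodes = list(cell_barcodes)
    if len(set(barcodes)) != len(barcodes):
        raise DuplicateBarcode("cell barcode list contains duplicates")
    bins = breakpoints or HomeostasisBins()
    ann = cells[["barcode", "sample_id"]].copy()
    ann["clone"] = clone_labels.to_numpy()
    ann = ann[ann["clone"].notna()]

    if scope == "global":
        sizes = ann.groupby("clone")["barcode"].count()
        totals = pd.Series(len(ann), index=ann["sample_id"].unique())
        ann["clonal_frequency"] = ann["clone"].map(sizes)
        ann["clonal_proportion"] = ann["clonal_frequency"] / len(ann)
    elif scope == "per-sample":
        sizes = ann.groupby(["sample_id", "clone"])["barcode"].count()
        totals = ann.groupby("sample_id")["barcode"].count()
        key = list(zip(ann["sample_id"], ann["clone"]))
        ann["clonal_frequency"] = [sizes[k] for k in key]
        ann["clonal_proportion"] = ann["clonal_frequency"] / ann["sample_id"].map(
            totals
        )
    else:
        raise ValueError(f"unknown scope {scope!r}")
    ann["clone_size_category"] = ann["clonal_proportion"].map(bins.assign)

    out = pd.DataFrame({"barcode": barcodes})
    out = out.merge(ann, on="barcode", how="left")
    doublets = set(doublet_barcodes or ())
    out["doublet_flag"] = out["barcode"].isin(doublets)
    annotated = out["clone"].notna().mean()
    logger.info("attach_clones: %.1f%% of %d barcodes annotated",
                100 * annotated, len(out))
    return out


def occupancy_by_cluster(
    annotations: pd.DataFrame,
    cluster_labels: pd.Series,
    normalize: bool = False,
    bins: HomeostasisBins | None = None,
) -> pd.DataFrame:
    """Cluster-by-expansion-category contingency of cells.

    Cells without receptor data fall in an explicit ``"None"`` category.
    With ``normalize=True`` rows sum to 1.
    """
    labels = bins.labels if bins else HomeostasisBins().labels
    cat = annotations["clone_size_category"].fillna("None")
    tab = pd.crosstab(cluster_labels, cat)
    cols = [l for l in list(labels) + ["None"] if l in tab.columns]
    tab = tab[cols]
    if normalize:
        tab = tab.div(tab.sum(axis=1).replace(0, np.nan), axis=0).fillna(0.0)
    tab.index.name = "cluster"
    tab.columns.name = "clone_size_category"
    return tab
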