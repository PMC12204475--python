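"""Paired-chain clonotype assembly.

Consolidates per-cell contigs into two chain slots (chain 1: TRA/TRG and the
light chains IGK/IGL; chain 2: TRB/TRD/IGH), builds the four clone identity
strings per cell, infers B-cell clonotypes by heavy-chain edit distance,
flags TCR/BCR doublets, and resolves clone labels for downstream analyses.

Clone identity strings follow the ``<chain1 part>_<chain2 part>`` convention
with missing parts rendered ``NA``:

* ``CTgene`` — gene segments, chain 1 as ``V.J.C``, chain 2 as ``V.D.J.C``;
* ``CTnt`` / ``CTaa`` — the CDR3 junction nucleotide / amino-acid strings;
* ``CTstrict`` — ``CTgene`` and ``CTnt`` joined (for BCR, the inferred
  heavy-clone cluster plus the light-chain V.J).
"""

from __future__ import annotations

import pandas as pd

from .clonal_clustering import cluster_sequences
from .constants import (
    ALL_LOCI,
    BCR_LOCI,
    CHAIN1_LOCI,
    DEFAULT_SIMILARITY_THRESHOLD,
    NA,
    TCR_LOCI,
    normalize_na,
)
from .errors import EmptyRepertoire, MixedReceptorError, UnknownColumn

SLOT_FIELDS = ["locus", "v_gene", "d_gene", "j_gene", "c_gene", "cdr3_aa",
               "cdr3_nt", "umis", "reads"]


def filter_receptor(contigs: pd.DataFrame, receptor: str) -> pd.DataFrame:
    """Keep only TCR (``"tcr"``) or BCR (``"bcr"``) loci of a contig table.

    Run this before assembly when a sample carries both receptor types
    (e.g. after doublet flagging), since each assembly path accepts a single
    receptor class.
    """
    loci = TCR_LOCI if receptor == "tcr" else BCR_LOCI
    out = contigs[contigs["locus"].isin(loci)].reset_index(drop=True)
    out.attrs = dict(contigs.attrs)
    return out


def strip_allele(gene: str) -> str:
    """Drop the allele suffix (text after '*') from a gene call."""
    g = normalize_na(gene)
    return g.split("*")[0] if g != NA else NA


def consolidate_chains(
    contigs: pd.DataFrame,
    productive_only: bool = True,
    filter_multi: bool = False,
    max_chains_per_slot: int = 2,
) -> pd.DataFrame:
    """Collapse contigs into at most one row per (barcode, chain slot).

    Within a slot, chains are ordered by UMIs (descending), then reads
    (descending), then junction nucleotide sequence (lexicographic); the top
    ``max_chains_per_slot`` are kept and their fields joined with ``";"`` in
    that order (``filter_multi=True`` keeps only the top chain).  Barcodes
    carrying both alpha-beta and gamma-delta TCR chains keep the locus pair
    with more total UMIs (ties favour alpha-beta).  Gene calls lose their
    allele suffix here so that clone identities are stable across pipelines.
    """
    df = contigs.copy()
    if productive_only:
        df = df[df["productive"] == True]  # noqa: E712 — NA must not pass
    df = df[df["locus"].isin(ALL_LOCI)]
    if df.empty:
        return pd.DataFrame(
            columns=["barcode", "sample_id", "slot", "n_collapsed"] + SLOT_FIELDS
        )
    for col in ("v_gene", "d_gene", "j_gene", "c_gene"):
        df[col] = df[col].map(strip_allele)
    df["cdr3_aa"] = df["cdr3_aa"].map(normalize_na)
    df["cdr3_nt"] = df["cdr3_nt"].map(normalize_na)

    # alpha-beta vs gamma-delta arbitration per barcode
    is_ab = df["locus"].isin({"TRA", "TRB"})
    is_gd = df["locus"].isin({"TRG", "TRD"})
    umis_ab = df.loc[is_ab].groupby("barcode")["umis"].sum()
    umis_gd = df.loc[is_gd].groupby("barcode")["umis"].sum()
    both = umis_ab.index.intersection(umis_gd.index)
    drop_idx = []
    for bc in both:
        if umis_gd[bc] > umis_ab[bc]:
            drop_idx.extend(df.index[(df["barcode"] == bc) & is_ab])
        else:
            drop_idx.extend(df.index[(df["barcode"] == bc) & is_gd])
    if drop_idx:
        df = df.drop(index=drop_idx)

    df["slot"] = df["locus"].map(
        lambda l: "chain1" if l in CHAIN1_LOCI else "chain2"
    )
    keep = 1 if filter_multi else max_chains_per_slot
    df = df.sort_values(
        ["barcode", "slot", "umis", "reads", "cdr3_nt"],
        ascending=[True, True, False, False, True],
        kind="mergesort",
    )
    rows = []
    for (bc, slot), grp in df.groupby(["barcode", "slot"], sort=True):
        top = grp.head(keep)
        row = {
            "barcode": bc,
            "sample_id": top["sample_id"].iloc[0],
            "slot": slot,
            "n_collapsed": len(top),
        }
        for f in SLOT_FIELDS:
            row[f] = ";".join(str(v) for v in top[f])
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["barcode", "sample_id", "slot", "n_collapsed"] + SLOT_FIELDS
    )


def _first(value: str) -> str:
    return str(value).split(";")[0]


def _gene_part(slot_row: pd.Series | None, chain: str) -> str:
    """Per-component dot-joined gene string for one slot."""
    if slot_row is None:
        return NA
    fields = (
        ["v_gene", "j_gene", "c_gene"]
        if chain == "chain1"
        else ["v_gene", "d_gene", "j_gene", "c_gene"]
    )
    parts = [str(slot_row[f]).split(";") for f in fields]
    n = max(len(p) for p in parts)
    comps = []
    for i in range(n):
        comps.append(".".join(p[i] if i < len(p) else NA for p in parts))
    return ";".join(comps)


def _pivot_slots(slots: pd.DataFrame) -> pd.DataFrame:
    """One row per barcode with chain1_*/chain2_* columns."""
    cells: dict[str, dict] = {}
    for _, row in slots.iterrows():
        rec = cells.setdefault(
            row["barcode"], {"barcode": row["barcode"], "sample_id": row["sample_id"]}
        )
        slot = row["slot"]
        for f in SLOT_FIELDS + ["n_collapsed"]:
            rec[f"{slot}_{f}"] = row[f]
        rec[f"_{slot}_row"] = row
    return pd.DataFrame(cells.values())


def _assemble(slots: pd.DataFrame, remove_na: bool) -> pd.DataFrame:
    if slots.empty:
        raise EmptyRepertoire("no chains to assemble")
    cells = _pivot_slots(slots)
    out_rows = []
    for _, cell in cells.iterrows():
        c1 = cell.get("_chain1_row")
        c2 = cell.get("_chain2_row")
        has1 = isinstance(c1, pd.Series)
        has2 = isinstance(c2, pd.Series)
        if remove_na and not (has1 and has2):
            continue
        g1 = _gene_part(c1 if has1 else None, "chain1")
        g2 = _gene_part(c2 if has2 else None, "chain2")
        nt1 = str(c1["cdr3_nt"]) if has1 else NA
        nt2 = str(c2["cdr3_nt"]) if has2 else NA
        aa1 = str(c1["cdr3_aa"]) if has1 else NA
        aa2 = str(c2["cdr3_aa"]) if has2 else NA
        rec = {
            "barcode": f"{cell['sample_id']}_{cell['barcode']}",
            "raw_barcode": cell["barcode"],
            "sample_id": cell["sample_id"],
        }
        for slot, present, row in (("chain1", has1, c1), ("chain2", has2, c2)):
            for f in SLOT_FIELDS:
                rec[f"{slot}_{f}"] = str(row[f]) if present else NA
            rec[f"{slot}_n_collapsed"] = int(row["n_collapsed"]) if present else 0
        rec["CTgene"] = f"{g1}_{g2}"
        rec["CTnt"] = f"{nt1}_{nt2}"
        rec["CTaa"] = f"{aa1}_{aa2}"
        rec["CTstrict"] = f"{rec['CTgene']}_{rec['CTnt']}"
        out_rows.append(rec)
    if not out_rows:
        raise EmptyRepertoire("no cells survive chain filtering")
    return pd.DataFrame(out_rows)


def build_tcr_clonotypes(slots: pd.DataFrame, remove_na: bool = False) -> pd.DataFrame:
    """One clonotype row per T cell with the four clone identity strings."""
    loci = set()
    for v in slots.get("locus", pd.Series(dtype=str)):
        loci.update(str(v).split(";"))
    if loci & BCR_LOCI:
        raise MixedReceptorError(
            f"TCR assembly received B-cell loci: {sorted(loci & BCR_LOCI)}"
        )
    return _assemble(slots, remove_na)


def infer_bcr_clonotypes(
    slots: pd.DataFrame,
    similarity_threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
    remove_na: bool = False,
) -> pd.DataFrame:
    """Assemble B cells and infer clonotypes by heavy-chain edit distance.

    Heavy-chain (IGH) junction nucleotide sequences are linked when they share
    both V and J gene and reach the normalized Levenshtein similarity
    threshold; connected components define the inferred heavy clones.
    ``CTstrict`` becomes ``<heavy clone label>_<light V.J>``; cells without a
    heavy chain fall back to a light-chain-only identity.
    """
    loci = set()
    for v in slots.get("locus", pd.Series(dtype=str)):
        loci.update(str(v).split(";"))
    if loci & TCR_LOCI:
        raise MixedReceptorError(
            f"BCR assembly received T-cell loci: {sorted(loci & TCR_LOCI)}"
        )
    cells = _assemble(slots, remove_na)
    heavy = cells[
        (cells["chain2_cdr3_nt"] != NA) & (cells["chain2_locus"] != NA)
    ].copy()
    if not heavy.empty:
        heavy["_seq"] = heavy["chain2_cdr3_nt"].map(_first)
        heavy["_vj"] = (
            heavy["chain2_v_gene"].map(_first) + "|" + heavy["chain2_j_gene"].map(_first)
        )
        graph = cluster_sequences(
            heavy[["_seq", "_vj"]].rename(columns={"_seq": "sequence", "_vj": "v_gene"}),
            threshold=similarity_threshold,
            same_v=True,
            chain_label="IGH",
        )
        # sequence alone is not unique across V|J scopes; key on both
        label_of = {
            (row["v_gene"], row["sequence"]): row["cluster"]
            for _, row in graph.nodes.iterrows()
        }
        heavy_label = heavy.apply(
            lambda r: label_of[(r["_vj"], r["_seq"])], axis=1
        )
    else:
        heavy_label = pd.Series(dtype=str)

    def light_vj(row):
        if row["chain1_v_gene"] == NA and row["chain1_j_gene"] == NA:
            return NA
        return f"{_first(row['chain1_v_gene'])}.{_first(row['chain1_j_gene'])}"

    strict = []
    for idx, row in cells.iterrows():
        if idx in heavy_label.index:
            strict.append(f"{heavy_label[idx]}_{light_vj(row)}")
        else:
            lv = light_vj(row)
            lnt = _first(row["chain1_cdr3_nt"])
            strict.append(f"NA_{lv}.{lnt}")
    cells["CTstrict"] = strict
    return cells


def detect_doublets(
    contigs: pd.DataFrame, productive_only: bool = True
) -> pd.DataFrame:
    """Flag barcodes carrying both productive T- and B-receptor chains.

    Returns one row per flagged barcode with per-receptor chain counts
    (``n_tcr``, ``n_bcr``); clean data yields an empty table.
    """
    df = contigs
    if productive_only:
        df = df[df["productive"] == True]  # noqa: E712
    df = df[df["locus"].isin(ALL_LOCI)]
    if df.empty:
        return pd.DataFrame(columns=["barcode", "n_tcr", "n_bcr"])
    counts = (
        df.assign(
            receptor=df["locus"].map(lambda l: "tcr" if l in TCR_LOCI else "bcr")
        )
        .groupby(["barcode", "receptor"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=["tcr", "bcr"], fill_value=0)
    )
    flagged = counts[(counts["tcr"] >= 1) & (counts["bcr"] >= 1)]
    return (
        flagged.rename(columns={"tcr": "n_tcr", "bcr": "n_bcr"})
        .reset_index()
        .sort_values("barcode")
        .reset_index(drop=True)
    )


def resolve_clone_ids(
    cells: pd.DataFrame,
    clone_call: str,
    cell_metadata: pd.DataFrame | None = None,
) -> pd.Series:
    """Per-cell clone labels under a clone definition.

    ``clone_call`` may be one of the built-in modes (``gene``, ``nt``, ``aa``,
    ``strict`` — mapping to the CT columns) or the name of a custom metadata
    column carrying clone labels from an external pipeline; missing custom
    values propagate as missing.
    """
    builtin = {"gene": "CTgene", "nt": "CTnt", "aa": "CTaa", "strict": "CTstrict"}
    if clone_call in builtin:
        return cells[builtin[clone_call]].copy()
    if clone_call in cells.columns:
        return cells[clone_call].copy()
    if cell_metadata is not None and clone_call in cell_metadata.columns:
        meta = cell_metadata.set_index("barcode") if "barcode" in cell_metadata.columns else cell_metadata
        return cells["barcode"].map(meta[clone_call])
    raise UnknownColumn(
        f"clone_call {clone_call!r} is neither a built-in mode nor a known column"
    )
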