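"""CDR3-level sequence summarisation.

Positions are left-aligned: position 1 is the first junction residue and a
sequence of length L contributes to positions 1..L, so per-position support
shrinks with length.  Multi-chain cells (";"-joined slots) contribute their
first — highest-UMI — chain unless the caller splits them beforehand.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .constants import (
    AA_ALPHABET,
    ATCHLEY_FACTORS,
    ATCHLEY_NAMES,
    NA,
    NT_ALPHABET,
)
from .errors import EmptyInput, KTooLarge, UnknownResidue

logger = logging.getLogger(__name__)


def _clean(sequences, split_multi: bool = False) -> list[str]:
    out = []
    for s in sequences:
        if s is None or (isinstance(s, float) and np.isnan(s)):
            continue
        s = str(s)
        if s == NA or not s:
            continue
        parts = s.split(";") if split_multi else [s.split(";")[0]]
        out.extend(p for p in parts if p and p != NA)
    return out


def percent_aa(sequences, split_multi: bool = False) -> pd.DataFrame:
    """Per-position residue frequencies (positions x residues).

    Position p counts the residues of every sequence with length >= p;
    frequencies are normalised by that per-position support, which is
    reported in the ``n`` column.
    """
    seqs = _clean(sequences, split_multi)
    if not seqs:
        raise EmptyInput("no usable sequences")
    lmax = max(len(s) for s in seqs)
    residues = sorted({ch for s in seqs for ch in s})
    counts = pd.DataFrame(
        0, index=pd.RangeIndex(1, lmax + 1, name="position"), columns=residues
    )
    for s in seqs:
        for p, ch in enumerate(s, start=1):
            counts.loc[p, ch] += 1
    support = counts.sum(axis=1)
    freq = counts.div(support.replace(0, np.nan), axis=0)
    freq["n"] = support
    return freq


def positional_entropy(sequences, method: str = "shannon",
                       split_multi: bool = False) -> pd.Series:
    """Residue variability along the junction.

    Per position, the chosen index of the residue frequency vector:
    ``shannon`` (nats), ``norm_entropy`` (Shannon / ln 20, in [0, 1]), or
    ``inv_simpson``.  Positions with zero support are missing.
    """
    freq = percent_aa(sequences, split_multi)
    support = freq.pop("n")
    out = {}
    for p in freq.index:
        if support[p] == 0:
            out[p] = np.nan
            continue
        probs = freq.loc[p].dropna()
        probs = probs[probs > 0].to_numpy()
        H = float(-np.sum(probs * np.log(probs)))
        if method == "shannon":
            out[p] = H
        elif method == "norm_entropy":
            out[p] = H / np.log(20.0)
        elif method == "inv_simpson":
            out[p] = float(1.0 / np.sum(probs**2))
        else:
            raise ValueError(f"unknown entropy method {method!r}")
    return pd.Series(out, name=method).rename_axis("position")


def positional_property(
    sequences,
    property_set: str = "atchley",
    strict: bool = False,
    split_multi: bool = False,
) -> pd.DataFrame:
    """Per-position means of physicochemical factors with 95% CIs.

    For each position and factor, the mean over the residues of covering
    sequences; the CI is the normal approximation mean +/- 1.96 sd/sqrt(n),
    reported missing where fewer than two sequences cover the position.
    Sequences containing residues absent from the factor table are skipped
    (counted in the log), or rejected outright in strict mode.
    """
    if property_set != "atchley":
        raise ValueError(f"unknown property set {property_set!r}")
    seqs = _clean(sequences, split_multi)
    if not seqs:
        raise EmptyInput("no usable sequences")
    known = set(ATCHLEY_FACTORS)
    usable, skipped = [], 0
    for s in seqs:
        if set(s) <= known:
            usable.append(s)
        elif strict:
            bad = sorted(set(s) - known)
            raise UnknownResidue(f"residues without factors: {bad} in {s!r}")
        else:
            skipped += 1
    if skipped:
        logger.info("positional_property: skipped %d sequences with "
                    "non-standard residues", skipped)
    if not usable:
        raise EmptyInput("no sequences with standard residues")
    lmax = max(len(s) for s in usable)
    rows = []
    for p in range(1, lmax + 1):
        vals = np.array(
            [ATCHLEY_FACTORS[s[p - 1]] for s in usable if len(s) >= p]
        )
        n = vals.shape[0]
        mean = vals.mean(axis=0)
        sd = vals.std(axis=0, ddof=1) if n > 1 else np.full(5, np.nan)
        for f, name in enumerate(ATCHLEY_NAMES):
            ci = 1.96 * sd[f] / np.sqrt(n) if n > 1 else np.nan
            rows.append(
                {"position": p, "factor": name, "mean": mean[f],
                 "ci_lower": mean[f] - ci, "ci_upper": mean[f] + ci, "n": n}
            )
    return pd.DataFrame(rows)


def percent_kmer(
    sequences_by_group: dict[str, list],
    k: int = 3,
    alphabet: str = "aa",
    top_n: int | None = 25,
    split_multi: bool = True,
) -> pd.DataFrame:
    """Group-wise k-mer frequency spectrum (groups x motifs).

    Windows slide with stride 1 within each chain segment; windows touching a
    ";" separator, a missing sentinel, or a character outside the alphabet
    are skipped.  Frequencies are normalised per group over all counted
    windows.  ``top_n`` keeps the motifs with the largest total frequency
    across groups (ties broken lexicographically); ``None`` keeps all.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    allowed = set(AA_ALPHABET if alphabet == "aa" else NT_ALPHABET)
    table: dict[str, dict[str, int]] = {}
    any_long_enough = False
    for group, seqs in sequences_by_group.items():
        counts: dict[str, int] = {}
        for seq in _clean(seqs, split_multi=split_multi):
            if len(seq) >= k:
                any_long_enough = True
            for i in range(len(seq) - k + 1):
                w = seq[i : i + k]
                if set(w) <= allowed:
                    counts[w] = counts.get(w, 0) + 1
        table[group] = counts
    if not any_long_enough:
        raise KTooLarge(f"no sequence reaches length k={k}")
    df = pd.DataFrame(table).T.fillna(0.0)
    df = df.div(df.sum(axis=1), axis=0)
    df = df[sorted(df.columns)]
    if top_n is not None and df.shape[1] > top_n:
        order = sorted(df.columns, key=lambda m: (-df[m].sum(), m))
        df = df[sorted(order[:top_n])]
    df.index.name = "group"
    return df


def percent_vj(
    cells: pd.DataFrame,
    locus: str,
    group_by: str = "sample_id",
) -> pd.DataFrame:
    """Group-wise V-J pairing frequencies for one locus (rows sum to 1).

    Uses the first (highest-UMI) chain of the slot carrying ``locus``;
    chains with a missing V or J call are excluded (counted in the log).
    """
    slot = None
    for s in ("chain1", "chain2"):
        col = f"{s}_locus"
        if col in cells.columns and (
            cells[col].astype(str).str.split(";").str[0] == locus
        ).any():
            slot = s
            break
    if slot is None:
        raise EmptyInput(f"no chains with locus {locus!r}")
    sub = cells[cells[f"{slot}_locus"].astype(str).str.split(";").str[0] == locus]
    v = sub[f"{slot}_v_gene"].astype(str).str.split(";").str[0]
    j = sub[f"{slot}_j_gene"].astype(str).str.split(";").str[0]
    ok = (v != NA) & (j != NA)
    dropped = int((~ok).sum())
    if dropped:
        logger.info("percent_vj: excluded %d chains with missing V/J", dropped)
    if not ok.any():
        raise EmptyInput("all chains missing V or J calls")
    pairs = v[ok] + "_" + j[ok]
    groups = sub.loc[ok.index[ok], group_by]
    tab = pd.crosstab(groups, pairs)
    tab = tab.div(tab.sum(axis=1), axis=0)
    tab.index.name = "group"
    tab.columns.name = "vj"
    return tab


def cdr3_length_distribution(
    sequences_by_group: dict[str, list], split_multi: bool = False
) -> pd.DataFrame:
    """Exact junction-length histogram per group (groups x lengths)."""
    hists = {}
    for group, seqs in sequences_by_group.items():
        lens = [len(s) for s in _clean(seqs, split_multi)]
        hists[group] = pd.Series(lens).value_counts().sort_index()
    out = pd.DataFrame(hists).T.fillna(0).astype(int)
    out.index.name = "group"
    out.columns.name = "length"
    return out
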