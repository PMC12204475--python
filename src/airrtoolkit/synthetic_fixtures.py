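"""Synthetic repertoires with known clonal structure.

Simulates paired-chain single-cell repertoires under a chosen clone-size law
and emits them in every supported input dialect, so the whole pipeline can
be exercised end-to-end against ground truth without external data.

Each clone owns one V/J combination per chain and one CDR3 amino-acid
junction anchored ``C...F``; the nucleotide junction is a codon-faithful
back-translation (uniform over synonymous codons), so amino-acid and
nucleotide clone definitions agree by construction.  Cells of a clone share
their sequences exactly; for BCR simulations a per-cell number of point
mutations can be planted in the heavy-chain junction to sit below or above
a clustering threshold.  Doublets are planted by giving a barcode productive
chains of both receptor types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import diversity as _div
from .constants import NA
from .errors import InfeasibleSpec, UnsupportedDialect

#: Standard genetic code, amino acid -> synonymous codons.
CODONS: dict[str, tuple[str, ...]] = {
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "C": ("TGT", "TGC"),
    "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"),
    "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
    "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"),
    "K": ("AAA", "AAG"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "M": ("ATG",),
    "N": ("AAT", "AAC"),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "Q": ("CAA", "CAG"),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"),
    "V": ("GTT", "GTC", "GTA", "GTG"),
    "W": ("TGG",),
    "Y": ("TAT", "TAC"),
}

_INNER_AA = "ADEGHIKLMNPQRSTVWY"  # junction interior (anchors supplied)


@dataclass
class SimulationSpec:
    """Parameters of one simulated repertoire.

    Defaults describe a typical 10x-scale T-cell sample: a geometric
    clone-size law (success probability 0.2, mean clone size 5), ~1%
    TCR/BCR doublets, 10% of cells missing the first chain, and 5% of cells
    carrying a secondary first chain.
    """

    n_cells: int = 1000
    clone_sizes: list[int] | None = None  # explicit sizes override the law
    size_law: str = "geometric"  # geometric | powerlaw
    geometric_p: float = 0.2
    powerlaw_alpha: float = 2.5
    receptor: str = "tcr"  # tcr | bcr | mixed
    doublet_rate: float = 0.01
    missing_chain_rate: float = 0.1
    multi_chain_rate: float = 0.05
    n_v_genes: int = 30
    n_j_genes: int = 10
    cdr3_len_mean: float = 14.0
    cdr3_len_sd: float = 2.0
    cdr3_len_min: int = 8
    cdr3_len_max: int = 22
    #: point mutations planted in each non-founder B cell's heavy junction
    bcr_mutations: int = 0
    sample_id: str = "sample"
    seed: int = 0

    def validate(self) -> None:
        for name in ("doublet_rate", "missing_chain_rate", "multi_chain_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InfeasibleSpec(f"{name} must be in [0, 1], got {v}")
        if self.clone_sizes is not None:
            if any(s < 1 for s in self.clone_sizes):
                raise InfeasibleSpec("explicit clone sizes must be >= 1")
            if sum(self.clone_sizes) > self.n_cells:
                raise InfeasibleSpec("explicit clone sizes exceed n_cells")
        if self.receptor not in ("tcr", "bcr", "mixed"):
            raise InfeasibleSpec(f"unknown receptor {self.receptor!r}")
        if self.n_cells < 1:
            raise InfeasibleSpec("n_cells must be >= 1")


@dataclass
class GroundTruth:
    """What the simulator planted, for recovery checks."""

    clone_of: dict[str, str]  # barcode -> true clone id
    clone_sizes: pd.Series  # realized cells per clone
    diversity: dict[str, float]  # indices of the realized size vector
    doublet_barcodes: list[str] = field(default_factory=list)
    receptor_of: dict[str, str] = field(default_factory=dict)


def _draw_clone_sizes(spec: SimulationSpec, rng) -> list[int]:
    if spec.clone_sizes is not None:
        sizes = list(spec.clone_sizes)
        rest = spec.n_cells - sum(sizes)
        sizes.extend([1] * rest)
        return sizes
    sizes: list[int] = []
    total = 0
    while total < spec.n_cells:
        if spec.size_law == "geometric":
            s = int(rng.geometric(spec.geometric_p))
        elif spec.size_law == "powerlaw":
            s = int(min(rng.zipf(spec.powerlaw_alpha), spec.n_cells))
        else:
            raise InfeasibleSpec(f"unknown size law {spec.size_law!r}")
        s = min(s, spec.n_cells - total)
        sizes.append(s)
        total += s
    return sizes


def _random_cdr3(rng, length: int, used: set[str]) -> str:
    for _ in range(1000):
        inner = "".join(rng.choice(list(_INNER_AA), size=length - 2))
        seq = f"C{inner}F"
        if seq not in used:
            used.add(seq)
            return seq
    raise InfeasibleSpec("could not draw a fresh CDR3; length space exhausted")


def back_translate(aa: str, rng) -> str:
    """Codon-faithful nucleotide junction (uniform synonymous codons)."""
    return "".join(CODONS[ch][rng.integers(len(CODONS[ch]))] for ch in aa)


def _mutate_nt(nt: str, n_mut: int, rng) -> str:
    """Plant exactly ``n_mut`` substitutions at distinct positions."""
    if n_mut == 0:
        return nt
    pos = rng.choice(len(nt), size=min(n_mut, len(nt)), replace=False)
    s = list(nt)
    for p in pos:
        alts = [b for b in "ACGT" if b != s[p]]
        s[p] = alts[rng.integers(3)]
    return "".join(s)


def _chain_genes(rng, locus: str, n_v: int, n_j: int):
    v = f"{locus}V{rng.integers(1, n_v + 1)}"
    j = f"{locus}J{rng.integers(1, n_j + 1)}"
    d = f"{locus}D{rng.integers(1, 3)}" if locus in ("TRB", "TRD", "IGH") else NA
    c = f"{locus}C" if not locus.startswith("IG") else f"{locus}M"
    return v, d, j, c


def simulate_repertoire(spec: SimulationSpec) -> tuple[GroundTruth, pd.DataFrame]:
    """Draw a repertoire; returns ground truth and a normalised contig table.

    Identical specs (including the seed) give byte-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sizes = _draw_clone_sizes(spec, rng)
    used_cdr3: set[str] = set()

    clones = []
    for ci, size in enumerate(sizes):
        receptor = (
            spec.receptor
            if spec.receptor != "mixed"
            else ("tcr", "bcr")[rng.integers(2)]
        )
        if receptor == "tcr":
            loci = ("TRA", "TRB")
        else:
            loci = ("IGK" if rng.integers(2) == 0 else "IGL", "IGH")
        chains = []
        for locus in loci:
            length = int(
                np.clip(
                    round(rng.normal(spec.cdr3_len_mean, spec.cdr3_len_sd)),
                    spec.cdr3_len_min,
                    spec.cdr3_len_max,
                )
            )
            aa = _random_cdr3(rng, length, used_cdr3)
            nt = back_translate(aa, rng)
            v, d, j, c = _chain_genes(rng, locus, spec.n_v_genes, spec.n_j_genes)
            chains.append({"locus": locus, "v": v, "d": d, "j": j, "c": c,
                           "aa": aa, "nt": nt})
        clones.append(
            {"id": f"clone{ci + 1:05d}", "size": size, "receptor": receptor,
             "chains": chains}
        )

    records = []
    clone_of: dict[str, str] = {}
    receptor_of: dict[str, str] = {}
    doublets: list[str] = []
    cell_idx = 0
    contig_idx = 0

    def add_contig(bc, chain, umis, aa=None, nt=None):
        nonlocal contig_idx
        contig_idx += 1
        records.append(
            {
                "barcode": bc,
                "contig_id": f"{bc}_contig_{contig_idx}",
                "locus": chain["locus"],
                "v_gene": chain["v"],
                "d_gene": chain["d"],
                "j_gene": chain["j"],
                "c_gene": chain["c"],
                "cdr3_aa": aa if aa is not None else chain["aa"],
                "cdr3_nt": nt if nt is not None else chain["nt"],
                "reads": int(umis) * 10,
                "umis": int(umis),
                "productive": True,
                "sample_id": spec.sample_id,
            }
        )

    for clone in clones:
        for member in range(clone["size"]):
            cell_idx += 1
            bc = f"bc{cell_idx:06d}"
            clone_of[bc] = clone["id"]
            receptor_of[bc] = clone["receptor"]
            chain1, chain2 = clone["chains"]
            umis1 = int(rng.integers(5, 50))
            umis2 = int(rng.integers(5, 50))
            drop1 = rng.random() < spec.missing_chain_rate
            if not drop1:
                add_contig(bc, chain1, umis1)
                if rng.random() < spec.multi_chain_rate:
                    # secondary light/alpha chain with strictly fewer UMIs
                    length = int(
                        np.clip(
                            round(rng.normal(spec.cdr3_len_mean, spec.cdr3_len_sd)),
                            spec.cdr3_len_min,
                            spec.cdr3_len_max,
                        )
                    )
                    aa = _random_cdr3(rng, length, used_cdr3)
                    sec = dict(chain1)
                    sec["aa"], sec["nt"] = aa, back_translate(aa, rng)
                    add_contig(bc, sec, max(1, umis1 // 2 - 1))
            mut = (
                spec.bcr_mutations
                if clone["receptor"] == "bcr" and member > 0
                else 0
            )
            nt2 = _mutate_nt(chain2["nt"], mut, rng)
            add_contig(bc, chain2, umis2, nt=nt2)
            if rng.random() < spec.doublet_rate:
                doublets.append(bc)
                other = "bcr" if clone["receptor"] == "tcr" else "tcr"
                locus = "IGH" if other == "bcr" else "TRB"
                length = int(
                    np.clip(
                        round(rng.normal(spec.cdr3_len_mean, spec.cdr3_len_sd)),
                        spec.cdr3_len_min,
                        spec.cdr3_len_max,
                    )
                )
                aa = _random_cdr3(rng, length, used_cdr3)
                v, d, j, c = _chain_genes(rng, locus, spec.n_v_genes, spec.n_j_genes)
                add_contig(
                    bc,
                    {"locus": locus, "v": v, "d": d, "j": j, "c": c,
                     "aa": aa, "nt": back_translate(aa, rng)},
                    int(rng.integers(1, 10)),
                )

    table = pd.DataFrame(records)
    table.attrs["dialect"] = "synthetic"
    table.attrs["sample_id"] = spec.sample_id
    realized = pd.Series(clone_of).value_counts().sort_index()
    truth = GroundTruth(
        clone_of=clone_of,
        clone_sizes=realized,
        diversity=_div.diversity_indices(realized.to_numpy()),
        doublet_barcodes=doublets,
        receptor_of=receptor_of,
    )
    return truth, table


# ---------------------------------------------------------------------------
# Dialect emitters
# ---------------------------------------------------------------------------

DIALECTS = ("tenx", "airr", "bd", "mixcr", "parse", "trust4", "wat3r")


def _pack_trust4(chains: pd.DataFrame) -> str:
    parts = []
    for _, r in chains.iterrows():
        star = lambda v: "*" if v == NA else v  # noqa: E731
        parts.append(
            f"{star(r['v_gene'])},{star(r['d_gene'])},{star(r['j_gene'])},"
            f"{star(r['c_gene'])},{r['cdr3_nt']},{r['cdr3_aa']},{r['reads']},"
            f"{r['contig_id']}"
        )
    return ";".join(parts)


def emit_dialect(contigs: pd.DataFrame, dialect: str, destination: str) -> str:
    """Write a normalised contig table as one pipeline dialect's output file.

    The emitted file satisfies the corresponding dialect signature, so
    ``load_contigs(..., format="auto")`` detects and loads it.  The WAT3R
    layout is TRA/TRB-only and one row per cell; emitting non-TCR or
    multi-contig-per-slot data in it raises :class:`UnsupportedDialect`.
    """
    df = contigs
    bool_str = lambda v: "True" if v is True else ("False" if v is False else "")  # noqa: E731
    if dialect == "tenx":
        out = pd.DataFrame(
            {
                "barcode": df["barcode"],
                "is_cell": "True",
                "contig_id": df["contig_id"],
                "high_confidence": "True",
                "chain": df["locus"],
                "v_gene": df["v_gene"],
                "d_gene": df["d_gene"],
                "j_gene": df["j_gene"],
                "c_gene": df["c_gene"],
                "cdr3": df["cdr3_aa"],
                "cdr3_nt": df["cdr3_nt"],
                "reads": df["reads"],
                "umis": df["umis"],
                "productive": df["productive"].map(bool_str),
            }
        )
        out.to_csv(destination, index=False)
    elif dialect == "airr":
        out = pd.DataFrame(
            {
                "cell_id": df["barcode"],
                "sequence_id": df["contig_id"],
                "locus": df["locus"],
                "v_call": df["v_gene"],
                "d_call": df["d_gene"],
                "j_call": df["j_gene"],
                "c_call": df["c_gene"],
                "junction": df["cdr3_nt"],
                "junction_aa": df["cdr3_aa"],
                "productive": df["productive"].map(
                    lambda v: "T" if v is True else ("F" if v is False else "")
                ),
                "consensus_count": df["reads"],
                "duplicate_count": df["umis"],
            }
        )
        out.to_csv(destination, sep="\t", index=False)
    elif dialect == "bd":
        out = pd.DataFrame(
            {
                "Cell_Index": df["barcode"],
                "Chain_Type": df["locus"],
                "V_gene_Dominant": df["v_gene"],
                "D_gene_Dominant": df["d_gene"],
                "J_gene_Dominant": df["j_gene"],
                "C_gene_Dominant": df["c_gene"],
                "CDR3_Nucleotide_Dominant": df["cdr3_nt"],
                "CDR3_Translation_Dominant": df["cdr3_aa"],
                "Read_Count": df["reads"],
                "Molecule_Count": df["umis"],
                "Productive": df["productive"].map(bool_str),
            }
        )
        out.to_csv(destination, index=False)
    elif dialect == "mixcr":
        out = pd.DataFrame(
            {
                "cloneId": range(len(df)),
                "tagValueCELL": df["barcode"],
                "allVHitsWithScore": df["v_gene"].map(
                    lambda v: NA if v == NA else f"{v}*00(100)"
                ),
                "allDHitsWithScore": df["d_gene"].map(
                    lambda v: NA if v == NA else f"{v}*00(50)"
                ),
                "allJHitsWithScore": df["j_gene"].map(
                    lambda v: NA if v == NA else f"{v}*00(80)"
                ),
                "allCHitsWithScore": df["c_gene"].map(
                    lambda v: NA if v == NA else f"{v}*00(90)"
                ),
                "nSeqCDR3": df["cdr3_nt"],
                "aaSeqCDR3": df["cdr3_aa"],
                "readCount": df["reads"],
                "uniqueMoleculeCount": df["umis"],
            }
        )
        out.to_csv(destination, sep="\t", index=False)
    elif dialect == "parse":
        out = pd.DataFrame(
            {
                "barcode": df["barcode"],
                "sample": df["sample_id"],
                "chain": df["locus"],
                "v_gene": df["v_gene"],
                "d_gene": df["d_gene"],
                "j_gene": df["j_gene"],
                "c_gene": df["c_gene"],
                "cdr3_aa": df["cdr3_aa"],
                "cdr3_nt": df["cdr3_nt"],
                "transcript_count": df["umis"],
                "read_count": df["reads"],
                "productive": df["productive"].map(bool_str),
            }
        )
        out.to_csv(destination, index=False)
    elif dialect == "trust4":
        from .constants import CHAIN1_LOCI, TCR_LOCI

        rows = []
        for bc, grp in df.groupby("barcode", sort=True):
            is1 = grp["locus"].isin(CHAIN1_LOCI)
            c1 = grp[is1].sort_values(["reads"], ascending=False, kind="mergesort")
            c2 = grp[~is1].sort_values(["reads"], ascending=False, kind="mergesort")
            any_t = grp["locus"].isin(TCR_LOCI).any()
            rows.append(
                {
                    "barcode": bc,
                    "cell_type": "abT" if any_t else "B",
                    "chain1": _pack_trust4(c1.head(1)) if len(c1) else "*",
                    "chain2": _pack_trust4(c2.head(1)) if len(c2) else "*",
                    "secondary_chain1": _pack_trust4(c1.iloc[1:]) if len(c1) > 1 else "*",
                    "secondary_chain2": _pack_trust4(c2.iloc[1:]) if len(c2) > 1 else "*",
                }
            )
        pd.DataFrame(rows).to_csv(destination, sep="\t", index=False)
    elif dialect == "wat3r":
        if not df["locus"].isin({"TRA", "TRB"}).all():
            raise UnsupportedDialect(
                "the WAT3R layout only carries TRA/TRB chains"
            )
        rows = []
        for bc, grp in df.groupby("barcode", sort=True):
            if (grp["locus"] == "TRA").sum() > 1 or (grp["locus"] == "TRB").sum() > 1:
                raise UnsupportedDialect(
                    "the WAT3R layout carries at most one TRA and one TRB per cell"
                )
            row = {"BC": bc}
            for locus in ("TRB", "TRA"):
                sub = grp[grp["locus"] == locus]
                if len(sub):
                    r = sub.iloc[0]
                    row[f"{locus}V"] = r["v_gene"]
                    if locus == "TRB":
                        row["TRBD"] = r["d_gene"]
                    row[f"{locus}J"] = r["j_gene"]
                    row[f"{locus}_CDR3"] = r["cdr3_aa"]
                    row[f"{locus}_CDR3_nt"] = r["cdr3_nt"]
                    row[f"{locus}_UMIcount"] = r["umis"]
                else:
                    row[f"{locus}V"] = NA
                    if locus == "TRB":
                        row["TRBD"] = NA
                    row[f"{locus}J"] = NA
                    row[f"{locus}_CDR3"] = NA
                    row[f"{locus}_CDR3_nt"] = NA
                    row[f"{locus}_UMIcount"] = 0
            rows.append(row)
        cols = ["BC", "TRBV", "TRBD", "TRBJ", "TRB_CDR3", "TRB_CDR3_nt",
                "TRB_UMIcount", "TRAV", "TRAJ", "TRA_CDR3", "TRA_CDR3_nt",
                "TRA_UMIcount"]
        pd.DataFrame(rows)[cols].to_csv(destination, index=False)
    else:
        raise UnsupportedDialect(f"unknown dialect {dialect!r}")
    return destination
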