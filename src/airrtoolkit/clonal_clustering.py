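"""Edit-distance clonal clustering of CDR3 sequences.

Sequences are linked when their normalized Levenshtein similarity

    sim(a, b) = 1 - lev(a, b) / max(|a|, |b|)

reaches a threshold (default 0.85); connected components of the resulting
graph are the clusters.  Two lossless prefilters keep the pair search
sub-quadratic in practice:

* length filter — a pair with ``|len(a) - len(b)| > floor((1-t) * max)``
  cannot reach similarity ``t``, because the edit distance is at least the
  length difference;
* character-bag filter — the edit distance is at least
  ``max(|a|, |b|) - |multiset intersection|``, computable from per-sequence
  letter counts without dynamic programming.

Surviving candidate pairs are verified with a banded edit-distance
computation that aborts once the distance exceeds the threshold-implied
bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from .constants import DEFAULT_SIMILARITY_THRESHOLD, NA
from .errors import EmptySequence


def levenshtein(a: str, b: str, k: int | None = None) -> int:
    """Unit-cost edit distance; returns -1 when a bound ``k`` is exceeded."""
    if k is None:
        return edlib.align(a, b, task="distance")["editDistance"]
    return edlib.align(a, b, task="distance", k=k)["editDistance"]


def normalized_similarity(a: str, b: str) -> float:
    """1 - lev(a,b)/max(|a|,|b|), in [0, 1]."""
    if not a or not b:
        raise EmptySequence("similarity requires non-empty sequences")
    return 1.0 - levenshtein(a, b) / max(len(a), len(b))


@dataclass
class ClusterGraph:
    """Similarity graph over unique sequences.

    Attributes
    ----------
    nodes
        One row per unique sequence (within its clustering scope):
        ``sequence, multiplicity, v_gene, group, cluster``.
    edges
        ``seq_a, seq_b, similarity, cluster`` — only pairs at or above the
        threshold.
    threshold
        The similarity threshold the graph was built with.
    """

    nodes: pd.DataFrame
    edges: pd.DataFrame
    threshold: float

    @property
    def components(self) -> dict[str, str]:
        """sequence -> cluster label (first scope occurrence wins)."""
        return dict(zip(self.nodes["sequence"], self.nodes["cluster"]))


class _DSU:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _bag_counts(seqs: list[str]) -> np.ndarray:
    """Per-sequence letter counts over A..Z (uint16)."""
    out = np.zeros((len(seqs), 26), dtype=np.uint16)
    for i, s in enumerate(seqs):
        for ch in s:
            o = ord(ch) - 65
            if 0 <= o < 26:
                out[i, o] += 1
    return out


def _candidate_pairs(seqs: list[str], threshold: float):
    """Yield (i, j, k_pair) for pairs surviving length and bag prefilters."""
    order = sorted(range(len(seqs)), key=lambda i: len(seqs[i]))
    lengths = np.array([len(seqs[i]) for i in order])
    bags = _bag_counts([seqs[i] for i in order])
    # bucket boundaries by length
    uniq_lens, starts = np.unique(lengths, return_index=True)
    bounds = dict(zip(uniq_lens.tolist(), starts.tolist()))
    ends = dict(zip(uniq_lens.tolist(), np.append(starts[1:], len(order)).tolist()))
    for lb in uniq_lens.tolist():
        k_pair = int((1.0 - threshold) * lb + 1e-12)
        lo = lb - k_pair
        for la in uniq_lens.tolist():
            if la < lo or la > lb:
                continue
            a0, a1 = bounds[la], ends[la]
            b0, b1 = bounds[lb], ends[lb]
            A, B = bags[a0:a1], bags[b0:b1]
            # chunk rows of A to bound memory at ~256 * nb * 26 ints
            for c0 in range(0, a1 - a0, 256):
                c1 = min(c0 + 256, a1 - a0)
                l1 = np.abs(
                    A[c0:c1, None, :].astype(np.int32) - B[None, :, :]
                ).sum(axis=2)
                lower = (lb - la + l1) // 2 + ((lb - la + l1) % 2)
                ii, jj = np.nonzero(lower <= k_pair)
                for i_loc, j_loc in zip(ii.tolist(), jj.tolist()):
                    gi = order[a0 + c0 + i_loc]
                    gj = order[b0 + j_loc]
                    if la == lb and gi >= gj:
                        continue
                    yield gi, gj, k_pair


def _cluster_partition(seqs: list[str], threshold: float):
    """Edges + component assignment for one scope (one group/V bucket)."""
    n = len(seqs)
    dsu = _DSU(n)
    edges = []
    for i, j, k_pair in _candidate_pairs(seqs, threshold):
        d = levenshtein(seqs[i], seqs[j], k=k_pair)
        if d < 0:
            continue
        sim = 1.0 - d / max(len(seqs[i]), len(seqs[j]))
        if sim >= threshold:
            edges.append((i, j, sim))
            dsu.union(i, j)
    comp = [dsu.find(i) for i in range(n)]
    return edges, comp


def cluster_sequences(
    sequences,
    threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
    same_v: bool = False,
    group_by: str | None = None,
    chain_label: str | None = None,
) -> ClusterGraph:
    """Cluster CDR3 sequences by normalized Levenshtein similarity.

    Parameters
    ----------
    sequences
        Either an iterable of strings, or a DataFrame with a ``sequence``
        column and optional ``v_gene``, ``count`` and grouping columns.
        Repeated sequences collapse to one node whose multiplicity is the
        number of occurrences (or the summed ``count``).
    threshold
        Similarity threshold in (0, 1]; pairs at or above it are linked.
    same_v
        When true, only sequences sharing a V gene may be linked.
    group_by
        Optional column name: clustering runs independently within each group.
    chain_label
        Optional prefix for cluster labels, e.g. ``"TRA"`` gives
        ``TRA.cluster.1``.

    Returns
    -------
    ClusterGraph
        Cluster labels ``[<chain>.]cluster.<k>`` are assigned per scope by
        decreasing component size, ties broken by the lexicographically
        smallest member sequence.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if isinstance(sequences, pd.DataFrame):
        df = sequences.copy()
    else:
        df = pd.DataFrame({"sequence": list(sequences)})
    if "v_gene" not in df.columns:
        df["v_gene"] = NA
    if "count" not in df.columns:
        df["count"] = 1
    if group_by is None:
        df["_group"] = "all"
    else:
        df["_group"] = df[group_by].astype(str)
    df = df[df["sequence"].astype(str).str.len() > 0]
    df = df[df["sequence"] != NA]

    prefix = f"{chain_label}.cluster" if chain_label else "cluster"
    node_rows = []
    edge_rows = []
    for group, gdf in df.groupby("_group", sort=True):
        # nodes: unique sequences within the group (and V gene when gating)
        if same_v:
            agg = (
                gdf.groupby(["v_gene", "sequence"], sort=True)
                .agg(multiplicity=("count", "sum"))
                .reset_index()[["sequence", "multiplicity", "v_gene"]]
            )
        else:
            agg = (
                gdf.groupby("sequence", sort=True)
                .agg(multiplicity=("count", "sum"), v_gene=("v_gene", "first"))
                .reset_index()
            )
        seqs = agg["sequence"].tolist()
        vgenes = agg["v_gene"].tolist()
        if same_v:
            scopes: dict[str, list[int]] = {}
            for i, v in enumerate(vgenes):
                scopes.setdefault(str(v), []).append(i)
        else:
            scopes = {"*": list(range(len(seqs)))}
        comp_global = {}
        comp_counter = 0
        edges_local = []
        for _, idxs in sorted(scopes.items()):
            sub = [seqs[i] for i in idxs]
            edges, comp = _cluster_partition(sub, threshold)
            remap = {}
            for local_root in comp:
                if local_root not in remap:
                    remap[local_root] = comp_counter
                    comp_counter += 1
            for i_loc, root in enumerate(comp):
                comp_global[idxs[i_loc]] = remap[root]
            for i_loc, j_loc, sim in edges:
                edges_local.append((idxs[i_loc], idxs[j_loc], sim))
        # label components: decreasing node count, then lexicographic min member
        members: dict[int, list[int]] = {}
        for i, c in comp_global.items():
            members.setdefault(c, []).append(i)
        ranked = sorted(
            members.items(),
            key=lambda kv: (-len(kv[1]), min(seqs[i] for i in kv[1])),
        )
        label_of_comp = {
            c: f"{prefix}.{rank + 1}" for rank, (c, _) in enumerate(ranked)
        }
        for i, seq in enumerate(seqs):
            node_rows.append(
                {
                    "sequence": seq,
                    "multiplicity": int(agg["multiplicity"].iloc[i]),
                    "v_gene": vgenes[i],
                    "group": group,
                    "cluster": label_of_comp[comp_global[i]],
                }
            )
        for i, j, sim in edges_local:
            edge_rows.append(
                {
                    "seq_a": seqs[i],
                    "seq_b": seqs[j],
                    "similarity": sim,
                    "cluster": label_of_comp[comp_global[i]],
                    "group": group,
                }
            )
    nodes = pd.DataFrame(
        node_rows,
        columns=["sequence", "multiplicity", "v_gene", "group", "cluster"],
    )
    edges = pd.DataFrame(
        edge_rows, columns=["seq_a", "seq_b", "similarity", "cluster", "group"]
    )
    return ClusterGraph(nodes=nodes, edges=edges, threshold=threshold)


def export_graph(graph: ClusterGraph, format: str, destination: str) -> str:
    """Write the cluster graph as an edge-list TSV or GraphML file.

    The edge list carries ``seq_a, seq_b, similarity, cluster``; GraphML
    preserves every node (isolated ones included) with ``multiplicity``,
    ``v_gene``, ``group`` and ``cluster`` attributes.
    """
    if format == "edgelist":
        graph.edges[["seq_a", "seq_b", "similarity", "cluster"]].to_csv(
            destination, sep="\t", index=False
        )
    elif format == "graphml":
        import networkx as nx

        g = nx.Graph()
        for _, row in graph.nodes.iterrows():
            node_id = f"{row['group']}|{row['sequence']}"
            g.add_node(
                node_id,
                sequence=row["sequence"],
                multiplicity=int(row["multiplicity"]),
                v_gene=str(row["v_gene"]),
                group=str(row["group"]),
                cluster=row["cluster"],
            )
        for _, row in graph.edges.iterrows():
            g.add_edge(
                f"{row['group']}|{row['seq_a']}",
                f"{row['group']}|{row['seq_b']}",
                similarity=float(row["similarity"]),
            )
        nx.write_graphml(g, destination)
    else:
        raise ValueError(f"unknown graph format {format!r}")
    return destination
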