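"""Indel re-coding and median-joining haplotype networks.

Network software for haplotype data masks alignment columns with too much
missing data, which on the COI-COII region would silently delete the P
element (absent in C-lineage sequences) and unshared Q copies. The re-coding
implemented here replaces every gap state with a surrogate base chosen from
the possibilities left at that column, so each indel column becomes an
ordinary countable character and no column is ever masked.

The median-joining construction follows the classic Bandelt scheme: a
minimum-spanning network (union of all minimum spanning trees, relaxed by an
epsilon margin) is augmented with quasi-median sequences of connected
triplets whenever adding one lowers the total connection cost, then median
nodes that stopped earning their keep are pruned, to a fixed point. One
network is built per structure class; classes are never mixed because their
alignments do not share a column space.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from coicoii.haplotypes import UnitAnchoredAlignment

__all__ = [
    "RecodedAlignment",
    "HaplotypeNetwork",
    "RecodingError",
    "recode_alignment",
    "hamming_matrix",
    "median_joining",
    "build_networks",
    "export_network",
    "read_graphml_network",
]

BASES = "ACGT"

#: Cap on quasi-median expansion per triplet (columns with three distinct
#: states multiply the candidate count).
_MAX_TRIPLET_CANDIDATES = 256


class RecodingError(ValueError):
    """Raised when a gapped column already holds all four bases."""


@dataclass(frozen=True)
class RecodedAlignment:
    """Gap-free four-letter matrix derived from a gapped alignment.

    Pairwise Hamming distance between recoded rows equals the number of SNP
    columns plus indel columns between the original rows. ``column_map``
    records, per altered column, the surrogate base used; ``excluded_rows``
    lists N-bearing rows dropped before recoding.
    """

    structure_class: str
    rows: dict[str, str]
    column_map: tuple[tuple[int, str], ...]
    excluded_rows: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("ragged recoded rows")
        for name, row in self.rows.items():
            bad = set(row) - set(BASES)
            if bad:
                raise ValueError(f"row {name!r} contains non-ACGT states {bad}")


def recode_alignment(alignment: UnitAnchoredAlignment) -> RecodedAlignment:
    """Replace gap states with surrogate bases, column by column.

    In each gapped column the surrogate is the alphabetically first base of
    {A,C,G,T} absent from the column's observed bases — deterministic, and
    guaranteed to differ from every real state, so a gap/base contrast stays
    a contrast after recoding. Rows containing N are excluded up front (a
    surrogate for N is not defined by the scheme); a gapped column already
    showing all four bases raises :class:`RecodingError` naming the column.
    """
    excluded = tuple(
        sorted(name for name, row in alignment.rows.items() if "N" in row)
    )
    kept = {n: r for n, r in alignment.rows.items() if n not in excluded}
    if not kept:
        raise ValueError("no rows left after excluding N-bearing rows")
    names = sorted(kept)
    length = len(kept[names[0]])
    columns = [[kept[n][i] for n in names] for i in range(length)]
    notes: list[tuple[int, str]] = []
    recoded_cols: list[list[str]] = []
    for idx, col in enumerate(columns):
        if "-" not in col:
            recoded_cols.append(col)
            continue
        observed = {c for c in col if c != "-"}
        free = [b for b in BASES if b not in observed]
        if not free:
            raise RecodingError(
                f"column {idx}: all four bases present alongside a gap; "
                "recoding impossible"
            )
        surrogate = free[0]
        recoded_cols.append([surrogate if c == "-" else c for c in col])
        notes.append((idx, surrogate))
    rows = {
        name: "".join(recoded_cols[i][j] for i in range(length))
        for j, name in enumerate(names)
    }
    return RecodedAlignment(
        structure_class=alignment.structure_class,
        rows=rows,
        column_map=tuple(notes),
        excluded_rows=excluded,
    )


def hamming_matrix(recoded: RecodedAlignment) -> tuple[list[str], np.ndarray]:
    """Symmetric integer Hamming distance matrix over the recoded rows."""
    names = sorted(recoded.rows)
    arr = np.array([list(recoded.rows[n]) for n in names])
    if arr.size == 0:
        return names, np.zeros((len(names), len(names)), dtype=int)
    dist = (arr[:, None, :] != arr[None, :, :]).sum(axis=2).astype(int)
    return names, dist


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _mst_edges(seqs: list[str]) -> tuple[list[tuple[int, int, int]], int]:
    """Kruskal MST over sequences with deterministic tie-breaks
    (weight, then lexicographic endpoint sequences). Returns (edges, cost)."""
    n = len(seqs)
    order = sorted(
        (
            (_hamming(seqs[i], seqs[j]), min(seqs[i], seqs[j]), max(seqs[i], seqs[j]), i, j)
            for i in range(n)
            for j in range(i + 1, n)
        )
    )
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges = []
    cost = 0
    for w, _, _, i, j in order:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            edges.append((i, j, w))
            cost += w
    return edges, cost


def _mst_cost(seqs: list[str]) -> int:
    return _mst_edges(seqs)[1]


def _minimax_distances(seqs: list[str]) -> np.ndarray:
    """Minimax (bottleneck) path distances over the complete Hamming graph:
    the largest edge on the minimax path between each pair, computed on the
    MST."""
    n = len(seqs)
    edges, _ = _mst_edges(seqs)
    adj: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n)}
    for i, j, w in edges:
        adj[i].append((j, w))
        adj[j].append((i, w))
    mm = np.zeros((n, n), dtype=int)
    for src in range(n):
        seen = {src}
        stack = [(src, 0)]
        while stack:
            node, best = stack.pop()
            for nxt, w in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    mm[src, nxt] = max(best, w)
                    stack.append((nxt, max(best, w)))
    return mm


def _feasible_links(seqs: list[str], epsilon: int) -> list[tuple[int, int, int]]:
    """Edges of the minimum-spanning network: pairs whose direct distance is
    within epsilon of their minimax path distance (epsilon 0 recovers the
    union of all MSTs)."""
    mm = _minimax_distances(seqs)
    links = []
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            d = _hamming(seqs[i], seqs[j])
            if d <= mm[i, j] + epsilon:
                links.append((i, j, d))
    return links


def _quasi_medians(u: str, v: str, w: str) -> list[str]:
    """Quasi-median sequences of a triplet: per-column majority where one
    exists; columns with three distinct states contribute all three."""
    slots: list[tuple[str, ...]] = []
    n_candidates = 1
    for a, b, c in zip(u, v, w):
        if a == b or a == c:
            slots.append((a,))
        elif b == c:
            slots.append((b,))
        else:
            slots.append(tuple(sorted({a, b, c})))
            n_candidates *= 3
        if n_candidates > _MAX_TRIPLET_CANDIDATES:
            return []
    return ["".join(combo) for combo in itertools.product(*slots)]


@dataclass
class HaplotypeNetwork:
    """A median-joining network for one structure class.

    ``graph`` is an undirected networkx graph whose nodes carry ``sequence``,
    ``kind`` (observed/median), ``frequency`` and ``populations`` attributes
    and whose edges carry integer ``weight`` equal to the Hamming distance of
    their endpoint sequences. ``total_cost`` is the connection cost of the
    final node set (its MST cost), the quantity median addition minimizes.
    """

    structure_class: str
    graph: nx.Graph
    epsilon: int
    total_cost: int

    @property
    def observed(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "observed"]

    @property
    def medians(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "median"]


def median_joining(
    recoded: RecodedAlignment,
    epsilon: int = 0,
    frequencies: dict[str, int] | None = None,
    populations: dict[str, str] | None = None,
) -> HaplotypeNetwork:
    """Build the median-joining network of a recoded alignment.

    Median vectors (labeled ``mv1``, ``mv2``, ... in insertion order) are
    added greedily whenever a quasi-median of a connected triplet lowers the
    connection cost of the node set; obsolete medians (degree <= 2 whose
    removal neither disconnects observed nodes nor raises the cost) are
    pruned afterwards. All tie-breaks are lexicographic on node sequences, so
    the result is deterministic. One haplotype yields a single node, two an
    edge weighted by their distance.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if not recoded.rows:
        raise ValueError("empty recoded alignment")
    seq_to_name: dict[str, str] = {}
    for name in sorted(recoded.rows):
        seq = recoded.rows[name]
        if seq in seq_to_name:
            raise ValueError(
                f"rows {seq_to_name[seq]!r} and {name!r} share a sequence; "
                "collapse haplotypes before building the network"
            )
        seq_to_name[seq] = name
    observed_seqs = sorted(seq_to_name)
    node_seqs = list(observed_seqs)
    median_seqs: list[str] = []

    # Median addition to a fixed point: each pass evaluates quasi-medians of
    # connected triplets and commits the single best cost-reducing one.
    for _ in range(4 * len(observed_seqs) + 16):
        links = _feasible_links(node_seqs, epsilon)
        linked = {(i, j) for i, j, _ in links}
        current = _mst_cost(node_seqs)
        existing = set(node_seqs)
        candidates: set[str] = set()
        n = len(node_seqs)
        for i, j, k in itertools.combinations(range(n), 3):
            pairs = [(i, j) in linked, (i, k) in linked, (j, k) in linked]
            if sum(pairs) < 2:
                continue
            for m in _quasi_medians(node_seqs[i], node_seqs[j], node_seqs[k]):
                if m not in existing:
                    candidates.add(m)
        best: tuple[int, str] | None = None
        for m in sorted(candidates):
            cost = _mst_cost(node_seqs + [m])
            if cost < current and (best is None or (cost, m) < best):
                best = (cost, m)
        if best is None:
            break
        node_seqs.append(best[1])
        median_seqs.append(best[1])

    # Prune obsolete medians.
    changed = True
    while changed:
        changed = False
        links = _feasible_links(node_seqs, epsilon)
        degree: dict[int, int] = {i: 0 for i in range(len(node_seqs))}
        for i, j, _ in links:
            degree[i] += 1
            degree[j] += 1
        current = _mst_cost(node_seqs)
        for seq in sorted(median_seqs):
            idx = node_seqs.index(seq)
            if degree[idx] > 2:
                continue
            without = [s for s in node_seqs if s != seq]
            if _mst_cost(without) <= current:
                node_seqs = without
                median_seqs.remove(seq)
                changed = True
                break

    graph = nx.Graph()
    median_names: dict[str, str] = {
        seq: f"mv{k + 1}" for k, seq in enumerate(median_seqs)
    }
    names = {}
    for seq in node_seqs:
        if seq in seq_to_name:
            names[seq] = seq_to_name[seq]
            graph.add_node(
                seq_to_name[seq],
                sequence=seq,
                kind="observed",
                frequency=(frequencies or {}).get(seq_to_name[seq], 1),
                populations=(populations or {}).get(seq_to_name[seq], ""),
            )
        else:
            names[seq] = median_names[seq]
            graph.add_node(
                median_names[seq], sequence=seq, kind="median", frequency=0, populations=""
            )
    for i, j, w in _feasible_links(node_seqs, epsilon):
        graph.add_edge(names[node_seqs[i]], names[node_seqs[j]], weight=int(w))
    return HaplotypeNetwork(
        structure_class=recoded.structure_class,
        graph=graph,
        epsilon=epsilon,
        total_cost=_mst_cost(node_seqs),
    )


def build_networks(
    alignments: dict[str, UnitAnchoredAlignment],
    epsilon: int = 0,
    frequencies: dict[str, dict[str, int]] | None = None,
    populations: dict[str, dict[str, str]] | None = None,
) -> dict[str, HaplotypeNetwork]:
    """One median-joining network per structure class; classes never mixed.

    Empty classes are skipped with a warning rather than raised on.
    """
    import warnings as _warnings

    networks: dict[str, HaplotypeNetwork] = {}
    for cls, alignment in sorted(alignments.items()):
        if not alignment.rows:
            _warnings.warn(f"structure class {cls!r} is empty; skipped")
            continue
        recoded = recode_alignment(alignment)
        networks[cls] = median_joining(
            recoded,
            epsilon=epsilon,
            frequencies=(frequencies or {}).get(cls),
            populations=(populations or {}).get(cls),
        )
    return networks


def export_network(network: HaplotypeNetwork, path: str | Path, format: str) -> None:
    """Write a network as GraphML or as a NEXUS Network block."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(network.graph, path)
    elif format == "nexus":
        _write_nexus(network, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_graphml_network(path: str | Path) -> nx.Graph:
    graph = nx.read_graphml(path)
    for _, _, data in graph.edges(data=True):
        data["weight"] = int(data["weight"])
    return graph


def _nexus_escape(label: str) -> str:
    return f"'{label}'" if any(c in label for c in " |()[]{};'\"") else label


def _write_nexus(network: HaplotypeNetwork, path: Path) -> None:
    g = network.graph
    taxa = sorted(network.observed)
    nodes = sorted(g.nodes)
    index = {n: i + 1 for i, n in enumerate(nodes)}
    lines = ["#NEXUS", ""]
    lines.append("BEGIN TAXA;")
    lines.append(f"    DIMENSIONS NTAX={len(taxa)};")
    lines.append("    TAXLABELS")
    for t in taxa:
        lines.append(f"        {_nexus_escape(t)}")
    lines.append("    ;")
    lines.append("END;")
    lines.append("")
    lines.append("BEGIN NETWORK;")
    lines.append(
        f"    DIMENSIONS NVERTICES={g.number_of_nodes()} NEDGES={g.number_of_edges()};"
    )
    lines.append("    VERTICES")
    for n in nodes:
        kind = g.nodes[n]["kind"]
        lines.append(f"        {index[n]} {_nexus_escape(n)} [{kind}]")
    lines.append("    ;")
    lines.append("    EDGES")
    for k, (u, v, data) in enumerate(
        sorted(g.edges(data=True), key=lambda e: (e[0], e[1])), start=1
    ):
        lines.append(f"        {k} {index[u]} {index[v]} {data['weight']}")
    lines.append("    ;")
    lines.append("END;")
    path.write_text("\n".join(lines) + "\n")
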