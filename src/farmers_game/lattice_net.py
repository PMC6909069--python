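"""Square-lattice interaction network with death reconnection.

Players sit on a rows x cols grid and interact with their von Neumann
(4-) neighbours.  By default the lattice has a hard border — no wraparound —
so corner and edge players have fewer interactions per round than interior
players.  A toroidal ("borderless") variant exists for scaling checks.

When a player dies it is removed from play and its still-alive former
neighbours are connected pairwise to each other (a clique), so survivors
keep playing.  This reconnection rule is a policy choice exposed on
:meth:`Network.remove_node_reconnect`.
"""

from __future__ import annotations

import pandas as pd


class Network:
    """Undirected interaction network over lattice nodes.

    Node ids are row-major: ``id = row * cols + col``.  Adjacency is kept as
    one set per node; edge iteration uses the sorted edge list so that runs
    are reproducible.
    """

    def __init__(self, rows: int, cols: int, adjacency: list[set[int]]):
        self.rows = rows
        self.cols = cols
        self.n_nodes = rows * cols
        self.adjacency = adjacency
        self.alive = [True] * self.n_nodes

    # -- queries ---------------------------------------------------------

    def coords(self, node: int) -> tuple[int, int]:
        return divmod(node, self.cols)

    def degree(self, node: int) -> int:
        return len(self.adjacency[node])

    def edges(self) -> list[tuple[int, int]]:
        """Sorted list of (a, b) with a < b, over all current edges."""
        out = []
        for a, nbrs in enumerate(self.adjacency):
            for b in nbrs:
                if a < b:
                    out.append((a, b))
        out.sort()
        return out

    def n_edges(self) -> int:
        return sum(len(s) for s in self.adjacency) // 2

    def alive_count(self) -> int:
        return sum(self.alive)

    # -- mutation --------------------------------------------------------

    def remove_node_reconnect(self, node: int, policy: str = "pairing") -> int:
        """Mark ``node`` dead, drop its edges, and reconnect its live former
        neighbours according to ``policy``.

        policy "pairing" (default) joins disjoint consecutive pairs of the
        sorted live former neighbours, so each survivor regains at most the
        one link it lost and degrees stay lattice-like; "clique" joins every
        pair of still-alive former neighbours; "none" performs no
        reconnection.  Pairs already connected are skipped in all policies.
        Returns the number of new edges created.
        """
        if not self.alive[node]:
            raise ValueError(f"node {node} is already dead")
        if policy not in ("pairing", "clique", "none"):
            raise ValueError(f"unknown reconnection policy: {policy!r}")
        self.alive[node] = False
        neighbours = sorted(self.adjacency[node])
        for b in neighbours:
            self.adjacency[b].discard(node)
        self.adjacency[node].clear()
        created = 0
        live = [b for b in neighbours if self.alive[b]]
        if policy == "clique":
            pairs = [(a, b) for i, a in enumerate(live) for b in live[i + 1:]]
        elif policy == "pairing":
            pairs = list(zip(live[0::2], live[1::2]))
        else:
            pairs = []
        for a, b in pairs:
            if b not in self.adjacency[a]:
                self.adjacency[a].add(b)
                self.adjacency[b].add(a)
                created += 1
        return created

    # -- export ----------------------------------------------------------

    def node_table(self) -> pd.DataFrame:
        rows = [
            {"id": i, "row": i // self.cols, "col": i % self.cols,
             "alive": self.alive[i]}
            for i in range(self.n_nodes)
        ]
        return pd.DataFrame(rows)

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges(), columns=["node_a", "node_b"])


def build_lattice(rows: int, cols: int, borderless: bool = False) -> Network:
    """Build a rows x cols 4-neighbourhood lattice.

    With ``borderless=True`` the lattice wraps toroidally, so every node has
    degree 4 (degenerate wrap edges on 1- or 2-wide lattices are collapsed
    to simple edges).
    """
    if rows < 1 or cols < 1:
        raise ValueError(f"lattice dimensions must be >= 1, got {rows}x{cols}")
    adjacency: list[set[int]] = [set() for _ in range(rows * cols)]

    def connect(a: int, b: int) -> None:
        if a != b:
            adjacency[a].add(b)
            adjacency[b].add(a)

    for r in range(rows):
        for c in range(cols):
            node = r * cols + c
            if c + 1 < cols:
                connect(node, node + 1)
            elif borderless:
                connect(node, r * cols)
            if r + 1 < rows:
                connect(node, node + cols)
            elif borderless:
                connect(node, c)
    return Network(rows, cols, adjacency)


def border_fraction(network: Network) -> float:
    """Fraction of nodes with initial degree < 4 (0 on a toroidal lattice).

    Meaningful on a freshly built lattice, before any deaths.
    """
    return sum(1 for s in network.adjacency if len(s) < 4) / network.n_nodes
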