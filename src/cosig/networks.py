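"""Capped interaction-network growth around signature (focus) genes.

Molecular interaction edges carry a directness flag (direct / indirect), a
relation code (E expression, T transcription, P phosphorylation /
dephosphorylation, PP protein-protein binding) and an optional regulatory
sign.  Networks are grown greedily and deterministically from focus-gene
seeds up to a molecule cap, then ranked by the upper-tail hypergeometric
probability of their focus-gene content (the same right-tailed Fisher
kernel the enrichment stage uses).

The growth rule: seed with the unused focus gene that has the most
focus-gene neighbors (ties broken lexicographically); repeatedly add the
adjacent node with the most edges into the current network, preferring
focus candidates over non-focus ones, until the cap is reached or no
connected candidate remains.  Focus genes already consumed by an earlier
network are not reused, so distinct networks are disjoint in their focus
genes (shared non-focus connectors are allowed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .enrichment import hypergeom_right_tail, score_from_p
from .errors import ConsistencyError, FormatError

__all__ = [
    "InteractionGraph",
    "NetworkResult",
    "load_interactions",
    "write_interactions",
    "build_networks",
    "score_network",
    "regulator_activity",
]

DIRECTNESS = frozenset({"direct", "indirect"})
RELATIONS = frozenset({"E", "T", "P", "PP"})
SIGNS = frozenset({"activating", "inhibiting", "unknown"})
EDGE_COLUMNS = ["source", "target", "directness", "relation", "sign"]


@dataclass
class InteractionGraph:
    """An undirected interaction graph; each edge keeps its typed records.

    Multiple relations between the same pair are stored as separate records
    on one graph edge.  Self-loops encode self-regulation (e.g. a positive
    feedback) and are kept but never traversed during network growth.
    """

    graph: nx.Graph

    @classmethod
    def from_frame(cls, edges: pd.DataFrame, source_name: str = "<frame>") -> "InteractionGraph":
        missing = [c for c in EDGE_COLUMNS[:4] if c not in edges.columns]
        if missing:
            raise FormatError(f"interaction table missing column(s) {missing}")
        if "sign" not in edges.columns:
            edges = edges.assign(sign="unknown")
        g = nx.Graph()
        seen: set[tuple[str, str, str]] = set()
        n_dup = 0
        for lineno, row in enumerate(edges.itertuples(index=False), start=2):
            a, b = str(row.source), str(row.target)
            directness, relation = str(row.directness), str(row.relation)
            sign = str(row.sign) if pd.notna(row.sign) and row.sign else "unknown"
            if directness not in DIRECTNESS:
                raise FormatError(f"unknown directness {directness!r}", line=lineno)
            if relation not in RELATIONS:
                raise FormatError(f"unknown relation {relation!r}", line=lineno)
            if sign not in SIGNS:
                raise FormatError(f"unknown sign {sign!r}", line=lineno)
            key = (min(a, b), max(a, b), relation)
            if key in seen:
                n_dup += 1
                continue
            seen.add(key)
            record = {"directness": directness, "relation": relation, "sign": sign}
            if g.has_edge(a, b):
                g.edges[a, b]["records"].append(record)
            else:
                g.add_edge(a, b, records=[record])
        if n_dup:
            warnings.warn(
                f"{source_name}: dropped {n_dup} duplicate (pair, relation) edge(s)",
                stacklevel=2,
            )
        return cls(graph=g)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a, b, data in sorted(self.graph.edges(data=True)):
            for rec in data["records"]:
                rows.append((a, b, rec["directness"], rec["relation"], rec["sign"]))
        return pd.DataFrame(rows, columns=EDGE_COLUMNS)

    def restrict_direct(self) -> "InteractionGraph":
        """Subgraph keeping only edges with at least one direct record."""
        g = nx.Graph()
        for a, b, data in self.graph.edges(data=True):
            direct = [r for r in data["records"] if r["directness"] == "direct"]
            if direct:
                g.add_edge(a, b, records=direct)
        return InteractionGraph(graph=g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def n_edge_records(self) -> int:
        return sum(len(d["records"]) for _, _, d in self.graph.edges(data=True))


def load_interactions(path: str | Path) -> InteractionGraph:
    edges = pd.read_csv(path, sep="\t", dtype=str)
    return InteractionGraph.from_frame(edges, source_name=str(path))


def write_interactions(ig: InteractionGraph, path: str | Path) -> None:
    ig.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class NetworkResult:
    """One grown network: its molecules, focus content, score and rank."""

    molecules: frozenset[str]
    focus_genes: frozenset[str]
    seed: str
    p_right: float
    score: float
    rank: int = 0

    @property
    def focus_count(self) -> int:
        return len(self.focus_genes)

    @property
    def size(self) -> int:
        return len(self.molecules)


def score_network(
    net: Iterable[str], focus: Iterable[str], universe: Iterable[str]
) -> tuple[float, float]:
    """Right-tailed hypergeometric p and -log10 score of a molecule set."""
    net = set(net)
    focus = set(focus)
    universe = set(universe)
    if not net <= universe:
        raise ConsistencyError("network molecules must lie inside the universe")
    k = len(net & focus)
    p = hypergeom_right_tail(len(universe), len(focus & universe), len(net), k)
    return p, score_from_p(p)


def _neighbors(g: nx.Graph, node: str) -> set[str]:
    return set(g.neighbors(node)) - {node}  # self-loops are not traversed


def build_networks(
    ig: InteractionGraph, focus: Iterable[str], max_size: int = 35
) -> list[NetworkResult]:
    """Grow disjoint-focus networks around the focus genes and rank them."""
    if max_size < 2:
        raise ValueError("max_size must be at least 2")
    g = ig.graph
    focus = set(focus)
    pool = sorted(focus & set(g.nodes))
    if not pool:
        warnings.warn("no focus gene appears in the interaction graph", stacklevel=2)
        return []
    universe = set(g.nodes)
    used_focus: set[str] = set()
    results: list[NetworkResult] = []

    while pool:
        # seed: unused focus gene with the most focus-gene neighbors,
        # lexicographic id on ties
        seed = min(pool, key=lambda x: (-len(_neighbors(g, x) & focus), x))
        net = {seed}
        while len(net) < max_size:
            candidates: set[str] = set()
            for member in net:
                candidates |= _neighbors(g, member)
            candidates -= net
            candidates -= used_focus  # focus genes are consumed by one network only
            if not candidates:
                break
            best = min(
                candidates,
                key=lambda x: (x not in focus, -len(_neighbors(g, x) & net), x),
            )
            net.add(best)
        net_focus = net & focus
        used_focus |= net_focus
        pool = [x for x in pool if x not in used_focus]
        p, score = score_network(net, focus, universe)
        results.append(
            NetworkResult(
                molecules=frozenset(net),
                focus_genes=frozenset(net_focus),
                seed=seed,
                p_right=p,
                score=score,
            )
        )

    results.sort(
        key=lambda r: (-r.score, -r.focus_count, tuple(sorted(r.molecules)))
    )
    for i, r in enumerate(results, start=1):
        r.rank = i
    return results


def networks_to_frame(results: list[NetworkResult]) -> pd.DataFrame:
    rows = [
        {
            "rank": r.rank,
            "seed": r.seed,
            "size": r.size,
            "focus_count": r.focus_count,
            "p_right": r.p_right,
            "score": r.score,
            "molecules": "|".join(sorted(r.molecules)),
        }
        for r in results
    ]
    return pd.DataFrame(
        rows, columns=["rank", "seed", "size", "focus_count", "p_right", "score", "molecules"]
    )


def regulator_activity(
    ig: InteractionGraph, fc: pd.DataFrame, regulator: str
) -> tuple[float, str]:
    """Sign-consistency activity call for a regulator node.

    Each signed target scores +1 when the edge sign is concordant with the
    target's fold-change direction (activating & up, or inhibiting & down)
    and -1 otherwise; z is the sum over targets divided by sqrt(#targets).
    |z| >= 2 yields an activated / inhibited call, otherwise indeterminate.
    Targets whose edges carry conflicting signs are skipped as ambiguous.
    """
    g = ig.graph
    if regulator not in g:
        raise ConsistencyError(f"regulator {regulator!r} not in interaction graph")
    contributions: list[int] = []
    for target in sorted(_neighbors(g, regulator)):
        if target not in fc.index:
            continue
        signs = {
            rec["sign"]
            for rec in g.edges[regulator, target]["records"]
            if rec["sign"] != "unknown"
        }
        if len(signs) != 1:
            continue  # unsigned or ambiguous edge
        sign = signs.pop()
        direction = fc.at[target, "direction"]
        concordant = (sign == "activating" and direction == "up") or (
            sign == "inhibiting" and direction == "down"
        )
        contributions.append(1 if concordant else -1)
    if not contributions:
        raise ConsistencyError(
            f"regulator {regulator!r} has no signed targets with fold-change entries"
        )
    z = sum(contributions) / len(contributions) ** 0.5
    call = "activated" if z >= 2 else "inhibited" if z <= -2 else "indeterminate"
    return z, call
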