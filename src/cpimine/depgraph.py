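"""Dependency graphs of masked sentences: shortest paths and triple topology.

A :class:`DepGraph` holds one parsed sentence — tokens as nodes, typed
dependencies (``nsubj``, ``compound``, ``appos``, ...) as labeled edges.
Shortest dependency paths (SDPs) are computed on the undirected view of the
graph, the standard practice for relation extraction (a directed mode is
available for users who need it).  Ties between equal-length paths are
broken by the lexicographically smallest node-index sequence so the whole
pipeline is reproducible bit-for-bit.

``sp_type`` classifies the topology of the {entity1, interaction word,
entity2} sub-structure into eight classes:

* 0/1/2 — one element lies on the SDP between the other two
  (0: iw on SDP(e1,e2); 1: e1 on SDP(iw,e2); 2: e2 on SDP(e1,iw));
* 3 — star: the three pairwise SDPs meet at a single hub node and removing
  the hub disconnects all three elements from each other;
* 4 — triangle: no element on another pair's SDP and no common hub;
* 5/6/7 — star plus an additional hub-avoiding path between (e1,e2),
  (iw,e2) or (iw,e1) respectively;
* −1 — the three elements are not in one connected component (fragmentary
  parses), encoded downstream as its own one-hot column.

Parsers are pluggable through the :class:`ParserAdapter` contract: any
callable from a masked token sequence to a DepGraph with one node per
token.  Two adapters ship with the package: a fixture store reading
pre-serialized parses (JSON-lines or CoNLL-U) and a small deterministic
rule-based parser producing UD-style trees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Protocol, Sequence

import networkx as nx

DISCONNECTED = -1


@dataclass(frozen=True)
class DepEdge:
    head: int
    dep: int
    label: str


@dataclass
class DepGraph:
    tokens: list[str]
    edges: list[DepEdge]

    def __post_init__(self) -> None:
        n = len(self.tokens)
        seen: set[tuple[int, int]] = set()
        for e in self.edges:
            if not (0 <= e.head < n and 0 <= e.dep < n):
                raise ValueError(f"edge {e} endpoints outside 0..{n - 1}")
            if (e.head, e.dep) in seen:
                raise ValueError(f"duplicate edge between {e.head} and {e.dep}")
            seen.add((e.head, e.dep))

    def to_undirected(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.tokens)))
        for e in self.edges:
            a, b = min(e.head, e.dep), max(e.head, e.dep)
            if g.has_edge(a, b):
                g[a][b]["labels"] = tuple(sorted(set(g[a][b]["labels"]) | {e.label}))
            else:
                g.add_edge(a, b, labels=(e.label,))
        return g

    def to_directed(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(len(self.tokens)))
        for e in self.edges:
            g.add_edge(e.head, e.dep, label=e.label)
        return g


@dataclass(frozen=True)
class DepPath:
    nodes: tuple[int, ...]
    labels: tuple[str, ...]

    @property
    def length(self) -> int:
        """Number of edges on the path."""
        return len(self.nodes) - 1

    @property
    def n_words(self) -> int:
        """Number of words (nodes) on the path."""
        return len(self.nodes)


class ParserAdapter(Protocol):
    def __call__(self, tokens: Sequence[str]) -> DepGraph: ...


class ParserContractError(RuntimeError):
    """An adapter returned a graph inconsistent with its input tokens."""


def parse(tokens: Sequence[str], adapter: ParserAdapter) -> DepGraph:
    """Run *adapter* on the masked token sequence and validate the contract."""
    g = adapter(tokens)
    if len(g.tokens) != len(tokens):
        raise ParserContractError(
            f"adapter returned {len(g.tokens)} nodes for {len(tokens)} tokens"
        )
    return g


# ---------------------------------------------------------------------------
# Shortest dependency paths
# ---------------------------------------------------------------------------

def shortest_path(
    g: DepGraph, a: int, b: int, *, directed: bool = False
) -> DepPath | None:
    """Minimum-edge path between nodes *a* and *b*, or None if disconnected.

    Undirected by default.  Among equal-length paths the lexicographically
    smallest node sequence is returned.
    """
    n = len(g.tokens)
    if not (0 <= a < n and 0 <= b < n):
        raise ValueError(f"nodes {a},{b} outside graph of size {n}")
    if a == b:
        return DepPath((a,), ())
    graph = g.to_directed() if directed else g.to_undirected()
    try:
        best = min(tuple(p) for p in nx.all_shortest_paths(graph, a, b))
    except nx.NetworkXNoPath:
        return None
    labels = tuple(_edge_label(g, u, v) for u, v in zip(best, best[1:]))
    return DepPath(best, labels)


def _edge_label(g: DepGraph, u: int, v: int) -> str:
    labels = sorted(
        e.label for e in g.edges if {e.head, e.dep} == {u, v}
    )
    return labels[0]


def path_labels(p: DepPath) -> dict[str, int]:
    """Multiset of dependency labels along the path."""
    out: dict[str, int] = {}
    for lab in p.labels:
        out[lab] = out.get(lab, 0) + 1
    return out


# ---------------------------------------------------------------------------
# Triple topology (sp_type)
# ---------------------------------------------------------------------------

def sp_type(g: DepGraph, e1: int, iw: int, e2: int) -> int:
    """Classify the {e1, iw, e2} sub-structure topology (0-7, or -1).

    See the module docstring for the eight classes.  Total over connected
    triples; deterministic.
    """
    und = g.to_undirected()
    dist = {x: nx.single_source_shortest_path_length(und, x) for x in (e1, iw, e2)}
    if e2 not in dist[e1] or iw not in dist[e1]:
        return DISCONNECTED

    def on_sdp(x: int, a: int, b: int) -> bool:
        return dist[a].get(x) is not None and dist[a][x] + dist[x].get(b, 10**9) == dist[a][b]

    if on_sdp(iw, e1, e2):
        return 0
    if on_sdp(e1, iw, e2):
        return 1
    if on_sdp(e2, e1, iw):
        return 2

    # hub candidates: nodes on a shortest path for all three pairs
    hubs = [
        h
        for h in und.nodes
        if h not in (e1, iw, e2)
        and _between(und, h, e1, e2, dist)
        and _between(und, h, e1, iw, dist)
        and _between(und, h, iw, e2, dist)
    ]
    if not hubs:
        return 4  # triangle: three pairwise edge-disjoint paths forming a cycle
    h = min(hubs)
    reduced = und.copy()
    reduced.remove_node(h)
    for a, b, t in ((e1, e2, 5), (iw, e2, 6), (iw, e1, 7)):
        if nx.has_path(reduced, a, b):
            return t
    return 3  # pure star


def _between(g: nx.Graph, x: int, a: int, b: int, dist: dict[int, dict[int, int]]) -> bool:
    da = dist[a].get(x)
    db = dist[b].get(x)
    return da is not None and db is not None and da + db == dist[a][b]


# ---------------------------------------------------------------------------
# Adapters
# ---------------------------------------------------------------------------

class FixtureParserAdapter:
    """Parser adapter backed by pre-serialized parses keyed by token sequence.

    Fixture format: one JSON object per line,
    ``{"tokens": [...], "edges": [[head, dep, "label"], ...]}``.
    """

    def __init__(self, parses: dict[tuple[str, ...], DepGraph] | None = None):
        self._parses: dict[tuple[str, ...], DepGraph] = dict(parses or {})

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "FixtureParserAdapter":
        parses: dict[tuple[str, ...], DepGraph] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                rec = json.loads(line)
                g = DepGraph(
                    list(rec["tokens"]),
                    [DepEdge(int(h), int(d), str(l)) for h, d, l in rec["edges"]],
                )
                parses[tuple(rec["tokens"])] = g
        return cls(parses)

    def add(self, graph: DepGraph) -> None:
        self._parses[tuple(graph.tokens)] = graph

    def write_jsonl(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for key in sorted(self._parses):
                g = self._parses[key]
                rec = {
                    "tokens": list(g.tokens),
                    "edges": [[e.head, e.dep, e.label] for e in g.edges],
                }
                fh.write(json.dumps(rec) + "\n")

    def __len__(self) -> int:
        return len(self._parses)

    def __call__(self, tokens: Sequence[str]) -> DepGraph:
        key = tuple(tokens)
        if key not in self._parses:
            raise KeyError(f"no fixture parse for token sequence {key!r}")
        return self._parses[key]


def read_conllu(path: str | Path) -> list[DepGraph]:
    """Read dependency trees from a CoNLL-U file (one graph per sentence).

    Heads use CoNLL-U 1-based convention with 0 = root; root attachments
    produce no edge.  Multi-word-token and empty-node lines are skipped.
    """
    graphs: list[DepGraph] = []
    tokens: list[str] = []
    edges: list[DepEdge] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                continue
            if not line:
                if tokens:
                    graphs.append(DepGraph(tokens, edges))
                    tokens, edges = [], []
                continue
            cols = line.split("\t")
            if "-" in cols[0] or "." in cols[0]:
                continue
            idx = int(cols[0]) - 1
            tokens.append(cols[1])
            head = int(cols[6])
            if head > 0:
                edges.append(DepEdge(head - 1, idx, cols[7]))
    if tokens:
        graphs.append(DepGraph(tokens, edges))
    return graphs


_DET = frozenset({"the", "a", "an", "this", "that", "these", "those", "its", "both"})
_ADP = frozenset({"of", "in", "by", "with", "for", "after", "to", "on", "at", "from",
                  "via", "through", "against", "into"})
_AUX = frozenset({"is", "are", "was", "were", "be", "been", "may", "can", "could",
                  "did", "does", "do"})
_CCONJ = frozenset({"and", "or", "but", "nor"})
_VERB_SUFFIXES = ("ates", "ated", "izes", "ized", "esses", "essed", "ibits",
                  "ibited", "uces", "uced", "eases", "eased", "ocks", "ocked",
                  "erts", "erted", "auses", "aused", "acts", "acted", "inds",
                  "ances", "anced", "enses", "imulates")


class RuleParser:
    """Small deterministic heuristic parser producing UD-style trees.

    Not a trained parser: a fixed rule set chooses a main predicate as root
    and attaches determiners, adpositional phrases and noun modifiers with a
    compact UD-like label inventory.  Its purpose is to satisfy the parser
    contract deterministically wherever pre-computed parses are unavailable;
    swap in fixture parses or an external UD parser for linguistic fidelity.
    """

    def __init__(self, verb_lexicon: Iterable[str] | None = None):
        base = {
            "acts", "binds", "bound", "interacts", "showed", "shows", "enhances",
            "caused", "causes", "remains", "exhibits", "displayed", "serves",
        }
        self.verbs = frozenset(base | {w.lower() for w in (verb_lexicon or [])})

    def _is_verbish(self, word: str) -> bool:
        low = word.lower()
        return low in self.verbs or low.endswith(_VERB_SUFFIXES)

    def _is_content(self, word: str) -> bool:
        low = word.lower()
        return bool(
            word
            and (word[0].isalnum())
            and low not in _DET
            and low not in _ADP
            and low not in _AUX
            and low not in _CCONJ
        )

    def __call__(self, tokens: Sequence[str]) -> DepGraph:
        n = len(tokens)
        if n == 0:
            return DepGraph([], [])
        lows = [t.lower() for t in tokens]
        root = next((i for i, t in enumerate(tokens) if self._is_verbish(t)), None)
        if root is None:
            root = next((i for i, t in enumerate(lows) if t in _AUX), None)
        if root is None:
            root = next((i for i, t in enumerate(tokens) if self._is_content(t)), 0)

        heads = [-1] * n
        labels = [""] * n
        content = [i for i in range(n) if self._is_content(tokens[i]) and i != root]

        def next_content(i: int) -> int | None:
            return next((j for j in content if j > i), None)

        def prev_content(i: int) -> int | None:
            return next((j for j in reversed(content) if j < i), None)

        entity_seen = False
        for i in range(n):
            if i == root:
                continue
            w, low = tokens[i], lows[i]
            if not w[0].isalnum():
                heads[i], labels[i] = root, "punct"
            elif low in _DET:
                j = next_content(i)
                heads[i], labels[i] = (j, "det") if j is not None else (root, "det")
            elif low in _ADP:
                j = next_content(i)
                heads[i], labels[i] = (j, "case") if j is not None else (root, "case")
            elif low in _AUX:
                heads[i], labels[i] = root, "cop" if i < root else "aux"
            elif low in _CCONJ:
                j = next_content(i)
                heads[i], labels[i] = (j, "cc") if j is not None else (root, "cc")
            elif i < root:
                # pre-root contents chain forward; the chain's last token is
                # the subject, so every attachment resolves toward the root
                j = next_content(i)
                if j is not None and j < root:
                    heads[i], labels[i] = j, "compound"
                else:
                    heads[i], labels[i] = root, "nsubj"
            else:
                # post-root contents attach backward (or to the root), which
                # keeps the output a tree: no forward/backward edge mix
                prev_adp = i > 0 and lows[i - 1] in _ADP
                prev_cc = i > 0 and lows[i - 1] in _CCONJ
                if prev_adp:
                    j = prev_content(i)
                    heads[i], labels[i] = (j, "nmod") if j is not None else (root, "obl")
                elif prev_cc:
                    j = prev_content(i)
                    heads[i], labels[i] = (j, "conj") if j is not None else (root, "conj")
                elif not entity_seen:
                    heads[i], labels[i] = root, "obj"
                    entity_seen = True
                else:
                    j = prev_content(i)
                    heads[i], labels[i] = (j, "compound") if j is not None else (root, "dep")
        edges = [DepEdge(h, i, labels[i]) for i, h in enumerate(heads) if h >= 0]
        return DepGraph(list(tokens), edges)
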