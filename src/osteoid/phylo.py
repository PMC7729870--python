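"""Maximum-parsimony tree building for aligned mtDNA sequences.

Fitch small parsimony scores a fixed unrooted topology: at each alignment
column, leaf states are base sets ({A},{C},{G},{T}; N and gaps act as the
full set, i.e. missing data), and a post-order pass counts one change
whenever the children's sets are disjoint.  Maximum parsimony seeks the
topology minimizing the total over columns — here either by exhaustive
enumeration of all (2n−5)!! unrooted binary topologies (n ≤ 9) or by
stepwise addition followed by nearest-neighbour-interchange (NNI)
hill-climbing for larger panels.

All tie-breaking is lexicographic on a canonical newick form (root placed
at the internal node adjacent to the alphabetically first leaf, subtrees
sorted), so exhaustive searches are reproducible without seeds.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from io import StringIO
from typing import Iterable, Iterator, Sequence

import numpy as np

from .haplogroup import MaskPolicy

__all__ = [
    "PanelRecord",
    "SequencePanel",
    "ParsimonyTree",
    "fitch_score",
    "mp_search",
    "mask_alignment",
]

_CODE = {"A": 1, "C": 2, "G": 4, "T": 8}
_FULL = 15  # N / gap / ambiguity: any base (missing data)


@dataclass(frozen=True)
class PanelRecord:
    id: str
    haplogroup: str
    sequence: str


@dataclass
class SequencePanel:
    """An aligned panel of mtDNA sequences (equal lengths, unique ids)."""

    records: list[PanelRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("empty panel")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids in panel")

    @property
    def alignment_length(self) -> int:
        return len(self.records[0].sequence)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, rec_id: str) -> PanelRecord:
        for r in self.records:
            if r.id == rec_id:
                return r
        raise KeyError(rec_id)

    def encoded(self) -> dict[str, np.ndarray]:
        """Per-taxon base-set bitmask arrays over alignment columns."""
        return {
            r.id: np.array(
                [_CODE.get(b, _FULL) for b in r.sequence.upper()], dtype=np.uint8
            )
            for r in self.records
        }

    @classmethod
    def from_fasta(cls, path) -> "SequencePanel":
        """Read an aligned FASTA; ids may carry a ``|haplogroup`` suffix."""
        from Bio import SeqIO

        records = []
        for rec in SeqIO.parse(str(path), "fasta"):
            rec_id, _, hap = rec.id.partition("|")
            records.append(PanelRecord(rec_id, hap, str(rec.seq).upper()))
        return cls(records)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                name = f"{r.id}|{r.haplogroup}" if r.haplogroup else r.id
                fh.write(f">{name}\n{r.sequence}\n")


@dataclass(frozen=True)
class ParsimonyTree:
    """An unrooted topology (canonical newick) with its parsimony score."""

    newick: str
    score: int
    n_taxa: int
    mode: str

    def to_dict(self) -> dict:
        return {"newick": self.newick, "score": self.score,
                "n_taxa": self.n_taxa, "mode": self.mode}


# ---------------------------------------------------------------------------
# internal unrooted-tree representation: adjacency over leaf names (str)
# and internal node ids (int)


class _Unrooted:
    __slots__ = ("adj", "_next")

    def __init__(self) -> None:
        self.adj: dict = {}
        self._next = 0

    @classmethod
    def star(cls, leaves: Sequence[str]) -> "_Unrooted":
        assert len(leaves) == 3
        t = cls()
        hub = t._new_internal()
        for leaf in leaves:
            t._connect(hub, leaf)
        return t

    def _new_internal(self) -> int:
        nid = self._next
        self._next += 1
        self.adj[nid] = set()
        return nid

    def _connect(self, u, v) -> None:
        self.adj.setdefault(u, set()).add(v)
        self.adj.setdefault(v, set()).add(u)

    def copy(self) -> "_Unrooted":
        t = _Unrooted()
        t.adj = {k: set(v) for k, v in self.adj.items()}
        t._next = self._next
        return t

    def edges(self) -> list[tuple]:
        seen, out = set(), []
        for u, nbrs in self.adj.items():
            for v in nbrs:
                key = frozenset((repr(u), repr(v)))
                if key not in seen:
                    seen.add(key)
                    out.append((u, v))
        return sorted(out, key=lambda e: (repr(e[0]), repr(e[1])))

    def insert_leaf(self, edge: tuple, leaf: str) -> None:
        u, v = edge
        w = self._new_internal()
        self.adj[u].discard(v)
        self.adj[v].discard(u)
        self._connect(u, w)
        self._connect(v, w)
        self._connect(w, leaf)

    def internal_edges(self) -> list[tuple[int, int]]:
        return [
            (u, v) for u, v in self.edges()
            if isinstance(u, int) and isinstance(v, int)
        ]

    def nni_neighbors(self) -> Iterator["_Unrooted"]:
        for u, v in self.internal_edges():
            a_side = sorted(self.adj[u] - {v}, key=repr)
            b_side = sorted(self.adj[v] - {u}, key=repr)
            # keep a_side[0] fixed; swapping a_side[1] with either b gives
            # the two distinct NNI rearrangements of this edge
            for b in b_side:
                t = self.copy()
                x = a_side[1]
                t.adj[u].discard(x); t.adj[x].discard(u)
                t.adj[v].discard(b); t.adj[b].discard(v)
                t._connect(u, b)
                t._connect(v, x)
                yield t

    def to_nested(self) -> tuple:
        """Rooted (trifurcating-root) nested-tuple view for scoring."""
        first_leaf = min(n for n in self.adj if isinstance(n, str))
        root = next(iter(self.adj[first_leaf]))

        def build(node, parent):
            if isinstance(node, str):
                return node
            return tuple(build(c, node) for c in sorted(self.adj[node] - {parent}, key=repr))

        return tuple(build(c, root) for c in sorted(self.adj[root], key=repr))

    def newick(self) -> str:
        """Canonical newick: rooted at the internal node adjacent to the
        alphabetically first leaf, subtrees sorted lexicographically."""
        first_leaf = min(n for n in self.adj if isinstance(n, str))
        root = next(iter(self.adj[first_leaf]))

        def render(node, parent) -> str:
            if isinstance(node, str):
                return node
            parts = sorted(render(c, node) for c in self.adj[node] - {parent})
            return "(" + ",".join(parts) + ")"

        parts = sorted(render(c, root) for c in self.adj[root])
        return "(" + ",".join(parts) + ");"


def _enumerate_topologies(taxa: Sequence[str]) -> Iterator[_Unrooted]:
    taxa = sorted(taxa)
    trees = [_Unrooted.star(taxa[:3])]
    for leaf in taxa[3:]:
        nxt = []
        for t in trees:
            for edge in t.edges():
                t2 = t.copy()
                t2.insert_leaf(edge, leaf)
                nxt.append(t2)
        trees = nxt
    return iter(trees)


def _parse_newick(s: str) -> tuple:
    from Bio import Phylo

    tree = Phylo.read(StringIO(s), "newick")

    def build(clade):
        if not clade.clades:
            return clade.name
        return tuple(build(c) for c in clade.clades)

    return build(tree.root)


def _fitch_nested(node, states: dict[str, np.ndarray]) -> tuple[np.ndarray, int]:
    if isinstance(node, str):
        if node not in states:
            raise ValueError(f"leaf {node!r} not present in panel")
        return states[node], 0
    if len(node) > 3:
        raise ValueError("tree must be binary (trifurcating root allowed)")
    acc, changes = _fitch_nested(node[0], states)
    for child in node[1:]:
        s, c = _fitch_nested(child, states)
        changes += c
        inter = acc & s
        disjoint = inter == 0
        changes += int(disjoint.sum())
        acc = np.where(disjoint, acc | s, inter)
    return acc, changes


def fitch_score(topology, panel: SequencePanel) -> int:
    """Minimum substitution count of a fixed topology over all columns.

    ``topology`` may be a newick string or a nested tuple of leaf ids;
    its leaf set must equal the panel's ids exactly.
    """
    if isinstance(topology, str):
        topology = _parse_newick(topology)
    leaves: set[str] = set()

    def collect(node):
        if isinstance(node, str):
            leaves.add(node)
        else:
            for c in node:
                collect(c)

    collect(topology)
    if leaves != set(panel.ids):
        raise ValueError(
            f"topology leaves {sorted(leaves)} != panel ids {sorted(panel.ids)}"
        )
    _, changes = _fitch_nested(topology, panel.encoded())
    return changes


def _score(tree: _Unrooted, states: dict[str, np.ndarray]) -> int:
    return _fitch_nested(tree.to_nested(), states)[1]


EXHAUSTIVE_MAX_TAXA = 9


def mp_search(
    panel: SequencePanel,
    mode: str = "exhaustive",
    seed: int | None = None,
    n_starts: int = 5,
) -> ParsimonyTree:
    """Search for a maximum-parsimony topology.

    ``exhaustive`` enumerates every unrooted binary topology (n ≤ 9;
    ties go to the lexicographically smallest canonical newick).
    ``nni`` runs ``n_starts`` stepwise-addition starts (addition orders
    drawn from ``seed``), each followed by best-improvement NNI
    hill-climbing, and keeps the best local optimum found.
    """
    n = len(panel)
    if n < 3:
        raise ValueError("need >= 3 taxa")
    states = panel.encoded()
    if mode == "exhaustive":
        if n > EXHAUSTIVE_MAX_TAXA:
            raise ValueError(
                f"exhaustive enumeration limited to {EXHAUSTIVE_MAX_TAXA} taxa "
                f"({n} given); use mode='nni'"
            )
        best_score, best_newick = None, None
        for t in _enumerate_topologies(panel.ids):
            s = _score(t, states)
            if best_score is None or s < best_score:
                best_score, best_newick = s, t.newick()
            elif s == best_score:
                best_newick = min(best_newick, t.newick())
        return ParsimonyTree(best_newick, best_score, n, mode)

    if mode != "nni":
        raise ValueError(f"unknown mode {mode!r}")

    rng = np.random.default_rng(seed)
    result = min(
        _stepwise_nni(panel, states, rng) for _ in range(n_starts)
    )
    return ParsimonyTree(result[1], result[0], n, mode)


def _stepwise_nni(
    panel: SequencePanel,
    states: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> tuple[int, str]:
    """One stepwise-addition start followed by best-improvement NNI."""
    order = [panel.ids[i] for i in rng.permutation(len(panel))]
    tree = _Unrooted.star(order[:3])
    for leaf in order[3:]:
        best = None
        for edge in tree.edges():
            t2 = tree.copy()
            t2.insert_leaf(edge, leaf)
            key = (_score(t2, states), t2.newick())
            if best is None or key < best[0]:
                best = (key, t2)
        tree = best[1]
    score = _score(tree, states)
    improved = True
    while improved:  # best-improvement hill climbing
        improved = False
        best = None
        for t2 in tree.nni_neighbors():
            key = (_score(t2, states), t2.newick())
            if best is None or key < best[0]:
                best = (key, t2)
        if best is not None and best[0][0] < score:
            score, tree, improved = best[0][0], best[1], True
    return score, tree.newick()


def mask_alignment(
    panel: SequencePanel,
    policy: MaskPolicy,
    ref_row: str = "rCRS",
) -> SequencePanel:
    """Gap out alignment columns at masked reference positions.

    Columns are mapped to reference coordinates through the designated
    reference row (gap-aware cumulative position); insertion columns
    (reference gap) carry no coordinate and are left untouched.  Mask
    exceptions (e.g. np 16189) are retained.
    """
    if not policy.excluded_ranges and not policy.excluded_points:
        return panel
    try:
        ref_seq = panel[ref_row].sequence
    except KeyError:
        raise ValueError(
            f"mask_alignment needs reference row {ref_row!r} in the panel"
        ) from None
    mask_cols = []
    pos = 0
    for col, base in enumerate(ref_seq):
        if base != "-":
            pos += 1
            if policy.covers(pos):
                mask_cols.append(col)
    if not mask_cols:
        return panel
    cols = set(mask_cols)
    records = [
        PanelRecord(
            r.id,
            r.haplogroup,
            "".join("-" if i in cols else b for i, b in enumerate(r.sequence)),
        )
        for r in panel.records
    ]
    return SequencePanel(records)
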