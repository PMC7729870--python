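"""mtDNA haplogroup assignment against a defining-variant tree.

The human mitochondrial phylogeny (PhyloTree-style) is a rooted tree
whose edges carry defining variants relative to the rCRS coordinate
system.  A consensus sequence is reduced to its substitution variant set
(hypervariable stretches masked), and every node is scored by how well
the variants accumulated on its root path explain the observed set.

Scoring uses the Kulczynski measure,

    score = ½ · (found/expected + found/(found + private)),

where *expected* counts the path's defining variants at covered
positions, *found* those actually observed, and *private* the observed
variants not on the path.  Uncovered positions shrink *expected* rather
than count against the sample — appropriate for ancient consensus
sequences with N-gaps.  Ties break toward the deeper node, then
lexicographically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

__all__ = [
    "Variant",
    "MaskPolicy",
    "HaplogroupNode",
    "HaplogroupTree",
    "HaplogroupCall",
    "RCRS_LENGTH",
    "default_mask_policy",
    "call_variants",
    "apply_mask",
    "assign_haplogroup",
]

RCRS_LENGTH = 16569  # bp, rCRS coordinate standard

_BASES = set("ACGT")


class Variant(NamedTuple):
    """A substitution on rCRS coordinates, e.g. Variant(16189, 'T', 'C')."""

    position: int
    ref_base: str
    alt_base: str

    def __str__(self) -> str:
        return f"{self.ref_base}{self.position}{self.alt_base}"


def _check_variant(v: Variant, max_position: int = RCRS_LENGTH) -> None:
    if not 1 <= v.position <= max_position:
        raise ValueError(f"variant position {v.position} outside [1, {max_position}]")
    if v.ref_base == v.alt_base:
        raise ValueError(f"variant {v} has ref == alt")


@dataclass(frozen=True)
class MaskPolicy:
    """Hypervariable sites disregarded when comparing mtDNA sequences."""

    excluded_ranges: tuple[tuple[int, int], ...] = ()
    excluded_points: tuple[int, ...] = ()
    exceptions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        for np_ in self.exceptions:
            if not self.covers(np_, ignore_exceptions=True):
                raise ValueError(f"exception np {np_} is not inside any excluded range/point")

    def covers(self, position: int, ignore_exceptions: bool = False) -> bool:
        if not ignore_exceptions and position in self.exceptions:
            return False
        if position in self.excluded_points:
            return True
        return any(lo <= position <= hi for lo, hi in self.excluded_ranges)

    @classmethod
    def from_json(cls, path) -> "MaskPolicy":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            tuple(tuple(r) for r in d.get("excluded_ranges", ())),
            tuple(d.get("excluded_points", ())),
            tuple(d.get("exceptions", ())),
        )


def default_mask_policy() -> MaskPolicy:
    """Standard control-region mask: A/C stretch length polymorphisms at
    nps 303–315, 522–523 and 16180–16193 (keeping 16189, a haplogroup-B
    defining site) plus the hypervariable point 16519."""
    return MaskPolicy(
        excluded_ranges=((303, 315), (522, 523), (16180, 16193)),
        excluded_points=(16519,),
        exceptions=(16189,),
    )


def call_variants(
    consensus: str,
    reference: str,
) -> tuple[list[Variant], set[int]]:
    """Substitution variants of a consensus versus an equal-length reference.

    Returns (variants, uncovered positions).  N (or non-ACGT) consensus
    positions are recorded as uncovered, never as variants; indels are
    out of scope (sequences must be pre-aligned, equal length).
    """
    if len(consensus) != len(reference):
        raise ValueError(
            f"consensus length {len(consensus)} != reference length "
            f"{len(reference)}; sequences must be pre-aligned"
        )
    variants: list[Variant] = []
    uncovered: set[int] = set()
    for i, (c, r) in enumerate(zip(consensus.upper(), reference.upper()), start=1):
        if c not in _BASES:
            uncovered.add(i)
        elif r in _BASES and c != r:
            variants.append(Variant(i, r, c))
    return variants, uncovered


def apply_mask(variants: Iterable[Variant], policy: MaskPolicy) -> list[Variant]:
    """Drop variants at masked positions; idempotent and order-preserving."""
    return [v for v in variants if not policy.covers(v.position)]


@dataclass
class HaplogroupNode:
    label: str
    variants: list[Variant]  # defining variants on the edge into this node
    children: list["HaplogroupNode"] = field(default_factory=list)
    parent: "HaplogroupNode | None" = None
    depth: int = 0


class HaplogroupTree:
    """Rooted defining-variant tree with unique node labels."""

    def __init__(self, root: HaplogroupNode, max_position: int = RCRS_LENGTH):
        self.root = root
        self.nodes: dict[str, HaplogroupNode] = {}
        stack = [(root, None, 0)]
        while stack:
            node, parent, depth = stack.pop()
            if node.label in self.nodes:
                raise ValueError(f"duplicate haplogroup label {node.label!r}")
            for v in node.variants:
                _check_variant(v, max_position)
            node.parent, node.depth = parent, depth
            self.nodes[node.label] = node
            for ch in node.children:
                stack.append((ch, node, depth + 1))

    def __contains__(self, label: str) -> bool:
        return label in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def labels(self) -> list[str]:
        return sorted(self.nodes)

    def path_variants(self, label: str) -> list[Variant]:
        """Defining variants accumulated root → node (root's own list included)."""
        if label not in self.nodes:
            raise KeyError(f"unknown haplogroup {label!r}")
        chain = []
        node = self.nodes[label]
        while node is not None:
            chain.append(node)
            node = node.parent
        out: list[Variant] = []
        for node in reversed(chain):
            out.extend(node.variants)
        return out

    @classmethod
    def from_json(cls, path, max_position: int = RCRS_LENGTH) -> "HaplogroupTree":
        """Import a PhyloTree-style tree serialized as nested JSON
        ``{"label": ..., "variants": ["C7028T", ...], "children": [...]}``.

        Variant strings carrying indel notation (``.``, ``d``) or
        back-mutation marks (``!``) are skipped with a warning — only
        substitutions are scored.
        """
        import warnings

        with open(path) as fh:
            d = json.load(fh)

        def build(obj) -> HaplogroupNode:
            variants = []
            for s in obj.get("variants", []):
                v = _parse_variant(s)
                if v is None:
                    warnings.warn(f"skipping non-substitution variant {s!r}")
                else:
                    variants.append(v)
            return HaplogroupNode(
                obj["label"], variants, [build(c) for c in obj.get("children", [])]
            )

        return cls(build(d), max_position)

    def to_json(self, path) -> None:
        def dump(node: HaplogroupNode) -> dict:
            return {
                "label": node.label,
                "variants": [str(v) for v in node.variants],
                "children": [dump(c) for c in node.children],
            }

        with open(path, "w") as fh:
            json.dump(dump(self.root), fh, indent=1)


def _parse_variant(s: str):
    s = s.strip()
    if "!" in s or "." in s or s.endswith("d") or not s:
        return None
    ref, alt = s[0].upper(), s[-1].upper()
    if ref not in _BASES or alt not in _BASES:
        return None
    try:
        pos = int(s[1:-1])
    except ValueError:
        return None
    return Variant(pos, ref, alt)


@dataclass(frozen=True)
class HaplogroupCall:
    best_label: str
    score: float
    expected: int
    found: int
    private: tuple[Variant, ...]
    runner_ups: tuple[tuple[str, float], ...] = ()

    def to_dict(self) -> dict:
        return {
            "best_label": self.best_label,
            "score": self.score,
            "expected": self.expected,
            "found": self.found,
            "private": [str(v) for v in self.private],
            "runner_ups": [list(r) for r in self.runner_ups],
        }


def assign_haplogroup(
    variants: Sequence[Variant],
    uncovered: set[int],
    tree: HaplogroupTree,
    n_runner_ups: int = 5,
) -> HaplogroupCall:
    """Score every tree node against an observed variant set and return the best.

    For each node the root-path defining variants are collected, those at
    uncovered positions dropped from *expected*, and the Kulczynski score
    computed.  Argmax wins; ties break to the deeper node, then to the
    lexicographically smaller label.
    """
    if len(tree) == 0:
        raise ValueError("empty haplogroup tree")
    observed = set(variants)
    scored: list[tuple[float, int, str, HaplogroupCall]] = []
    for label in tree.labels():
        path = [v for v in tree.path_variants(label) if v.position not in uncovered]
        expected = len(path)
        found = sum(1 for v in path if v in observed)
        private = tuple(sorted(v for v in observed if v not in set(path)))
        r_exp = found / expected if expected else 1.0
        r_obs = found / (found + len(private)) if (found + len(private)) else 1.0
        score = 0.5 * (r_exp + r_obs)
        call = HaplogroupCall(label, score, expected, found, private)
        scored.append((score, tree.nodes[label].depth, label, call))
    # best score, then deeper, then lexicographically smaller label
    scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
    best = scored[0][3]
    runners = tuple((t[2], t[0]) for t in scored[1 : 1 + n_runner_ups])
    return HaplogroupCall(
        best.best_label, best.score, best.expected, best.found, best.private, runners
    )
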