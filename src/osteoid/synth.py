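"""Synthetic inputs for every pipeline stage.

Generators for: a random mtDNA-like reference, a fictional ~25-node
defining-variant haplogroup tree consistent with that reference,
haplotypes produced by walking the tree, short ancient-style read
fragments with parameterized terminal deamination (emitted as plain SAM
plus a per-read truth log), calibration curves with closed-form
posteriors, and bivariate-normal isotope reference clusters.  Everything
is a deterministic function of its parameters and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .haplogroup import (
    HaplogroupNode,
    HaplogroupTree,
    MaskPolicy,
    Variant,
    default_mask_policy,
)
from .isotopes import ReferenceCluster
from .radiocarbon import CalibrationCurve

__all__ = [
    "DamageModel",
    "ReadSimSpec",
    "random_reference",
    "build_fixture_tree",
    "simulate_haplotype",
    "simulate_reads",
    "synth_curve",
    "synth_isotope_cluster",
]

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def random_reference(length: int = 16569, seed: int = 0) -> str:
    """A uniform-random A/C/G/T reference sequence of the given length."""
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(_BASES), size=length))


# ---------------------------------------------------------------------------
# haplogroup fixtures and haplotypes

#: label -> (parent, number of defining variants on the edge in).
#: A fictional mini-phylogeny shaped like the human mtDNA tree (macro-
#: haplogroups L3/M/N down to fine H1e2b-style tips); variants are drawn
#: per-reference, so this is synthetic test scaffolding, not PhyloTree.
_FIXTURE_SHAPE: list[tuple[str, str | None, int]] = [
    ("ROOT", None, 0),
    ("L3", "ROOT", 2),
    ("M", "L3", 3),
    ("D", "M", 2),
    ("D4", "D", 2),
    ("G", "M", 2),
    ("N", "L3", 2),
    ("A", "N", 3),
    ("R", "N", 1),
    ("B", "R", 2),
    ("B2", "B", 2),
    ("B2a", "B2", 2),
    ("F", "R", 2),
    ("R0", "R", 1),
    ("HV", "R0", 2),
    ("V", "HV", 2),
    ("H", "HV", 2),
    ("H1", "H", 1),
    ("H1e", "H1", 2),
    ("H1e2", "H1e", 1),
    ("H1e2b", "H1e2", 2),
    ("H2", "H", 2),
    ("J", "R", 3),
    ("T", "R", 3),
    ("X", "N", 2),
]


def build_fixture_tree(
    reference: str,
    seed: int = 17,
    mask: MaskPolicy | None = None,
) -> HaplogroupTree:
    """A small fictional haplogroup tree with defining variants valid on
    ``reference`` (synthetic stand-in for a PhyloTree-style tree).

    Defining positions are distinct across the whole tree and avoid the
    mask (default: the standard hypervariable-site mask), so that every
    node is recoverable from a clean haplotype.
    """
    mask = mask if mask is not None else default_mask_policy()
    rng = np.random.default_rng(seed)
    usable = [p for p in range(1, len(reference) + 1) if not mask.covers(p)]
    n_needed = sum(k for _, _, k in _FIXTURE_SHAPE)
    positions = iter(sorted(rng.choice(usable, size=n_needed, replace=False)))
    nodes: dict[str, HaplogroupNode] = {}
    for label, parent, k in _FIXTURE_SHAPE:
        variants = []
        for _ in range(k):
            pos = int(next(positions))
            ref_base = reference[pos - 1]
            alt = str(rng.choice([b for b in _BASES if b != ref_base]))
            variants.append(Variant(pos, ref_base, alt))
        node = HaplogroupNode(label, variants)
        nodes[label] = node
        if parent is not None:
            nodes[parent].children.append(node)
    return HaplogroupTree(nodes["ROOT"], max_position=len(reference))


def simulate_haplotype(
    tree: HaplogroupTree,
    node_label: str,
    reference: str,
    n_private: int = 0,
    seed: int = 0,
    mask: MaskPolicy | None = None,
) -> str:
    """Apply a node's root-path defining variants to the reference, plus
    ``n_private`` random substitutions away from defining/masked sites."""
    mask = mask if mask is not None else default_mask_policy()
    path = tree.path_variants(node_label)  # raises KeyError for unknown label
    seq = list(reference.upper())
    for v in path:
        if seq[v.position - 1] != v.ref_base:
            raise ValueError(f"defining variant {v} inconsistent with reference")
        seq[v.position - 1] = v.alt_base
    if n_private:
        rng = np.random.default_rng(seed)
        defining = {v.position for lbl in tree.labels() for v in tree.path_variants(lbl)}
        free = [
            p for p in range(1, len(reference) + 1)
            if p not in defining and not mask.covers(p)
        ]
        for pos in rng.choice(free, size=n_private, replace=False):
            cur = seq[pos - 1]
            seq[pos - 1] = str(rng.choice([b for b in _BASES if b != cur]))
    return "".join(seq)


# ---------------------------------------------------------------------------
# ancient-read simulation


@dataclass(frozen=True)
class DamageModel:
    """Geometric-decay terminal deamination plus a flat base-error rate.

    Damage probability at read offset k (1-based from the relevant end)
    is ``terminal_rate * decay**(k-1)``.  Double-stranded libraries show
    C→T at 5' and G→A at 3'; single-stranded show C→T at both ends.
    """

    terminal_rate: float = 0.0
    decay: float = 0.5
    base_error: float = 0.0
    library_type: str = "double"

    def __post_init__(self) -> None:
        if not 0.0 <= self.terminal_rate <= 1.0:
            raise ValueError("terminal_rate must be in [0, 1]")
        if not 0.0 < self.decay <= 1.0:
            raise ValueError("decay must be in (0, 1]")
        if not 0.0 <= self.base_error <= 1.0:
            raise ValueError("base_error must be in [0, 1]")
        if self.library_type not in ("single", "double"):
            raise ValueError("library_type must be 'single' or 'double'")

    def rate_at(self, offset: int) -> float:
        return self.terminal_rate * self.decay ** (offset - 1)


@dataclass(frozen=True)
class ReadSimSpec:
    """Parameters of one simulated ancient-read run.

    Defaults emulate typical ancient-DNA fragment sizes (mean 60 bp,
    sd 15 bp, minimum 25 bp).
    """

    reference: str
    n_reads: int
    seed: int = 0
    fragment_length_mean: float = 60.0
    fragment_length_sd: float = 15.0
    min_length: int = 25
    reference_name: str = "ref"
    damage: DamageModel = field(default_factory=DamageModel)

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if self.min_length < 20:
            raise ValueError("min_length must be >= 20")
        if len(self.reference) < self.min_length:
            raise ValueError("reference shorter than min_length")


def simulate_reads(spec: ReadSimSpec) -> tuple[str, list[dict]]:
    """Simulate aligned ancient reads; returns (SAM text, truth log).

    Fragments have truncated-normal lengths at uniform start positions
    and uniform strand; damage is applied in read orientation, then flat
    base errors; the SAM stores sequences in reference orientation with
    an all-match CIGAR and MAPQ 60.  The truth log lists every injected
    event as {read, kind, end, offset, ref_pos}.
    """
    rng = np.random.default_rng(spec.seed)
    ref = spec.reference.upper()
    L = len(ref)
    dmg = spec.damage
    max_len = min(L, int(spec.fragment_length_mean + 6 * spec.fragment_length_sd))
    lines = [
        "@HD\tVN:1.6\tSO:unsorted",
        f"@SQ\tSN:{spec.reference_name}\tLN:{L}",
    ]
    truth: list[dict] = []
    for i in range(spec.n_reads):
        while True:
            flen = int(round(rng.normal(spec.fragment_length_mean,
                                        spec.fragment_length_sd)))
            if spec.min_length <= flen <= max_len:
                break
        start = int(rng.integers(0, L - flen + 1))  # 0-based
        reverse = bool(rng.integers(0, 2))
        fragment = ref[start : start + flen]
        read = list(fragment if not reverse else _revcomp(fragment))
        qname = f"sim{i:06d}"

        def ref_pos_of(j: int) -> int:  # 1-based reference position of read index j
            return start + flen - j if reverse else start + 1 + j

        # terminal deamination, read orientation
        for j in range(flen):
            off5, off3 = j + 1, flen - j
            base = read[j]
            if dmg.library_type == "double":
                if base == "C" and rng.random() < dmg.rate_at(off5):
                    read[j] = "T"
                    truth.append(dict(read=qname, kind="CT", end="5p",
                                      offset=off5, ref_pos=ref_pos_of(j)))
                elif base == "G" and rng.random() < dmg.rate_at(off3):
                    read[j] = "A"
                    truth.append(dict(read=qname, kind="GA", end="3p",
                                      offset=off3, ref_pos=ref_pos_of(j)))
            else:  # single-stranded: C→T from both ends
                if base == "C":
                    p = 1 - (1 - dmg.rate_at(off5)) * (1 - dmg.rate_at(off3))
                    if rng.random() < p:
                        read[j] = "T"
                        end = "5p" if off5 <= off3 else "3p"
                        truth.append(dict(read=qname, kind="CT", end=end,
                                          offset=min(off5, off3),
                                          ref_pos=ref_pos_of(j)))
        # flat sequencing error
        if dmg.base_error > 0:
            for j in range(flen):
                if rng.random() < dmg.base_error:
                    cur = read[j]
                    read[j] = str(rng.choice([b for b in _BASES if b != cur]))
                    truth.append(dict(read=qname, kind="err", end=None,
                                      offset=j + 1, ref_pos=ref_pos_of(j)))
        seq = "".join(read)
        if reverse:
            seq = _revcomp(seq)  # SAM stores reference orientation
        flag = 16 if reverse else 0
        lines.append(
            f"{qname}\t{flag}\t{spec.reference_name}\t{start + 1}\t60\t{flen}M"
            f"\t*\t0\t0\t{seq}\t{'I' * flen}"
        )
    return "\n".join(lines) + "\n", truth


# ---------------------------------------------------------------------------
# calibration curves and isotope clusters


def synth_curve(
    kind: str,
    domain: tuple[float, float],
    knot_step: float = 5.0,
    sigma: float = 0.0,
    c: float = 0.0,
    a: float = 0.0,
    b: float = 1.0,
    amplitude: float = 0.0,
    period: float = 200.0,
    name: str | None = None,
) -> CalibrationCurve:
    """A synthetic calibration curve with a closed-form shape.

    ``constant``: μ(θ) = c.  ``linear``: μ(θ) = a + b·θ (b = 1, a = 0
    gives the identity curve whose posterior is exactly Gaussian).
    ``wiggle``: linear plus ``amplitude·sin(2πθ/period)``, useful for
    constructing posteriors with a known number of modes.
    """
    lo, hi = domain
    if not lo < hi:
        raise ValueError("empty domain")
    theta = np.arange(lo, hi + knot_step / 2, knot_step, dtype=float)
    if kind == "constant":
        mu = np.full_like(theta, float(c))
    elif kind == "linear":
        mu = a + b * theta
    elif kind == "wiggle":
        mu = a + b * theta + amplitude * np.sin(2 * np.pi * theta / period)
    else:
        raise ValueError(f"unknown curve kind {kind!r}")
    return CalibrationCurve(name or f"synthetic-{kind}", theta, mu,
                            np.full_like(theta, float(sigma)))


def synth_isotope_cluster(
    n: int,
    mean: tuple[float, float],
    covariance,
    seed: int = 0,
    label: str = "synthetic",
) -> ReferenceCluster:
    """Bivariate-normal (δ13C, δ15N) reference cluster, deterministic in seed."""
    cov = np.asarray(covariance, dtype=float)
    if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
        raise ValueError("covariance must be symmetric 2x2")
    if np.any(np.linalg.eigvalsh(cov) <= 0):
        raise ValueError("covariance must be positive-definite")
    rng = np.random.default_rng(seed)
    members = rng.multivariate_normal(np.asarray(mean, dtype=float), cov, size=n,
                                      method="cholesky")
    return ReferenceCluster(label, members)
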