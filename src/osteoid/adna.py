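"""Ancient-DNA read processing: filtering, damage profiling, consensus.

Post-mortem cytosine deamination produces C→T substitutions (and, on the
complementary strand, G→A) concentrated at the ends of ancient DNA
fragments.  An elevated terminal substitution rate relative to the read
interior is the standard authentication signal for ancient sequence data.

The workflow mirrors standard aDNA practice: damage is profiled on raw
mapped reads, then terminal bases are clipped before pileup and consensus
so that damage-induced miscalls do not enter the consensus sequence.
Reads arrive as plain SAM against a single mtDNA reference; coordinates
are 1-based inclusive and the reference is treated as linear.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pysam

__all__ = [
    "AlignedRead",
    "PileupColumn",
    "DamageProfile",
    "CoverageStats",
    "AuthenticationResult",
    "read_sam",
    "filter_reads",
    "damage_profile",
    "authenticate",
    "pileup",
    "coverage_stats",
    "consensus",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_MAPQ_MIN = 30
DEFAULT_CLIP_BASES = 2
DEFAULT_MIN_DEPTH = 2
DEFAULT_MIN_FRACTION = 0.7


@dataclass(frozen=True)
class AlignedRead:
    """One aligned read after CIGAR resolution.

    ``aligned_pairs`` holds (1-based reference position, read base) for
    match/mismatch columns only, in reference order; bases are stored in
    reference-forward orientation as in SAM.
    """

    read_id: str
    ref_start: int
    strand: str  # '+' or '-'
    mapq: int
    aligned_pairs: tuple[tuple[int, str], ...]
    clipped: bool = False

    def oriented_pairs(self) -> tuple[tuple[int, str], ...]:
        """Pairs ordered 5'→3' of the sequenced molecule, bases in read
        orientation (reverse-strand reads complemented and reversed)."""
        if self.strand == "+":
            return self.aligned_pairs
        return tuple(
            (pos, base.translate(_COMPLEMENT))
            for pos, base in reversed(self.aligned_pairs)
        )


@dataclass
class PileupColumn:
    ref_pos: int  # 1-based
    ref_base: str
    counts: dict[str, int]

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass
class CoverageStats:
    reference_length: int
    breadth_pct: float  # % positions with depth >= floor, 1 decimal
    mean_depth: float
    depth_floor: int = 1


@dataclass
class DamageProfile:
    """Per-offset terminal substitution rates pooled over reads.

    ``rates[(end, cls)]`` maps ('5p'|'3p', 'CT'|'GA') to an array over
    offsets 1..max_offset; entries with zero opportunities are NaN
    (undefined), never silently 0.
    """

    max_offset: int
    hits: dict[tuple[str, str], np.ndarray]
    opportunities: dict[tuple[str, str], np.ndarray]

    @property
    def rates(self) -> dict[tuple[str, str], np.ndarray]:
        out = {}
        for key, h in self.hits.items():
            opp = self.opportunities[key]
            with np.errstate(invalid="ignore", divide="ignore"):
                out[key] = np.where(opp > 0, h / np.maximum(opp, 1), np.nan)
            out[key][opp == 0] = np.nan
        return out

    def rate(self, end: str, cls: str, offset: int) -> float:
        return float(self.rates[(end, cls)][offset - 1])

    def to_table(self):
        """Long-form table (offset, end, class, hits, opportunities, rate)."""
        import pandas as pd

        rows = []
        rates = self.rates
        for (end, cls), h in sorted(self.hits.items()):
            opp = self.opportunities[(end, cls)]
            for k in range(self.max_offset):
                rows.append(
                    dict(offset=k + 1, end=end, substitution=cls,
                         hits=int(h[k]), opportunities=int(opp[k]),
                         rate=rates[(end, cls)][k])
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class AuthenticationResult:
    authentic: bool | None  # None = inconclusive
    summary: str
    terminal_rates: dict
    interior_rates: dict


def read_sam(path) -> list[AlignedRead]:
    """Load mapped records from a plain SAM file against a single reference."""
    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        if fh.nreferences > 1:
            raise ValueError(f"{path}: expected a single reference, got {fh.nreferences}")
        for rec in fh:
            if rec.is_unmapped or rec.query_sequence is None:
                reads.append(
                    AlignedRead(rec.query_name, 0, "+", rec.mapping_quality, ())
                )
                continue
            seq = rec.query_sequence
            pairs = tuple(
                (rpos + 1, seq[qpos])
                for qpos, rpos in rec.get_aligned_pairs(matches_only=True)
            )
            reads.append(
                AlignedRead(
                    read_id=rec.query_name,
                    ref_start=rec.reference_start + 1,
                    strand="-" if rec.is_reverse else "+",
                    mapq=rec.mapping_quality,
                    aligned_pairs=pairs,
                )
            )
    return reads


def filter_reads(
    reads: Iterable[AlignedRead],
    mapq_min: int = DEFAULT_MAPQ_MIN,
    clip_bases: int = DEFAULT_CLIP_BASES,
    exclude_ids: set[str] | None = None,
) -> list[AlignedRead]:
    """Drop unmapped/low-MAPQ/excluded reads and mask terminal bases.

    ``exclude_ids`` is the pluggable hook for external contaminant
    screens (e.g. BLASTN hits to non-human genomes, numt matches): any
    read whose id appears there is removed.  Idempotent: already-clipped
    reads are not clipped again.
    """
    exclude_ids = exclude_ids or set()
    out = []
    for r in reads:
        if not r.aligned_pairs or r.mapq < mapq_min or r.read_id in exclude_ids:
            continue
        if clip_bases > 0 and not r.clipped:
            pairs = r.aligned_pairs[clip_bases:len(r.aligned_pairs) - clip_bases]
            if not pairs:
                continue
            r = replace(r, aligned_pairs=pairs, clipped=True)
        out.append(r)
    return out


def damage_profile(
    reads: Sequence[AlignedRead],
    reference: str,
    max_offset: int = 25,
) -> DamageProfile:
    """Terminal C→T and G→A substitution rates by offset from each read end.

    Must run on un-clipped reads: clipping removes exactly the positions
    the profile measures.  Reverse-strand reads are complemented and
    reversed so offsets count along the sequenced molecule 5'→3'.
    """
    reads = [r for r in reads if r.aligned_pairs]
    if not reads:
        raise ValueError("damage profile undefined for an empty read set")
    keys = [(e, c) for e in ("5p", "3p") for c in ("CT", "GA")]
    hits = {k: np.zeros(max_offset) for k in keys}
    opps = {k: np.zeros(max_offset) for k in keys}
    ref = reference.upper()
    for r in reads:
        if r.clipped:
            raise ValueError("damage_profile requires un-clipped reads")
        pairs = r.oriented_pairs()
        comp = r.strand == "-"
        n = len(pairs)
        for end, indexed in (("5p", pairs[:max_offset]),
                             ("3p", pairs[::-1][:max_offset])):
            for k, (pos, base) in enumerate(indexed):
                rb = ref[pos - 1]
                if comp:
                    rb = rb.translate(_COMPLEMENT)
                if rb == "C":
                    opps[(end, "CT")][k] += 1
                    if base == "T":
                        hits[(end, "CT")][k] += 1
                elif rb == "G":
                    opps[(end, "GA")][k] += 1
                    if base == "A":
                        hits[(end, "GA")][k] += 1
    return DamageProfile(max_offset, hits, opps)


def authenticate(
    profile: DamageProfile,
    library_type: str = "double",
    terminal_offsets: range = range(1, 3),
    interior_offsets: range = range(11, 26),
    min_ratio: float = 3.0,
    min_opportunities: int = 100,
    pseudo_rate: float = 0.005,
) -> AuthenticationResult:
    """Decide whether a damage profile shows the ancient-DNA signature.

    Double-stranded libraries show C→T at the 5' end and G→A at the 3'
    end; single-stranded libraries show C→T at both ends.  The read is
    judged authentic when the mean terminal rate is at least ``min_ratio``
    times the mean interior rate (floored at ``pseudo_rate``) at BOTH
    ends.  Too few opportunities at any compared cell → inconclusive.
    """
    if library_type == "double":
        checks = [("5p", "CT"), ("3p", "GA")]
    elif library_type == "single":
        checks = [("5p", "CT"), ("3p", "CT")]
    else:
        raise ValueError(f"unknown library_type {library_type!r}")

    def _mean_rate(end: str, cls: str, offsets: range) -> tuple[float, float]:
        idx = [k - 1 for k in offsets if k <= profile.max_offset]
        h = profile.hits[(end, cls)][idx].sum()
        o = profile.opportunities[(end, cls)][idx].sum()
        return (h / o if o > 0 else np.nan), o

    term, inter, lines, verdicts = {}, {}, [], []
    conclusive = True
    for end, cls in checks:
        t_rate, t_opp = _mean_rate(end, cls, terminal_offsets)
        i_rate, i_opp = _mean_rate(end, cls, interior_offsets)
        term[(end, cls)] = t_rate
        inter[(end, cls)] = i_rate
        if t_opp < min_opportunities or i_opp < min_opportunities:
            conclusive = False
            lines.append(f"{end} {cls}: insufficient opportunities "
                         f"(terminal {t_opp:.0f}, interior {i_opp:.0f})")
            continue
        ok = t_rate >= min_ratio * max(i_rate, pseudo_rate)
        verdicts.append(ok)
        lines.append(f"{end} {cls}: terminal {t_rate:.4f} vs interior {i_rate:.4f} "
                     f"→ {'elevated' if ok else 'not elevated'}")
    if not conclusive:
        return AuthenticationResult(None, "inconclusive: " + "; ".join(lines), term, inter)
    authentic = all(verdicts)
    verdict = "authentic ancient damage pattern" if authentic else "no ancient damage pattern"
    return AuthenticationResult(authentic, verdict + " — " + "; ".join(lines), term, inter)


def pileup(reads: Iterable[AlignedRead], reference: str) -> list[PileupColumn]:
    """Per-position base counts over all aligned pairs (1-based positions)."""
    ref = reference.upper()
    counters: list[Counter] = [Counter() for _ in ref]
    for r in reads:
        for pos, base in r.aligned_pairs:
            counters[pos - 1][base.upper()] += 1
    return [
        PileupColumn(i + 1, ref[i], dict(counters[i])) for i in range(len(ref))
    ]


def coverage_stats(
    columns: Sequence[PileupColumn],
    reference_length: int,
    depth_floor: int = 1,
) -> CoverageStats:
    """Breadth (% positions at or above depth_floor, 1 decimal) and mean depth."""
    if reference_length <= 0:
        raise ValueError("reference_length must be positive")
    depths = np.array([c.depth for c in columns])
    covered = int((depths >= depth_floor).sum())
    breadth = round(100.0 * covered / reference_length, 1)
    return CoverageStats(reference_length, breadth, depths.sum() / reference_length,
                         depth_floor)


def consensus(
    columns: Sequence[PileupColumn],
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> str:
    """Majority-rule substitution consensus; uncalled sites emit N.

    A base is called when depth >= min_depth and the modal base's
    fraction >= min_fraction; ties between modal bases emit N.
    """
    out = []
    for col in columns:
        depth = col.depth
        if depth < min_depth or not col.counts:
            out.append("N")
            continue
        ranked = sorted(col.counts.items(), key=lambda kv: -kv[1])
        base, count = ranked[0]
        if len(ranked) > 1 and ranked[1][1] == count:
            out.append("N")  # tie
        elif count / depth >= min_fraction and base in "ACGT":
            out.append(base)
        else:
            out.append("N")
    return "".join(out)
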