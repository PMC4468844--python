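"""Per-cluster amplicon grouping, filtering and consensus calling.

Within one barcode cluster, reads are first assigned to target regions
by matching the read-2 prefix against the target-specific primers
(mismatch tolerant), under-supported groups and clusters are dropped,
and each target group is sub-clustered by sequence content.  The
dominant variant group per target yields an amplicon consensus, and the
cluster is labelled monoclonally amplified when the dominant group
holds at least ``dominant_threshold`` of each present target's reads.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .barcodes import hamming_distance, iterative_greedy_cluster
from .errors import ConfigurationError
from .util import ALPHABET

__all__ = [
    "VariantGroup",
    "TargetGroup",
    "AmpliconConsensus",
    "FilterReport",
    "validate_primers",
    "assign_reads_to_targets",
    "filter_clusters",
    "subcluster_reads",
    "call_consensus",
    "classify_amplification_clonality",
]


@dataclass
class VariantGroup:
    """One sequence variant within a target group."""

    representative: str
    reads: list[str]

    @property
    def size(self) -> int:
        return len(self.reads)


@dataclass
class TargetGroup:
    cluster_id: str
    target_id: str
    reads: list[str]
    variant_groups: list[VariantGroup] = field(default_factory=list)


@dataclass(frozen=True)
class AmpliconConsensus:
    cluster_id: str
    target_id: str
    consensus: str
    support: int
    dominant_fraction: float


@dataclass
class FilterReport:
    n_target_groups_dropped: int = 0
    n_clusters_dropped: int = 0
    n_reads_dropped: int = 0


def validate_primers(
    target_primers: Mapping[str, str], max_primer_mismatch: int = 2
) -> None:
    """Reject primer sets that cannot assign reads unambiguously."""
    items = list(target_primers.items())
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            (t1, p1), (t2, p2) = items[i], items[j]
            if len(p1) != len(p2):
                continue  # different lengths are trivially distinguishable
            if hamming_distance(p1, p2) <= 2 * max_primer_mismatch:
                raise ConfigurationError(
                    f"primers for {t1} and {t2} are too similar to "
                    f"distinguish at {max_primer_mismatch} mismatches"
                )


def assign_reads_to_targets(
    reads: Sequence[tuple[str, str]],
    target_primers: Mapping[str, str],
    max_primer_mismatch: int = 2,
) -> tuple[dict[str, list[tuple[str, str]]], list[str]]:
    """Assign read-2 sequences to targets by their primer prefix.

    ``reads`` are ``(read_id, seq2)`` pairs.  A read goes to the unique
    target whose primer matches the read prefix within
    ``max_primer_mismatch``; the returned sequences have the primer
    trimmed off.  Returns ``(target_id -> [(read_id, trimmed_seq)],
    unassigned read ids)``.
    """
    validate_primers(target_primers, max_primer_mismatch)
    out: dict[str, list[tuple[str, str]]] = {t: [] for t in target_primers}
    unassigned: list[str] = []
    for read_id, seq in reads:
        hit = None
        for tid, primer in target_primers.items():
            prefix = seq[: len(primer)]
            if len(prefix) < len(primer):
                continue
            if hamming_distance(prefix, primer) <= max_primer_mismatch:
                hit = tid
                break  # primer validation makes the hit unique
        if hit is None:
            unassigned.append(read_id)
        else:
            out[hit].append((read_id, seq[len(target_primers[hit]) :]))
    return out, unassigned


def filter_clusters(
    groups: Mapping[str, Mapping[str, Sequence]],
    min_reads_per_target: int = 3,
    min_cluster_reads: int = 5,
) -> tuple[dict[str, dict[str, list]], FilterReport]:
    """Drop under-supported target groups and clusters.

    ``groups`` maps cluster_id -> target_id -> reads.  Target groups with
    fewer than ``min_reads_per_target`` reads are removed first; clusters
    whose surviving reads total fewer than ``min_cluster_reads`` are then
    removed entirely.
    """
    report = FilterReport()
    retained: dict[str, dict[str, list]] = {}
    for cid, targets in groups.items():
        kept: dict[str, list] = {}
        for tid, reads in targets.items():
            if len(reads) >= min_reads_per_target:
                kept[tid] = list(reads)
            else:
                report.n_target_groups_dropped += 1
                report.n_reads_dropped += len(reads)
        total = sum(len(r) for r in kept.values())
        if kept and total >= min_cluster_reads:
            retained[cid] = kept
        else:
            report.n_clusters_dropped += 1
            report.n_reads_dropped += total
    return retained, report


def _truncated_within(max_fraction: float):
    def within(a: str, b: str) -> bool:
        n = min(len(a), len(b))
        limit = max_fraction * n
        d = 0
        for x, y in zip(a[:n], b[:n]):
            if x != y:
                d += 1
                if d > limit:
                    return False
        return d <= limit

    return within


def subcluster_reads(
    reads: Sequence[str], max_mismatch_fraction: float = 0.02
) -> list[VariantGroup]:
    """Group a target's reads into sequence variants.

    Uses the same abundance-ranked iterative greedy procedure as barcode
    clustering, with a per-base threshold of ``max_mismatch_fraction``
    times the compared length (comparisons truncate to the shorter
    sequence).  Groups are returned sorted by descending size.
    """
    if not reads:
        return []
    counts = Counter(reads)
    grouped = iterative_greedy_cluster(
        counts, _truncated_within(max_mismatch_fraction)
    )
    out = []
    for seed, members in grouped:
        expanded: list[str] = []
        for seq, n in members.items():
            expanded.extend([seq] * n)
        out.append(VariantGroup(representative=seed, reads=expanded))
    out.sort(key=lambda g: (-g.size, g.representative))
    return out


def call_consensus(reads: Sequence[str]) -> str:
    """Positional majority consensus of a variant group.

    The consensus length is the modal read length (ties -> shorter); at
    each position the majority base over all reads covering it is taken,
    ties broken toward the lexicographically smallest base.
    """
    if not reads:
        raise ValueError("call_consensus requires a non-empty group")
    lengths = Counter(len(r) for r in reads)
    length = sorted(lengths, key=lambda L: (-lengths[L], L))[0]
    out = []
    for i in range(length):
        votes = Counter(r[i] for r in reads if len(r) > i)
        best = min(
            (b for b in ALPHABET if votes.get(b, 0) == max(votes.values())),
        )
        out.append(best)
    return "".join(out)


def classify_amplification_clonality(
    target_variant_groups: Mapping[str, Sequence[VariantGroup]],
    dominant_threshold: float = 0.90,
) -> str:
    """Label a cluster's amplification monoclonal or polyclonal.

    Monoclonal iff for every present target the largest variant group
    holds at least ``dominant_threshold`` of that target's reads.
    """
    for groups in target_variant_groups.values():
        if not groups:
            continue
        total = sum(g.size for g in groups)
        if groups[0].size / total < dominant_threshold:
            return "polyclonal"
    return "monoclonal"


def dominant_fraction(groups: Sequence[VariantGroup]) -> float:
    total = sum(g.size for g in groups)
    return groups[0].size / total if total else 0.0
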