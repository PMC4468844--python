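"""Barcode extraction, well demultiplexing and mismatch-tolerant clustering.

A read carries a degenerate bead barcode flanked by fixed handle
sequences (optionally preceded by a well tag).  Because sequencing
introduces substitution errors, reads from one bead show a cloud of
barcode variants around the true barcode; the clustering here groups
those variants back onto an abundance-ranked seed, with a configurable
Hamming mismatch tolerance, iterating the greedy sweep until the number
of clusters stops shrinking.  A resulting barcode cluster is the unit of
downstream analysis and is the proxy for one amplicon-carrying bead.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional

import numpy as np

from .errors import ConfigurationError, InvalidInputError
from .util import encode_seq, encode_seq_lenient

__all__ = [
    "ReadPair",
    "ReadLayout",
    "BarcodeObservation",
    "BarcodeCluster",
    "hamming_distance",
    "extract_barcode",
    "demultiplex_wells",
    "cluster_barcodes",
    "classify_well_clonality",
    "iterative_greedy_cluster",
]


@dataclass
class ReadPair:
    """One (possibly single-end) read record.

    ``seq2``/quality strings may be empty for single-end sorting reads;
    ``well_tag_observed`` is filled in by demultiplexing.
    """

    read_id: str
    seq1: str
    seq2: str = ""
    qual1: str = ""
    qual2: str = ""
    well_tag_observed: Optional[str] = None

    def __post_init__(self) -> None:
        if self.qual1 and len(self.qual1) != len(self.seq1):
            raise InvalidInputError(f"{self.read_id}: qual1/seq1 length mismatch")
        if self.qual2 and len(self.qual2) != len(self.seq2):
            raise InvalidInputError(f"{self.read_id}: qual2/seq2 length mismatch")


@dataclass(frozen=True)
class ReadLayout:
    """Fixed structure of read 1: [well tag] + 5' handle + barcode + 3' handle."""

    handle_5p: str
    handle_3p: str
    barcode_length: int = 15
    well_tag_length: int = 0
    handle_max_mismatch: int = 4

    @property
    def barcode_offset(self) -> int:
        return self.well_tag_length + len(self.handle_5p)

    @property
    def min_read_length(self) -> int:
        return self.barcode_offset + self.barcode_length + len(self.handle_3p)


@dataclass(frozen=True)
class BarcodeObservation:
    read_id: str
    barcode: str
    handle_mismatches: int


@dataclass(frozen=True)
class Rejection:
    read_id: str
    reason: str  # "too_short" | "handle_mismatch"


@dataclass
class BarcodeCluster:
    """All barcodes (and their read counts) grouped to one seed barcode."""

    cluster_id: str
    seed_barcode: str
    members: dict[str, int] = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return sum(self.members.values())

    @property
    def n_distinct(self) -> int:
        return len(self.members)


def hamming_distance(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length strings."""
    if len(a) != len(b):
        raise InvalidInputError(
            f"hamming_distance requires equal lengths ({len(a)} vs {len(b)})"
        )
    return sum(x != y for x, y in zip(a, b))


def extract_barcode(
    read: ReadPair, layout: ReadLayout
) -> BarcodeObservation | Rejection:
    """Pull the bead barcode out of read 1, tolerating handle mismatches.

    Both handles are located at their fixed offsets; the read is kept if
    the total number of mismatches across both handle sequences is within
    ``layout.handle_max_mismatch`` (default 4), otherwise rejected with a
    reason code.
    """
    seq = read.seq1
    if len(seq) < layout.min_read_length:
        return Rejection(read.read_id, "too_short")
    off = layout.well_tag_length
    h5 = seq[off : off + len(layout.handle_5p)]
    bc_start = layout.barcode_offset
    bc_end = bc_start + layout.barcode_length
    h3 = seq[bc_end : bc_end + len(layout.handle_3p)]
    mm = hamming_distance(h5, layout.handle_5p) + hamming_distance(
        h3, layout.handle_3p
    )
    if mm > layout.handle_max_mismatch:
        return Rejection(read.read_id, "handle_mismatch")
    return BarcodeObservation(read.read_id, seq[bc_start:bc_end], mm)


def demultiplex_wells(
    reads: Iterable[ReadPair],
    well_tags: list[str],
    max_mismatch: int = 2,
) -> tuple[dict[int, list[ReadPair]], list[ReadPair]]:
    """Assign reads to wells by the tag at the start of read 1.

    Well tags must be equal length and pairwise more than 2*max_mismatch
    apart, which guarantees each observed tag is within ``max_mismatch``
    of at most one designed tag.  Returns ``(well_index -> reads,
    unassigned reads)``.
    """
    if not well_tags:
        raise ConfigurationError("no well tags supplied")
    tag_len = len(well_tags[0])
    if any(len(t) != tag_len for t in well_tags):
        raise ConfigurationError("well tags must be equal length")
    for i in range(len(well_tags)):
        for j in range(i + 1, len(well_tags)):
            d = hamming_distance(well_tags[i], well_tags[j])
            if d <= 2 * max_mismatch:
                raise ConfigurationError(
                    f"well tags {i} and {j} are only {d} mismatches apart; "
                    f"need > {2 * max_mismatch} for unambiguous assignment"
                )
    assigned: dict[int, list[ReadPair]] = {i: [] for i in range(len(well_tags))}
    unassigned: list[ReadPair] = []
    reads = list(reads)
    tag_mat = np.stack([encode_seq(t) for t in well_tags])
    candidates = [r for r in reads if len(r.seq1) >= tag_len]
    unassigned.extend(r for r in reads if len(r.seq1) < tag_len)
    # vectorised nearest-tag search; the separation precondition guarantees
    # at most one tag within max_mismatch, so argmin is the unique hit
    chunk = 4096
    for start in range(0, len(candidates), chunk):
        block = candidates[start : start + chunk]
        prefixes = np.stack(
            [encode_seq_lenient(r.seq1[:tag_len]) for r in block]
        )
        dists = (prefixes[:, None, :] != tag_mat[None, :, :]).sum(axis=2)
        best = dists.argmin(axis=1)
        best_d = dists[np.arange(len(block)), best]
        for read, hit, d in zip(block, best, best_d):
            if d <= max_mismatch:
                read.well_tag_observed = read.seq1[:tag_len]
                assigned[int(hit)].append(read)
            else:
                unassigned.append(read)
    return assigned, unassigned


def iterative_greedy_cluster(
    counts: Mapping[str, int],
    within: Callable[[str, str], bool],
) -> list[tuple[str, dict[str, int]]]:
    """Abundance-ranked greedy grouping, iterated to a fixed point.

    Each pass ranks current cluster seeds by descending aggregated count
    (ties broken lexicographically), sweeps the ranking, and absorbs every
    later unabsorbed seed for which ``within(seed, other)`` holds.  Passes
    repeat until the number of clusters stops decreasing.  Returns
    ``(seed, members)`` pairs where the reported seed is the most abundant
    member (ties lexicographic).

    This is the reference-shaped implementation shared by barcode and
    read-variant clustering; ``cluster_barcodes`` provides an equivalent
    vectorised path for equal-length barcodes.
    """
    clusters: list[dict[str, int]] = [{b: c} for b, c in counts.items()]
    seeds: list[str] = list(counts.keys())
    while True:
        n_before = len(clusters)
        order = sorted(
            range(n_before),
            key=lambda i: (-sum(clusters[i].values()), seeds[i]),
        )
        absorbed = [False] * n_before
        new_clusters: list[dict[str, int]] = []
        new_seeds: list[str] = []
        for pos, i in enumerate(order):
            if absorbed[pos]:
                continue
            merged = clusters[i]
            for pos2 in range(pos + 1, n_before):
                if absorbed[pos2]:
                    continue
                j = order[pos2]
                if within(seeds[i], seeds[j]):
                    merged.update(clusters[j])
                    absorbed[pos2] = True
            new_clusters.append(merged)
            new_seeds.append(seeds[i])
        clusters, seeds = new_clusters, new_seeds
        if len(clusters) == n_before:
            break
    out = []
    for members in clusters:
        seed = max(members, key=lambda b: (members[b], _lex_rank(b)))
        out.append((seed, members))
    return out


def _lex_rank(s: str):
    # max() with this key prefers higher count, then lexicographically
    # smaller string.
    return tuple(-ord(c) for c in s)


def cluster_barcodes(
    counts: Mapping[str, int], max_mismatch: int = 2
) -> list[BarcodeCluster]:
    """Group observed barcodes into clusters around abundant seeds.

    Implements the iterative abundance-ranked greedy procedure of
    :func:`iterative_greedy_cluster` with a Hamming radius of
    ``max_mismatch`` (default 2), vectorised over equal-length barcodes.
    Clusters are returned sorted by descending total reads (ties by seed)
    and labelled ``bc000000`` onwards.
    """
    barcodes = list(counts.keys())
    if not barcodes:
        return []
    length = len(barcodes[0])
    if any(len(b) != length for b in barcodes):
        raise InvalidInputError("all barcodes must have equal length")

    enc = np.empty((len(barcodes), length), dtype=np.uint8)
    for i, b in enumerate(barcodes):
        enc[i] = encode_seq(b)

    # cluster state: seed index into `barcodes`, member indices, total count
    seed_idx = list(range(len(barcodes)))
    members: list[list[int]] = [[i] for i in seed_idx]
    totals = np.array([counts[b] for b in barcodes], dtype=np.int64)
    cluster_totals = totals.copy()

    while True:
        n_before = len(seed_idx)
        order = sorted(
            range(n_before),
            key=lambda ci: (-int(cluster_totals[ci]), barcodes[seed_idx[ci]]),
        )
        seed_rows = enc[[seed_idx[ci] for ci in order]]
        absorbed = np.zeros(n_before, dtype=bool)
        new_seed_idx: list[int] = []
        new_members: list[list[int]] = []
        new_totals: list[int] = []
        for pos in range(n_before):
            if absorbed[pos]:
                continue
            ci = order[pos]
            mem = members[ci]
            tot = int(cluster_totals[ci])
            if pos + 1 < n_before:
                d = (seed_rows[pos + 1 :] != seed_rows[pos]).sum(axis=1)
                hits = np.nonzero((~absorbed[pos + 1 :]) & (d <= max_mismatch))[0]
                for h in hits:
                    cj = order[pos + 1 + h]
                    mem = mem + members[cj]
                    tot += int(cluster_totals[cj])
                    absorbed[pos + 1 + h] = True
            new_seed_idx.append(seed_idx[ci])
            new_members.append(mem)
            new_totals.append(tot)
        seed_idx, members = new_seed_idx, new_members
        cluster_totals = np.array(new_totals, dtype=np.int64)
        if len(seed_idx) == n_before:
            break

    clusters = []
    for mem in members:
        mdict = {barcodes[i]: counts[barcodes[i]] for i in mem}
        seed = max(mdict, key=lambda b: (mdict[b], _lex_rank(b)))
        clusters.append((seed, mdict))
    clusters.sort(key=lambda sc: (-sum(sc[1].values()), sc[0]))
    return [
        BarcodeCluster(cluster_id=f"bc{i:06d}", seed_barcode=seed, members=mdict)
        for i, (seed, mdict) in enumerate(clusters)
    ]


def barcode_counts(observations: Iterable[BarcodeObservation]) -> Counter:
    """Tally reads per observed barcode sequence."""
    return Counter(obs.barcode for obs in observations)


def classify_well_clonality(
    clusters_in_well: list[BarcodeCluster], min_fraction: float = 0.10
) -> str:
    """Label a well empty/monoclonal/polyclonal from its barcode clusters.

    A cluster "counts" if it holds at least ``min_fraction`` of the well's
    reads; 0 counting clusters -> "empty", 1 -> "monoclonal",
    >= 2 -> "polyclonal".  This is an automated surrogate for a manual call
    on the per-well barcode distribution.
    """
    total = sum(c.total_reads for c in clusters_in_well)
    if total == 0:
        return "empty"
    major = sum(
        1 for c in clusters_in_well if c.total_reads / total >= min_fraction
    )
    if major == 0:
        return "empty"
    return "monoclonal" if major == 1 else "polyclonal"
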