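"""Phasing statistics: observed, chance-expected and corrected match rates.

A barcode cluster with both target regions classified to the same
species is a putative phasing event — but two co-compartmentalised
fragments of the same species produce the same signal by chance.  The
chance level is estimated by shuffling one target's classifications
across clusters (the random match rate, with an analytic collision
check sum(p_i^2)), and the observed phasing rate is corrected to

    P_corr = (P_obs - P_rand) / (1 - P_rand),

the estimated fraction of both-target clusters whose match is not
explained by chance, i.e. that truly derive from a single molecule.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .classify import AMBIGUOUS, TaxonAssignment
from .errors import InvalidParameterError, UndefinedResultError

__all__ = [
    "ClusterCall",
    "PhasingSummary",
    "OverlapReport",
    "target_presence_fractions",
    "phasing_rate",
    "random_match_rate",
    "analytic_random_match",
    "corrected_phasing_rate",
    "remove_dominant_species",
    "hitlist_overlap_reduction",
    "depth_subsample",
    "summarize_phasing",
]


@dataclass(frozen=True)
class ClusterCall:
    """Per-cluster species calls for the targets that survived filtering."""

    cluster_id: str
    calls: dict[str, str]  # target_id -> species or AMBIGUOUS
    monoclonal: bool = True
    hit_lists: dict[str, frozenset] = field(default_factory=dict)


def _eligible(
    calls: Iterable[ClusterCall], t1: str, t2: str
) -> list[ClusterCall]:
    return [
        c
        for c in calls
        if t1 in c.calls
        and t2 in c.calls
        and c.calls[t1] != AMBIGUOUS
        and c.calls[t2] != AMBIGUOUS
    ]


def target_presence_fractions(
    calls: Sequence[ClusterCall], t1: str, t2: str
) -> dict[str, float]:
    """Fractions of clusters showing only target 1, only target 2, or both."""
    n = len(calls)
    if n == 0:
        return {"only_1": 0.0, "only_2": 0.0, "both": 0.0}
    only1 = sum(1 for c in calls if t1 in c.calls and t2 not in c.calls)
    only2 = sum(1 for c in calls if t2 in c.calls and t1 not in c.calls)
    both = sum(1 for c in calls if t1 in c.calls and t2 in c.calls)
    return {"only_1": only1 / n, "only_2": only2 / n, "both": both / n}


def phasing_rate(calls: Sequence[ClusterCall], t1: str, t2: str) -> float:
    """Observed phasing rate P_obs.

    Fraction of eligible clusters (both targets called, neither
    ambiguous) whose two targets classify to the same species.
    """
    eligible = _eligible(calls, t1, t2)
    if not eligible:
        raise UndefinedResultError("no clusters with both targets called")
    matches = sum(1 for c in eligible if c.calls[t1] == c.calls[t2])
    return matches / len(eligible)


def random_match_rate(
    calls: Sequence[ClusterCall],
    t1: str,
    t2: str,
    n_shuffles: int = 100,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, float]:
    """Shuffle-based chance match rate P_rand with its Monte-Carlo SE.

    For each shuffle the second target's calls are permuted uniformly
    across eligible clusters (first target fixed) and the match fraction
    recomputed; returns the mean over shuffles and its standard error.
    """
    eligible = _eligible(calls, t1, t2)
    if len(eligible) < 2:
        raise UndefinedResultError("need >= 2 eligible clusters to shuffle")
    if rng is None:
        rng = np.random.default_rng(seed)
    a = np.array([c.calls[t1] for c in eligible])
    b = np.array([c.calls[t2] for c in eligible])
    rates = np.empty(n_shuffles)
    for s in range(n_shuffles):
        perm = rng.permutation(len(b))
        rates[s] = float((a == b[perm]).mean())
    se = float(rates.std(ddof=1) / np.sqrt(n_shuffles)) if n_shuffles > 1 else 0.0
    return float(rates.mean()), se


def analytic_random_match(p: Sequence[float]) -> float:
    """Collision probability sum(p_i^2) of two independent draws from p."""
    arr = np.asarray(p, dtype=float)
    if (arr < 0).any() or abs(arr.sum() - 1.0) > 1e-9:
        raise InvalidParameterError(
            "frequency vector must be non-negative and sum to 1"
        )
    return float((arr**2).sum())


def corrected_phasing_rate(p_obs: float, p_rand: float) -> float:
    """Chance-corrected phasing rate (P_obs - P_rand) / (1 - P_rand).

    Clamped below at 0; undefined when the chance rate reaches 1.
    """
    if p_rand >= 1.0:
        raise UndefinedResultError("random match rate is 1; correction undefined")
    return max(0.0, (p_obs - p_rand) / (1.0 - p_rand))


def remove_dominant_species(
    calls: Sequence[ClusterCall],
    abundances: dict[str, Counter],
    t1: str,
    t2: str,
    n_shuffles: int = 100,
    seed: int = 0,
) -> tuple[str, list[ClusterCall], dict[str, float]]:
    """Drop clusters involving the most abundant species; recompute rates.

    In a sample dominated by one species the chance match rate is high
    and the correction uninformative; removing the dominant species'
    clusters re-exposes the phasing signal among the minor species.
    Returns ``(dominant_species, remaining calls, {p_obs, p_rand,
    p_rand_se, p_corr})``.
    """
    from .classify import dominant_species

    dom = dominant_species(abundances)
    remaining = [c for c in calls if dom not in c.calls.values()]
    if not remaining:
        raise UndefinedResultError(
            f"removing dominant species {dom!r} leaves no clusters"
        )
    p_obs = phasing_rate(remaining, t1, t2)
    p_rand, se = random_match_rate(
        remaining, t1, t2, n_shuffles=n_shuffles, seed=seed
    )
    stats = {
        "p_obs": p_obs,
        "p_rand": p_rand,
        "p_rand_se": se,
        "p_corr": corrected_phasing_rate(p_obs, p_rand),
    }
    return dom, remaining, stats


@dataclass
class OverlapReport:
    """Hit-list overlap between the two targets, per cluster and averaged."""

    mean_len_1: float
    mean_len_2: float
    mean_overlap: float
    mean_reduction: float
    per_cluster: list[float]
    n_skipped: int

    def to_dict(self) -> dict:
        return {
            "mean_len_1": self.mean_len_1,
            "mean_len_2": self.mean_len_2,
            "mean_overlap": self.mean_overlap,
            "mean_reduction": self.mean_reduction,
            "n_clusters": len(self.per_cluster),
            "n_skipped": self.n_skipped,
        }


def hitlist_overlap_reduction(
    pairs: Sequence[tuple[frozenset, frozenset]],
) -> OverlapReport:
    """How much does phasing shrink the candidate-species list?

    For each both-target cluster with hit lists A and B, the reduction is
    ``1 - |A & B| / mean(|A|, |B|)``: 0 when phasing adds nothing
    (identical lists), 1 when the two lists are disjoint.  Clusters with
    an empty list are skipped and counted.
    """
    reductions: list[float] = []
    lens1: list[int] = []
    lens2: list[int] = []
    overlaps: list[int] = []
    skipped = 0
    for a, b in pairs:
        if not a or not b:
            skipped += 1
            continue
        inter = len(a & b)
        mean_len = (len(a) + len(b)) / 2
        reductions.append(1.0 - inter / mean_len)
        lens1.append(len(a))
        lens2.append(len(b))
        overlaps.append(inter)
    if not reductions:
        return OverlapReport(0.0, 0.0, 0.0, 0.0, [], skipped)
    return OverlapReport(
        mean_len_1=float(np.mean(lens1)),
        mean_len_2=float(np.mean(lens2)),
        mean_overlap=float(np.mean(overlaps)),
        mean_reduction=float(np.mean(reductions)),
        per_cluster=reductions,
        n_skipped=skipped,
    )


@dataclass
class PhasingSummary:
    """All headline quantities for one run (None where undefined)."""

    n_clusters: int
    target_1: str
    target_2: str
    frac_only_1: float
    frac_only_2: float
    frac_both: float
    monoclonal_rate: Optional[float]
    p_obs: Optional[float]
    p_rand: Optional[float]
    p_rand_se: Optional[float]
    p_corr: Optional[float]
    overlap: Optional[OverlapReport] = None

    def to_dict(self) -> dict:
        d = {
            "n_clusters": self.n_clusters,
            "target_1": self.target_1,
            "target_2": self.target_2,
            "frac_only_1": self.frac_only_1,
            "frac_only_2": self.frac_only_2,
            "frac_both": self.frac_both,
            "monoclonal_rate": self.monoclonal_rate,
            "p_obs": self.p_obs,
            "p_rand": self.p_rand,
            "p_rand_se": self.p_rand_se,
            "p_corr": self.p_corr,
        }
        if self.overlap is not None:
            d["overlap"] = self.overlap.to_dict()
        return d


def summarize_phasing(
    calls: Sequence[ClusterCall],
    t1: str,
    t2: str,
    n_shuffles: int = 100,
    seed: int = 0,
) -> PhasingSummary:
    """Compute the full summary, degrading gracefully on sparse input."""
    fracs = target_presence_fractions(calls, t1, t2)
    n = len(calls)
    mono = sum(1 for c in calls if c.monoclonal) / n if n else None
    p_obs = p_rand = p_rand_se = p_corr = None
    try:
        p_obs = phasing_rate(calls, t1, t2)
        p_rand, p_rand_se = random_match_rate(
            calls, t1, t2, n_shuffles=n_shuffles, seed=seed
        )
        p_corr = corrected_phasing_rate(p_obs, p_rand)
    except UndefinedResultError:
        pass
    pairs = [
        (c.hit_lists[t1], c.hit_lists[t2])
        for c in calls
        if t1 in c.hit_lists and t2 in c.hit_lists
    ]
    overlap = hitlist_overlap_reduction(pairs) if pairs else None
    return PhasingSummary(
        n_clusters=n,
        target_1=t1,
        target_2=t2,
        frac_only_1=fracs["only_1"],
        frac_only_2=fracs["only_2"],
        frac_both=fracs["both"],
        monoclonal_rate=mono,
        p_obs=p_obs,
        p_rand=p_rand,
        p_rand_se=p_rand_se,
        p_corr=p_corr,
        overlap=overlap,
    )


def depth_subsample(
    reads: Sequence,
    fractions: Sequence[float],
    pipeline: Callable[[Sequence], PhasingSummary],
    seed: int = 0,
) -> pd.DataFrame:
    """Rerun the pipeline on random read subsets of decreasing depth.

    For each fraction f in (0, 1], a subset of round(f * n) read pairs is
    drawn without replacement and the full pipeline rerun on it; the
    table reports, per fraction, the number of clusters passing filters
    and the fraction of clusters with both targets.
    """
    if any(not 0 < f <= 1 for f in fractions):
        raise InvalidParameterError("fractions must be in (0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    reads = list(reads)
    for f in fractions:
        if f == 1.0:
            subset = reads
        else:
            k = int(round(f * len(reads)))
            idx = rng.choice(len(reads), size=k, replace=False)
            subset = [reads[i] for i in sorted(idx)]
        summary = pipeline(subset)
        rows.append(
            {
                "fraction": f,
                "n_reads": len(subset),
                "n_clusters": summary.n_clusters,
                "frac_both": summary.frac_both,
            }
        )
    return pd.DataFrame(rows)
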