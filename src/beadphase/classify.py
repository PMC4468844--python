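"""Desk-scale taxonomic classification of amplicon consensuses.

Each consensus is scored against a small reference panel by k-mer
containment: score(species) = |k-mers shared with the reference| /
|k-mers of the consensus|.  All species within a score margin of the
top hit form the hit list; the best call is the top species only when
it clears the runner-up by more than the margin, otherwise the call is
explicitly "ambiguous".  For species-level differences concentrated in
variable regions this deterministic scheme separates the panel without
an alignment engine.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ConfigurationError, InvalidInputError, InvalidParameterError
from .simulate import Reference

__all__ = [
    "ReferenceIndex",
    "TaxonAssignment",
    "AMBIGUOUS",
    "build_reference_index",
    "classify_consensus",
    "abundance_table",
]

AMBIGUOUS = "ambiguous"


def _kmers(seq: str, k: int) -> frozenset[str]:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


@dataclass(frozen=True)
class ReferenceIndex:
    """k-mer sets per (species, target) over the reference panel."""

    k: int
    postings: dict[tuple[str, str], frozenset[str]]

    def species_for_target(self, target_id: str) -> list[str]:
        return sorted(
            {sp for sp, tid in self.postings.keys() if tid == target_id}
        )


def build_reference_index(reference: Reference, k: int = 8) -> ReferenceIndex:
    """Index every reference sequence by its k-mer content."""
    if k < 4:
        raise InvalidParameterError(f"k must be >= 4, got {k}")
    postings: dict[tuple[str, str], frozenset[str]] = {}
    for sp in reference.species:
        for tid, seq in sp.target_sequences.items():
            if len(seq) <= k:
                raise InvalidInputError(
                    f"{sp.species_id}/{tid}: sequence shorter than k={k}"
                )
            key = (sp.species_id, tid)
            if key in postings:
                raise InvalidInputError(f"duplicate reference entry {key}")
            postings[key] = _kmers(seq, k)
    return ReferenceIndex(k=k, postings=postings)


@dataclass(frozen=True)
class TaxonAssignment:
    cluster_id: str
    target_id: str
    hit_list: tuple[tuple[str, float], ...]  # (species, score), best first
    best_call: str  # species id or AMBIGUOUS

    @property
    def hit_species(self) -> frozenset[str]:
        return frozenset(sp for sp, _ in self.hit_list)


def classify_consensus(
    consensus: str,
    index: ReferenceIndex,
    target_id: str,
    margin: float = 0.05,
    cluster_id: str = "",
) -> TaxonAssignment:
    """Score one consensus against all species indexed for its target."""
    if not index.postings:
        raise ConfigurationError("reference index is empty")
    if len(consensus) < index.k:
        raise InvalidInputError(
            f"consensus shorter than k={index.k}; cannot classify"
        )
    qk = _kmers(consensus, index.k)
    scored = []
    for sp in index.species_for_target(target_id):
        ref = index.postings[(sp, target_id)]
        scored.append((sp, len(qk & ref) / len(qk)))
    scored.sort(key=lambda s: (-s[1], s[0]))
    top = scored[0][1] if scored else 0.0
    hits = tuple(
        (sp, sc) for sp, sc in scored if sc > 0 and sc >= top - margin
    )
    if not hits:
        best = AMBIGUOUS
    elif len(hits) == 1:
        best = hits[0][0]
    elif hits[0][1] - hits[1][1] > margin:
        best = hits[0][0]
    else:
        best = AMBIGUOUS
    return TaxonAssignment(
        cluster_id=cluster_id,
        target_id=target_id,
        hit_list=hits,
        best_call=best,
    )


def abundance_table(
    assignments: Iterable[TaxonAssignment],
) -> dict[str, Counter]:
    """Best-call counts per target and combined ("ambiguous" kept apart)."""
    out: dict[str, Counter] = {"combined": Counter()}
    for a in assignments:
        out.setdefault(a.target_id, Counter())[a.best_call] += 1
        out["combined"][a.best_call] += 1
    return out


def dominant_species(abundances: dict[str, Counter]) -> str:
    """Most abundant non-ambiguous best-call species (ties lexicographic)."""
    combined = abundances["combined"]
    candidates = sorted(
        ((-n, sp) for sp, n in combined.items() if sp != AMBIGUOUS)
    )
    if not candidates:
        raise InvalidInputError("no classified species in abundance table")
    return candidates[0][1]
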