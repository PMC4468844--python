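"""Seeded simulator of the two-emulsion bead-barcoding experiment.

The generator emulates the structure of the assay end to end:

* a first emulsion loads degenerate barcode oligonucleotides onto beads
  at a Poisson rate (``barcode_cpb``), so a bead carries 0, 1 or more
  distinct barcodes;
* a second emulsion pairs one enriched (barcode-carrying) bead per
  droplet with a Poisson(``fragment_cpb``) number of genomic fragments
  drawn from a (typically skewed) species mixture;
* every fragment can template amplicons for each configured target
  region; each amplicon emits a Poisson-distributed number of read
  pairs, read 1 holding handle + bead barcode + handle and read 2 the
  target amplicon (primer + species-specific variable region);
* independent per-base substitution errors are applied to both mates.

Everything is driven by a single seed and a full ground-truth record
(``SimTruth``) is produced, so every downstream stage of the pipeline
can be validated read by read without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .barcodes import ReadPair, hamming_distance
from .errors import InvalidInputError, InvalidParameterError
from .util import decode_seq, encode_seq, random_seq, stage_rng

__all__ = [
    "SpeciesReference",
    "Reference",
    "SimConfig",
    "SimTruth",
    "SortingTruth",
    "make_reference",
    "make_well_tags",
    "mutate_sequence",
    "simulate_bead_library",
    "simulate_phasing_run",
    "simulate_sorting_run",
]

DEFAULT_HANDLE_5P = "CTCTTTCCCTACACGACGCT"
DEFAULT_HANDLE_3P = "AGATCGGAAGAGCACACGTC"
DEFAULT_TARGETS = ("16S.1", "16S.2")


@dataclass(frozen=True)
class SpeciesReference:
    """One species and its sequence for every target region."""

    species_id: str
    target_sequences: dict[str, str]

    def __post_init__(self) -> None:
        for tid, seq in self.target_sequences.items():
            if not set(seq) <= set("ACGT"):
                raise InvalidInputError(
                    f"{self.species_id}/{tid}: sequence not over ACGT"
                )


@dataclass(frozen=True)
class Reference:
    """A species panel plus the target-specific primers shared by all species.

    ``target_primers`` maps each target id to the constant primer that
    starts every read-2 of that target; the per-species
    ``target_sequences`` are the variable regions that follow it.
    """

    species: tuple[SpeciesReference, ...]
    target_primers: dict[str, str]

    @property
    def target_ids(self) -> tuple[str, ...]:
        return tuple(self.target_primers.keys())

    @property
    def species_ids(self) -> tuple[str, ...]:
        return tuple(sp.species_id for sp in self.species)

    def __post_init__(self) -> None:
        targets = set(self.target_primers)
        for sp in self.species:
            if set(sp.target_sequences) != targets:
                raise InvalidInputError(
                    f"{sp.species_id} does not define all targets {sorted(targets)}"
                )


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated run.

    Defaults reflect the assay's design point: ~0.1 copies per bead for
    both barcode oligos and genomic fragments (so ~95% of occupied
    compartments are monoclonal), 15-nt degenerate barcodes, a skewed
    four-species mixture, and a 0.5% per-base substitution error rate.
    """

    n_beads: int = 60_000
    barcode_length: int = 15
    barcode_cpb: float = 0.1
    n_droplets: int = 5_000
    fragment_cpb: float = 0.1
    species_abundances: tuple[float, ...] = (0.4, 0.3, 0.2, 0.1)
    reads_per_amplicon: float = 20.0
    substitution_error_rate: float = 0.005
    handle_5p: str = DEFAULT_HANDLE_5P
    handle_3p: str = DEFAULT_HANDLE_3P
    seed: int = 0

    def __post_init__(self) -> None:
        if not 15 <= self.barcode_length <= 20:
            raise InvalidParameterError(
                f"barcode_length must be in [15, 20], got {self.barcode_length}"
            )
        if self.barcode_cpb < 0 or self.fragment_cpb < 0:
            raise InvalidParameterError("loading rates must be >= 0")
        if not 0 <= self.substitution_error_rate < 1:
            raise InvalidParameterError("substitution_error_rate must be in [0, 1)")
        if self.n_beads < 0 or self.n_droplets < 0 or self.reads_per_amplicon < 0:
            raise InvalidParameterError("counts must be >= 0")
        p = np.asarray(self.species_abundances, dtype=float)
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise InvalidParameterError(
                "species_abundances must be non-negative and sum to 1"
            )


class ReadOrigin(NamedTuple):
    droplet_id: int
    target_id: str
    species_id: str
    true_barcode: str
    fragment_id: int


@dataclass
class SimTruth:
    """Complete ground truth of a simulated phasing run."""

    bead_barcodes: dict[int, list[str]] = field(default_factory=dict)
    # droplet -> (bead_id, [(species_id, fragment_id), ...])
    droplet_contents: dict[int, tuple[int, list[tuple[str, int]]]] = field(
        default_factory=dict
    )
    read_origins: dict[str, ReadOrigin] = field(default_factory=dict)

    def enriched_beads(self) -> list[int]:
        return [b for b, bcs in self.bead_barcodes.items() if bcs]

    def to_rows(self):
        """Truth as TSV-ready rows: one per emitted read."""
        for rid, o in self.read_origins.items():
            bead_id = self.droplet_contents[o.droplet_id][0]
            yield (
                rid,
                o.droplet_id,
                bead_id,
                o.species_id,
                o.target_id,
                o.true_barcode,
                o.fragment_id,
            )


@dataclass
class SortingTruth:
    """Ground truth of a simulated bead-sorting (well plate) run."""

    bead_barcodes: dict[int, list[str]]
    well_beads: dict[int, int] = field(default_factory=dict)
    # read_id -> (well_id, bead_id, true_barcode)
    read_origins: dict[str, tuple[int, int, str]] = field(default_factory=dict)


def make_reference(
    n_species: int = 4,
    target_lengths: Optional[dict[str, int]] = None,
    divergence: float = 0.05,
    seed: int = 0,
    primer_length: int = 20,
    species_ids: Optional[Sequence[str]] = None,
) -> Reference:
    """Generate a synthetic species panel for the configured targets.

    Each target gets one random ancestral variable region; every species'
    copy is derived from it by independent substitutions at the given
    per-base ``divergence``, so two species differ at an expected
    ``2 * divergence * (1 - divergence)`` fraction of positions.  A
    constant primer (distinct per target) is generated alongside.
    """
    if n_species < 1:
        raise InvalidParameterError("n_species must be >= 1")
    if not 0 < divergence < 0.5:
        raise InvalidParameterError(
            f"divergence must be in (0, 0.5), got {divergence}"
        )
    if target_lengths is None:
        target_lengths = {t: 150 for t in DEFAULT_TARGETS}
    if species_ids is None:
        species_ids = [f"species_{i + 1}" for i in range(n_species)]
    elif len(species_ids) != n_species:
        raise InvalidInputError("species_ids length must equal n_species")

    rng = stage_rng(seed, "reference")
    primers: dict[str, str] = {}
    ancestors: dict[str, str] = {}
    for tid, length in target_lengths.items():
        while True:
            primer = random_seq(rng, primer_length)
            # primers must be mutually distinguishable at the default
            # 2-mismatch tolerance
            if all(hamming_distance(primer, p) > 4 for p in primers.values()):
                primers[tid] = primer
                break
        ancestors[tid] = random_seq(rng, length)

    species = []
    for sid in species_ids:
        seqs = {}
        for tid, anc in ancestors.items():
            if n_species == 1:
                seqs[tid] = anc
            else:
                seqs[tid] = mutate_sequence(anc, divergence, rng)
        species.append(SpeciesReference(species_id=sid, target_sequences=seqs))
    return Reference(species=tuple(species), target_primers=primers)


def make_well_tags(
    n: int, length: int = 12, min_distance: int = 5, seed: int = 0
) -> list[str]:
    """Random well tags with guaranteed pairwise Hamming separation."""
    rng = stage_rng(seed, "well_tags")
    tags: list[str] = []
    attempts = 0
    while len(tags) < n:
        cand = random_seq(rng, length)
        if all(hamming_distance(cand, t) >= min_distance for t in tags):
            tags.append(cand)
        attempts += 1
        if attempts > 100_000:
            raise InvalidParameterError(
                f"cannot place {n} tags of length {length} at distance {min_distance}"
            )
    return tags


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Apply i.i.d. per-base substitutions at the given rate.

    Each mutated base becomes one of the three other bases uniformly;
    length is preserved (no indels).
    """
    if not 0 <= rate < 1:
        raise InvalidParameterError(f"rate must be in [0, 1), got {rate}")
    if rate == 0 or not seq:
        return seq
    arr = encode_seq(seq)
    hit = rng.random(arr.shape[0]) < rate
    n_hit = int(hit.sum())
    if n_hit == 0:
        return seq
    out = arr.copy()
    shift = rng.integers(1, 4, size=n_hit, dtype=np.uint8)
    out[hit] = (out[hit] + shift) % 4
    return decode_seq(out)


def simulate_bead_library(cfg: SimConfig) -> SimTruth:
    """First emulsion: load Poisson(barcode_cpb) random barcodes per bead.

    Beads with no barcode are unenriched; beads with two or more are
    polyclonal at the loading level.
    """
    rng = stage_rng(cfg.seed, "beads")
    counts = rng.poisson(cfg.barcode_cpb, size=cfg.n_beads)
    total = int(counts.sum())
    flat = rng.integers(0, 4, size=(total, cfg.barcode_length), dtype=np.uint8)
    truth = SimTruth()
    pos = 0
    for bead_id in range(cfg.n_beads):
        k = int(counts[bead_id])
        truth.bead_barcodes[bead_id] = [
            decode_seq(flat[pos + j]) for j in range(k)
        ]
        pos += k
    return truth


def simulate_phasing_run(
    cfg: SimConfig,
    reference: Reference,
    truth: SimTruth,
) -> tuple[list[ReadPair], SimTruth]:
    """Second emulsion: droplets pair one enriched bead with fragments.

    Each of ``cfg.n_droplets`` droplets receives one distinct enriched
    bead and a Poisson(``fragment_cpb``) number of fragments drawn from
    ``species_abundances``.  Every fragment templates each target; each
    amplicon emits Poisson(``reads_per_amplicon``) read pairs.  Read 1 is
    handle + barcode + handle (a polyclonal bead contributes each read's
    barcode uniformly at random from its set); read 2 is primer + the
    species' variable region.  Substitution errors are applied to both.
    """
    if not reference.species:
        raise InvalidInputError("reference has no species")
    rng = stage_rng(cfg.seed, "phasing")
    enriched = truth.enriched_beads()
    if len(enriched) < cfg.n_droplets:
        raise InvalidInputError(
            f"need {cfg.n_droplets} enriched beads, have {len(enriched)}"
        )
    chosen = rng.choice(len(enriched), size=cfg.n_droplets, replace=False)
    species_ids = reference.species_ids
    by_species = {sp.species_id: sp for sp in reference.species}
    abund = np.asarray(cfg.species_abundances, dtype=float)
    if len(abund) != len(species_ids):
        raise InvalidInputError(
            "species_abundances length does not match reference species count"
        )

    reads: list[ReadPair] = []
    fragment_counter = 0
    read_counter = 0
    err = cfg.substitution_error_rate
    for droplet_id in range(cfg.n_droplets):
        bead_id = enriched[int(chosen[droplet_id])]
        bead_bcs = truth.bead_barcodes[bead_id]
        n_frag = int(rng.poisson(cfg.fragment_cpb))
        frag_species = rng.choice(len(species_ids), size=n_frag, p=abund)
        contents: list[tuple[str, int]] = []
        for fs in frag_species:
            sid = species_ids[int(fs)]
            fragment_id = fragment_counter
            fragment_counter += 1
            contents.append((sid, fragment_id))
            for tid in reference.target_ids:
                template2 = (
                    reference.target_primers[tid]
                    + by_species[sid].target_sequences[tid]
                )
                n_reads = int(rng.poisson(cfg.reads_per_amplicon))
                for _ in range(n_reads):
                    if len(bead_bcs) == 1:
                        bc = bead_bcs[0]
                    else:
                        bc = bead_bcs[int(rng.integers(len(bead_bcs)))]
                    seq1 = mutate_sequence(
                        cfg.handle_5p + bc + cfg.handle_3p, err, rng
                    )
                    seq2 = mutate_sequence(template2, err, rng)
                    rid = f"r{read_counter:08d}"
                    read_counter += 1
                    reads.append(
                        ReadPair(
                            read_id=rid,
                            seq1=seq1,
                            seq2=seq2,
                            qual1="I" * len(seq1),
                            qual2="I" * len(seq2),
                        )
                    )
                    truth.read_origins[rid] = ReadOrigin(
                        droplet_id, tid, sid, bc, fragment_id
                    )
        truth.droplet_contents[droplet_id] = (bead_id, contents)
    return reads, truth


def simulate_sorting_run(
    cfg: SimConfig,
    n_wells: int,
    well_tags: list[str],
    truth: SimTruth,
    reads_per_well: float = 100.0,
) -> tuple[list[ReadPair], SortingTruth]:
    """Sorting experiment: one enriched bead per well, tagged reads out.

    Each well's reads are ``well_tag + handle + barcode + handle`` with
    substitution errors; a polyclonal bead contributes each read's
    barcode uniformly at random from its set.
    """
    if n_wells > len(well_tags):
        raise InvalidInputError(
            f"{n_wells} wells but only {len(well_tags)} tags"
        )
    rng = stage_rng(cfg.seed, "sorting")
    enriched = truth.enriched_beads()
    if len(enriched) < n_wells:
        raise InvalidInputError(
            f"need {n_wells} enriched beads, have {len(enriched)}"
        )
    chosen = rng.choice(len(enriched), size=n_wells, replace=False)
    sorting = SortingTruth(bead_barcodes=truth.bead_barcodes)
    reads: list[ReadPair] = []
    err = cfg.substitution_error_rate
    read_counter = 0
    for well_id in range(n_wells):
        bead_id = enriched[int(chosen[well_id])]
        sorting.well_beads[well_id] = bead_id
        bead_bcs = truth.bead_barcodes[bead_id]
        n_reads = int(rng.poisson(reads_per_well))
        for _ in range(n_reads):
            if len(bead_bcs) == 1:
                bc = bead_bcs[0]
            else:
                bc = bead_bcs[int(rng.integers(len(bead_bcs)))]
            template = well_tags[well_id] + cfg.handle_5p + bc + cfg.handle_3p
            seq = mutate_sequence(template, err, rng)
            rid = f"s{read_counter:08d}"
            read_counter += 1
            reads.append(
                ReadPair(read_id=rid, seq1=seq, qual1="I" * len(seq))
            )
            sorting.read_origins[rid] = (well_id, bead_id, bc)
    return reads, sorting
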