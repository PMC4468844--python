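"""File I/O: FASTQ/FASTA via Biopython, tables via pandas, manifests as JSON."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .barcodes import ReadPair
from .simulate import Reference, SimTruth, SpeciesReference


def write_fastq(reads: Iterable[ReadPair], path, mate: int = 1) -> None:
    """Write one mate of each read as plain 4-line FASTQ."""
    with open(path, "w") as fh:
        for r in reads:
            seq = r.seq1 if mate == 1 else r.seq2
            qual = (r.qual1 if mate == 1 else r.qual2) or "I" * len(seq)
            fh.write(f"@{r.read_id}\n{seq}\n+\n{qual}\n")


def write_fastq_pair(reads: Sequence[ReadPair], path1, path2) -> None:
    write_fastq(reads, path1, mate=1)
    write_fastq(reads, path2, mate=2)


def read_fastq_pair(path1, path2) -> list[ReadPair]:
    """Read matched-order paired FASTQ files into ReadPair records."""
    out = []
    it1 = SeqIO.parse(str(path1), "fastq")
    it2 = SeqIO.parse(str(path2), "fastq")
    for rec1, rec2 in zip(it1, it2):
        if rec1.id != rec2.id:
            raise ValueError(
                f"read order mismatch: {rec1.id} vs {rec2.id}"
            )
        out.append(
            ReadPair(read_id=rec1.id, seq1=str(rec1.seq), seq2=str(rec2.seq))
        )
    return out


def read_fastq_single(path) -> list[ReadPair]:
    return [
        ReadPair(read_id=rec.id, seq1=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_reference_fasta(reference: Reference, path) -> None:
    """Species sequences as ``>species|target`` records."""
    with open(path, "w") as fh:
        for sp in reference.species:
            for tid, seq in sp.target_sequences.items():
                fh.write(f">{sp.species_id}|{tid}\n{seq}\n")


def write_primer_fasta(reference: Reference, path) -> None:
    with open(path, "w") as fh:
        for tid, primer in reference.target_primers.items():
            fh.write(f">{tid}\n{primer}\n")


def read_reference_fasta(species_path, primer_path) -> Reference:
    """Inverse of write_reference_fasta/write_primer_fasta."""
    primers = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(primer_path), "fasta")
    }
    per_species: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(species_path), "fasta"):
        sid, tid = rec.id.split("|", 1)
        per_species.setdefault(sid, {})[tid] = str(rec.seq)
    species = tuple(
        SpeciesReference(species_id=sid, target_sequences=seqs)
        for sid, seqs in per_species.items()
    )
    return Reference(species=species, target_primers=primers)


def write_truth_tsv(truth: SimTruth, path) -> None:
    df = pd.DataFrame(
        truth.to_rows(),
        columns=[
            "read_id",
            "droplet_id",
            "bead_id",
            "species_id",
            "target_id",
            "true_barcode",
            "fragment_id",
        ],
    )
    df.to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"true_barcode": str})


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_manifest(path, config: dict, seed: int) -> None:
    """Run manifest: config, its hash and the seed (no timestamps, so a
    rerun with the same config is byte-identical)."""
    from . import __version__

    manifest = {
        "package": "beadphase",
        "version": __version__,
        "seed": seed,
        "config": config,
        "config_hash": config_hash(config),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
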