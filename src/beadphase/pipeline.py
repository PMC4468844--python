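"""End-to-end orchestration of the phasing and sorting analyses.

``run_phasing_pipeline`` chains barcode extraction -> barcode clustering
-> target assignment -> filtering -> variant sub-clustering -> consensus
-> classification -> phasing summary, conserving and reporting read
counts at every stage.  ``run_sorting_pipeline`` is the well-plate
variant: demultiplex by well tag, cluster barcodes per well, and label
each well's clonality.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .barcodes import (
    BarcodeCluster,
    BarcodeObservation,
    ReadLayout,
    ReadPair,
    barcode_counts,
    classify_well_clonality,
    cluster_barcodes,
    demultiplex_wells,
    extract_barcode,
)
from .classify import (
    TaxonAssignment,
    abundance_table,
    build_reference_index,
    classify_consensus,
)
from .consensus import (
    AmpliconConsensus,
    FilterReport,
    VariantGroup,
    assign_reads_to_targets,
    call_consensus,
    classify_amplification_clonality,
    dominant_fraction,
    filter_clusters,
    subcluster_reads,
)
from .phasing import ClusterCall, PhasingSummary, summarize_phasing
from .simulate import Reference

__all__ = ["Thresholds", "PhasingRunResult", "run_phasing_pipeline",
           "SortingRunResult", "run_sorting_pipeline"]


@dataclass(frozen=True)
class Thresholds:
    """All tunable mismatch/support thresholds of the analysis."""

    barcode_max_mismatch: int = 2
    handle_max_mismatch: int = 4
    primer_max_mismatch: int = 2
    well_tag_max_mismatch: int = 2
    min_reads_per_target: int = 3
    min_cluster_reads: int = 5
    subcluster_mismatch_fraction: float = 0.02
    dominant_threshold: float = 0.90
    well_min_fraction: float = 0.10
    k: int = 8
    margin: float = 0.05
    n_shuffles: int = 100


@dataclass
class PhasingRunResult:
    clusters: list[BarcodeCluster]
    read_to_cluster: dict[str, str]
    variant_groups: dict[str, dict[str, list[VariantGroup]]]
    consensuses: list[AmpliconConsensus]
    assignments: list[TaxonAssignment]
    calls: list[ClusterCall]
    summary: PhasingSummary
    filter_report: FilterReport
    stage_counts: dict[str, int] = field(default_factory=dict)


def run_phasing_pipeline(
    reads: Sequence[ReadPair],
    reference: Reference,
    layout: ReadLayout,
    thresholds: Thresholds = Thresholds(),
    seed: int = 0,
    outdir: Optional[str | Path] = None,
) -> PhasingRunResult:
    """Run the full phasing analysis on paired reads.

    Returns every intermediate (clusters, consensuses, assignments,
    per-cluster calls) plus the phasing summary; if ``outdir`` is given,
    all artifacts are written there as plain TSV/FASTA/JSON.
    """
    th = thresholds
    t1, t2 = list(reference.target_ids)[:2]

    # 1. barcode extraction
    observations: list[BarcodeObservation] = []
    read2: dict[str, str] = {}
    n_rejected = 0
    for read in reads:
        res = extract_barcode(read, layout)
        if isinstance(res, BarcodeObservation):
            observations.append(res)
            read2[read.read_id] = read.seq2
        else:
            n_rejected += 1

    # 2. barcode clustering
    clusters = cluster_barcodes(
        barcode_counts(observations), max_mismatch=th.barcode_max_mismatch
    )
    barcode_to_cluster = {
        b: cl.cluster_id for cl in clusters for b in cl.members
    }
    read_to_cluster = {
        obs.read_id: barcode_to_cluster[obs.barcode] for obs in observations
    }

    # 3. per-cluster target assignment
    cluster_reads: dict[str, list[tuple[str, str]]] = defaultdict(list)
    for obs in observations:
        cluster_reads[read_to_cluster[obs.read_id]].append(
            (obs.read_id, read2[obs.read_id])
        )
    groups: dict[str, dict[str, list[tuple[str, str]]]] = {}
    n_unassigned = 0
    for cid, creads in cluster_reads.items():
        assigned, unassigned = assign_reads_to_targets(
            creads, reference.target_primers, th.primer_max_mismatch
        )
        n_unassigned += len(unassigned)
        groups[cid] = {tid: rs for tid, rs in assigned.items() if rs}

    # 4. support filtering
    retained, filter_report = filter_clusters(
        groups,
        min_reads_per_target=th.min_reads_per_target,
        min_cluster_reads=th.min_cluster_reads,
    )

    # 5-7. sub-cluster, consensus, classify
    index = build_reference_index(reference, k=th.k)
    variant_groups: dict[str, dict[str, list[VariantGroup]]] = {}
    consensuses: list[AmpliconConsensus] = []
    assignments: list[TaxonAssignment] = []
    calls: list[ClusterCall] = []
    for cid in sorted(retained):
        per_target: dict[str, list[VariantGroup]] = {}
        cluster_calls: dict[str, str] = {}
        hit_lists: dict[str, frozenset] = {}
        for tid, rs in sorted(retained[cid].items()):
            vgs = subcluster_reads(
                [seq for _, seq in rs],
                max_mismatch_fraction=th.subcluster_mismatch_fraction,
            )
            per_target[tid] = vgs
            cons = call_consensus(vgs[0].reads)
            consensuses.append(
                AmpliconConsensus(
                    cluster_id=cid,
                    target_id=tid,
                    consensus=cons,
                    support=vgs[0].size,
                    dominant_fraction=dominant_fraction(vgs),
                )
            )
            assignment = classify_consensus(
                cons, index, tid, margin=th.margin, cluster_id=cid
            )
            assignments.append(assignment)
            cluster_calls[tid] = assignment.best_call
            hit_lists[tid] = assignment.hit_species
        label = classify_amplification_clonality(
            per_target, dominant_threshold=th.dominant_threshold
        )
        variant_groups[cid] = per_target
        calls.append(
            ClusterCall(
                cluster_id=cid,
                calls=cluster_calls,
                monoclonal=(label == "monoclonal"),
                hit_lists=hit_lists,
            )
        )

    # 8. summary
    summary = summarize_phasing(
        calls, t1, t2, n_shuffles=th.n_shuffles, seed=seed
    )
    stage_counts = {
        "reads_in": len(reads),
        "barcode_rejected": n_rejected,
        "barcode_extracted": len(observations),
        "target_unassigned": n_unassigned,
        "filtered_out": filter_report.n_reads_dropped,
        "reads_analyzed": len(observations)
        - n_unassigned
        - filter_report.n_reads_dropped,
        "clusters_total": len(clusters),
        "clusters_retained": len(retained),
    }
    result = PhasingRunResult(
        clusters=clusters,
        read_to_cluster=read_to_cluster,
        variant_groups=variant_groups,
        consensuses=consensuses,
        assignments=assignments,
        calls=calls,
        summary=summary,
        filter_report=filter_report,
        stage_counts=stage_counts,
    )
    if outdir is not None:
        _write_phasing_artifacts(result, Path(outdir))
    return result


def _write_phasing_artifacts(result: PhasingRunResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "cluster_id": cl.cluster_id,
                "seed_barcode": cl.seed_barcode,
                "n_distinct_barcodes": cl.n_distinct,
                "n_reads": cl.total_reads,
            }
            for cl in result.clusters
        ]
    ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(result.read_to_cluster.items()),
        columns=["read_id", "cluster_id"],
    ).to_csv(outdir / "read_assignments.tsv", sep="\t", index=False)
    with open(outdir / "consensus.fasta", "w") as fh:
        for c in result.consensuses:
            fh.write(
                f">{c.cluster_id}|{c.target_id}|support={c.support}\n"
                f"{c.consensus}\n"
            )
    pd.DataFrame(
        [
            {
                "cluster_id": a.cluster_id,
                "target_id": a.target_id,
                "best_call": a.best_call,
                "hit_list": ",".join(sp for sp, _ in a.hit_list),
                "scores": ",".join(f"{sc:.4f}" for _, sc in a.hit_list),
            }
            for a in result.assignments
        ]
    ).to_csv(outdir / "taxa.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "cluster_id": c.cluster_id,
                "monoclonal": c.monoclonal,
                **{f"call_{t}": s for t, s in sorted(c.calls.items())},
            }
            for c in result.calls
        ]
    ).to_csv(outdir / "clonality.tsv", sep="\t", index=False)
    payload = {
        "summary": result.summary.to_dict(),
        "stage_counts": result.stage_counts,
        "filter_report": asdict(result.filter_report),
    }
    (outdir / "summary.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n"
    )


@dataclass
class SortingRunResult:
    well_table: pd.DataFrame
    monoclonal_fraction: Optional[float]
    n_unassigned: int


def run_sorting_pipeline(
    reads: Sequence[ReadPair],
    well_tags: list[str],
    layout: ReadLayout,
    thresholds: Thresholds = Thresholds(),
    outdir: Optional[str | Path] = None,
) -> SortingRunResult:
    """Well-plate monoclonality analysis.

    Demultiplexes reads to wells by tag, clusters each well's barcodes,
    labels wells empty/monoclonal/polyclonal, and reports the monoclonal
    fraction among non-empty wells.
    """
    th = thresholds
    by_well, unassigned = demultiplex_wells(
        list(reads), well_tags, max_mismatch=th.well_tag_max_mismatch
    )
    rows = []
    for well, wreads in sorted(by_well.items()):
        observations = []
        for read in wreads:
            res = extract_barcode(read, layout)
            if isinstance(res, BarcodeObservation):
                observations.append(res)
        clusters = cluster_barcodes(
            barcode_counts(observations),
            max_mismatch=th.barcode_max_mismatch,
        )
        label = classify_well_clonality(
            clusters, min_fraction=th.well_min_fraction
        )
        rows.append(
            {
                "well": well,
                "n_reads": len(wreads),
                "n_barcodes_extracted": len(observations),
                "n_clusters": len(clusters),
                "label": label,
            }
        )
    table = pd.DataFrame(rows)
    nonempty = table[table["label"] != "empty"]
    mono = (
        float((nonempty["label"] == "monoclonal").mean())
        if len(nonempty)
        else None
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "wells.tsv", sep="\t", index=False)
        (outdir / "sorting_summary.json").write_text(
            json.dumps(
                {
                    "n_wells": len(table),
                    "n_nonempty": int(len(nonempty)),
                    "monoclonal_fraction": mono,
                    "n_unassigned_reads": len(unassigned),
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
    return SortingRunResult(
        well_table=table,
        monoclonal_fraction=mono,
        n_unassigned=len(unassigned),
    )
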