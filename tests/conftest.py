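"""Shared fixtures: simulated runs at two scales plus pipeline results."""

from collections import Counter, defaultdict

import pytest

import beadphase as bp


def make_layout(cfg: bp.SimConfig, well_tag_length: int = 0) -> bp.ReadLayout:
    return bp.ReadLayout(
        handle_5p=cfg.handle_5p,
        handle_3p=cfg.handle_3p,
        barcode_length=cfg.barcode_length,
        well_tag_length=well_tag_length,
    )


@pytest.fixture(scope="session")
def reference():
    return bp.make_reference(n_species=4, divergence=0.05, seed=1)


@pytest.fixture(scope="session")
def sim_run(reference):
    """Full-scale run at the study's design point (5,000 droplets,
    c.p.b. 0.1 for barcodes and fragments, 0.5% substitution errors)."""
    cfg = bp.SimConfig(seed=1)
    truth = bp.simulate_bead_library(cfg)
    reads, truth = bp.simulate_phasing_run(cfg, reference, truth)
    return cfg, reads, truth


@pytest.fixture(scope="session")
def pipeline_result(sim_run, reference):
    cfg, reads, _ = sim_run
    return bp.run_phasing_pipeline(
        reads, reference, make_layout(cfg), seed=1
    )


@pytest.fixture(scope="session")
def clean_run(reference):
    """Small error-free run: every read is an exact copy of its template."""
    cfg = bp.SimConfig(
        n_beads=6_000,
        n_droplets=400,
        substitution_error_rate=0.0,
        seed=7,
    )
    truth = bp.simulate_bead_library(cfg)
    reads, truth = bp.simulate_phasing_run(cfg, reference, truth)
    return cfg, reads, truth


@pytest.fixture(scope="session")
def clean_pipeline_result(clean_run, reference):
    cfg, reads, _ = clean_run
    return bp.run_phasing_pipeline(
        reads, reference, make_layout(cfg), seed=7
    )


def cluster_truth_lookup(result, truth):
    """Map each cluster to its majority droplet and per-target truth species."""
    cluster_reads = defaultdict(list)
    for rid, cid in result.read_to_cluster.items():
        cluster_reads[cid].append(rid)
    info = {}
    for cid, rids in cluster_reads.items():
        droplet = Counter(
            truth.read_origins[r].droplet_id for r in rids
        ).most_common(1)[0][0]
        species_per_target = {}
        for tid in ("16S.1", "16S.2"):
            votes = Counter(
                truth.read_origins[r].species_id
                for r in rids
                if truth.read_origins[r].target_id == tid
            )
            if votes:
                species_per_target[tid] = votes.most_common(1)[0][0]
        info[cid] = (droplet, species_per_target)
    return info
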