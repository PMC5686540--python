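"""End-to-end orchestration: universe -> reference package -> placed reads
-> taxonomic profiles.

The reference build mirrors the curated-database workflow: screen genomes
for the single-copy markers, subsample to two genomes per genus (the focal
genus exempt, as its whole isolate collection is the point), align each
marker, purge genomes with aberrant terminal branches, and build the
concatenated-alignment reference tree whose topology is shared by every
marker package so node structure stays comparable across markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import placer, profiler, refdb
from .align import Alignment
from .simdata import FOCAL_GENUS, ReferenceUniverse


@dataclass
class ReferenceBuild:
    package: refdb.ReferencePackage
    database: placer.Stage1Database
    engines: dict[int, placer.PlacementEngine]
    discarded: dict[str, list[str]]
    removal_log: list[set[str]] = field(default_factory=list)


def build_reference(universe: ReferenceUniverse, k_per_genus: int = 2,
                    curation_threshold: float = 5.0, seed: int = 0) -> ReferenceBuild:
    """Screen, curate and package the reference side of the pipeline."""
    cfg = universe.config
    # training profiles from the annotated marker sets
    train_profiles: dict[int, refdb.Profile] = {}
    for m in range(1, cfg.n_markers + 1):
        seqs = {g.genome_id: universe.marker_truth[(g.genome_id, m)] for g in universe.genomes}
        aln = Alignment.from_sequences(seqs)
        train_profiles[m] = refdb.build_profiles(aln, marker_id=m)

    hits, discarded = refdb.screen_markers(universe.genomes, train_profiles)
    retained_ids = sorted({h.genome_id for h in hits})
    retained = [g for g in universe.genomes if g.genome_id in retained_ids]
    curated = refdb.subsample_genera(retained, universe.taxonomy, k=k_per_genus,
                                     keep_genera={FOCAL_GENUS})
    curated_ids = {g.genome_id for g in curated}
    gene_seq = {g.genome_id: dict(g.proteins) for g in universe.genomes}
    hit_gene = {(h.genome_id, h.marker_id): h.gene_id for h in hits}

    marker_alignments: dict[int, Alignment] = {}
    for m in range(1, cfg.n_markers + 1):
        seqs = {gid: gene_seq[gid][hit_gene[(gid, m)]] for gid in sorted(curated_ids)}
        marker_alignments[m] = refdb.align_marker(seqs)

    kept_ids, _trees, removal_log = refdb.curate_by_branch_length(
        marker_alignments, threshold=curation_threshold)
    if set(kept_ids) != curated_ids:
        marker_alignments = {
            m: Alignment([i for i in a.ids if i in set(kept_ids)],
                         a.codes[[r for r, i in enumerate(a.ids) if i in set(kept_ids)]])
            for m, a in marker_alignments.items()
        }

    # shared reference topology from the concatenated supermatrix
    supermatrix = refdb.concatenate([marker_alignments[m] for m in sorted(marker_alignments)])
    D, labels = refdb.alignment_distances(supermatrix)
    ref_tree = refdb.build_tree_nj(D, labels)
    trees = {m: ref_tree.copy().number_edges() for m in marker_alignments}

    taxonomy = {gid: universe.taxonomy[gid] for gid in kept_ids}
    calibration = placer.calibrate_karlin_altschul(seed=seed)
    package = refdb.build_reference_package(marker_alignments, trees, taxonomy,
                                            calibration=calibration, seed=seed)
    proteins = []
    marker_of_gene = {(h.genome_id, h.gene_id): h.marker_id for h in hits}
    for g in universe.genomes:
        if g.genome_id not in set(kept_ids):
            continue
        for gene_id, seq in g.proteins:
            proteins.append((gene_id, marker_of_gene.get((g.genome_id, gene_id)), seq))
    database = placer.Stage1Database(proteins, calibration=calibration, seed=seed)
    engines = {m: placer.PlacementEngine(package.markers[m]) for m in package.markers}
    return ReferenceBuild(package=package, database=database, engines=engines,
                          discarded=discarded, removal_log=removal_log)


@dataclass
class SampleResult:
    sample_id: str
    n_reads: int
    n_stage1: int
    n_stage2: int
    placements: dict[int, list[placer.Placement]]
    filter_hits: list[placer.FilterHit]


def place_sample(build: ReferenceBuild, reads: dict[str, str], sample_id: str,
                 evalue1: float = 1e-5, evalue2: float = 1e-10,
                 max_keep: int = 20, seed: int = 0) -> SampleResult:
    """Run one sample's reads through both filters, alignment and placement."""
    candidates = placer.stage1_search(reads, build.database, evalue_max=evalue1)
    hits = placer.stage2_profile_filter(candidates, reads, build.package,
                                        evalue_max=evalue2, seed=seed)
    placements: dict[int, list[placer.Placement]] = {}
    for h in hits:
        prof = build.package.markers[h.marker_id].profile
        aligned = placer.align_to_profile(h.read_id, reads[h.read_id], prof,
                                          marker_id=h.marker_id)
        cols = aligned.col_map[aligned.col_map >= 0]
        h.aligned_columns = (int(cols.min()), int(cols.max()) + 1)
        pl = build.engines[h.marker_id].place(aligned, max_keep=max_keep)
        placements.setdefault(h.marker_id, []).append(pl)
    return SampleResult(sample_id=sample_id, n_reads=len(reads),
                        n_stage1=len(candidates), n_stage2=len(hits),
                        placements=placements, filter_hits=hits)


def branch_abundance(build: ReferenceBuild,
                     sample_results: list[SampleResult]) -> profiler.BranchAbundance:
    """Collect per-read placement records into a BranchAbundance container."""
    edge_leaves = {m: eng.edge_leaves for m, eng in build.engines.items()}
    ba = profiler.BranchAbundance(taxonomy=build.package.taxonomy,
                                  edge_leaves=edge_leaves)
    for sr in sample_results:
        for m, pls in sr.placements.items():
            for pl in pls:
                tot = sum(r[2] for r in pl.records)
                if tot <= 0:
                    continue
                edges = np.array([r[0] for r in pl.records], dtype=int)
                masses = np.array([r[2] / tot for r in pl.records])
                ba.add(profiler.ReadPlacementRecord(pl.read_id, sr.sample_id, m,
                                                    edges, masses))
    return ba


def run_study(universe: ReferenceUniverse, compositions: dict[str, dict[str, float]],
              n_reads_per_sample: int, read_len: int = 40, decoy_frac: float = 0.05,
              seed: int = 0, build: ReferenceBuild | None = None
              ) -> tuple[profiler.BranchAbundance, pd.DataFrame, list[SampleResult], ReferenceBuild]:
    """Simulate reads for every sample and push them through the pipeline."""
    from .simdata import simulate_reads

    if build is None:
        build = build_reference(universe, seed=seed)
    truths = []
    results = []
    for sid in sorted(compositions):
        reads, truth = simulate_reads(universe, compositions[sid], n_reads_per_sample,
                                      read_len=read_len, decoy_frac=decoy_frac,
                                      seed=seed, sample_id=sid)
        truths.append(truth)
        results.append(place_sample(build, reads, sid, seed=seed))
    ba = branch_abundance(build, results)
    return ba, pd.concat(truths, ignore_index=True), results, build
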