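"""Turn placement mass into rank-resolved taxonomic profiles.

Each placed read carries up to 20 (edge, likelihood-weight) records whose
kept mass is renormalized to 1.  At a given rank every edge maps to the
taxon shared by all leaves of its distal subtree (or to no taxon if the
subtree spans several).  A read is assigned to the taxon holding a majority
(> ``consensus_frac``, default 0.5) of its mass, otherwise it counts as
"unclassified" at that rank.  Per-sample profiles average the per-marker
relative abundances with equal marker weight, which corrects for unequal
marker detection; a pooled mode (all markers' reads in one pool) is
available behind a flag.

Focal-genus reads are further binned onto sub-OTU clades with the same
consensus rule; reads with a genus-level assignment but no clade consensus
are the "failed to classify" fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RANKS = ("phylum", "family", "genus", "clade")
UNCLASSIFIED = "unclassified"


@dataclass
class ReadPlacementRecord:
    read_id: str
    sample_id: str
    marker_id: int
    edges: np.ndarray   # kept edge numbers
    masses: np.ndarray  # kept like-weight-ratios renormalized to sum 1


@dataclass
class BranchAbundance:
    """Placement mass per edge, with the per-read records that produced it.

    ``edge_leaves[marker_id]`` gives, for every edge number, the frozenset of
    genome ids in that edge's distal subtree (the reference trees share their
    taxonomy but may differ per marker).
    """

    taxonomy: dict[str, tuple[str, str, str, str | None]]
    edge_leaves: dict[int, list[frozenset]]
    records: list[ReadPlacementRecord] = field(default_factory=list)
    _taxa_cache: dict = field(default_factory=dict, repr=False)

    def add(self, rec: ReadPlacementRecord) -> None:
        self.records.append(rec)

    @property
    def samples(self) -> list[str]:
        return sorted({r.sample_id for r in self.records})

    def matrix(self, marker_id: int) -> pd.DataFrame:
        """Edges x samples placement-mass matrix for one marker."""
        samples = self.samples
        n_edges = len(self.edge_leaves[marker_id])
        M = np.zeros((n_edges, len(samples)))
        col = {s: i for i, s in enumerate(samples)}
        for r in self.records:
            if r.marker_id != marker_id:
                continue
            M[r.edges, col[r.sample_id]] += r.masses
        return pd.DataFrame(M, columns=samples)

    # -- edge -> taxon maps ------------------------------------------------
    def edge_taxa(self, marker_id: int, rank: str) -> list[str | None]:
        if rank not in RANKS:
            raise ValueError(f"no taxon map for rank {rank!r}")
        key = (marker_id, rank)
        if key in self._taxa_cache:
            return self._taxa_cache[key]
        level = RANKS.index(rank)
        out: list[str | None] = []
        for leaves in self.edge_leaves[marker_id]:
            taxa = {self.taxonomy[g][level] for g in leaves}
            taxa.discard(None)
            out.append(taxa.pop() if len(taxa) == 1 else None)
        self._taxa_cache[key] = out
        return out


@dataclass
class AbundanceProfile:
    rank: str
    data: pd.DataFrame  # taxa (rows, incl. "unclassified") x samples; columns sum to 1


def _assign_read(rec: ReadPlacementRecord, taxa: list[str | None],
                 consensus_frac: float) -> str:
    shares: dict[str, float] = {}
    for e, m in zip(rec.edges, rec.masses):
        t = taxa[e]
        if t is not None:
            shares[t] = shares.get(t, 0.0) + float(m)
    if shares:
        best = max(sorted(shares), key=lambda t: shares[t])
        if shares[best] > consensus_frac:
            return best
    return UNCLASSIFIED


def classify_mass(ba: BranchAbundance, rank: str, consensus_frac: float = 0.5,
                  pooled: bool = False) -> AbundanceProfile:
    """Rank-level relative abundances per sample, with unclassified mass.

    Per marker, assigned-read counts are divided by that marker's placed-read
    total; the profile averages the markers present in the sample with equal
    weight (``pooled=True`` instead normalizes one pooled read count).
    """
    if rank not in RANKS:
        raise ValueError(f"no taxon map for rank {rank!r}")
    # counts[(sample, marker)][taxon]
    counts: dict[tuple[str, int], dict[str, float]] = {}
    for rec in sorted(ba.records, key=lambda r: (r.sample_id, r.marker_id, r.read_id)):
        taxa = ba.edge_taxa(rec.marker_id, rank)
        label = _assign_read(rec, taxa, consensus_frac)
        d = counts.setdefault((rec.sample_id, rec.marker_id), {})
        d[label] = d.get(label, 0.0) + 1.0
    samples = ba.samples
    all_taxa = sorted({t for d in counts.values() for t in d} - {UNCLASSIFIED})
    rows = all_taxa + [UNCLASSIFIED]
    data = pd.DataFrame(0.0, index=rows, columns=samples)
    for s in samples:
        marker_frames = []
        for (ss, m), d in counts.items():
            if ss != s:
                continue
            tot = sum(d.values())
            marker_frames.append(pd.Series(d) / tot if not pooled else pd.Series(d))
        if not marker_frames:
            continue
        if pooled:
            pooled_counts = pd.concat(marker_frames, axis=1).fillna(0.0).sum(axis=1)
            profile = pooled_counts / pooled_counts.sum()
        else:
            profile = pd.concat(marker_frames, axis=1).fillna(0.0).mean(axis=1)
        data.loc[profile.index, s] = profile.values
    return AbundanceProfile(rank=rank, data=data)


def bin_clades(ba: BranchAbundance, focal_genus: str,
               clade_map: dict[str, set[str]] | None = None,
               consensus_frac: float = 0.5) -> tuple[AbundanceProfile, pd.Series]:
    """Bin focal-genus reads onto sub-OTU clades.

    ``clade_map`` maps clade name -> genome ids (default: derived from the
    package taxonomy); the clade subtrees must be disjoint.  Returns the
    clade profile over focal reads per sample (including the
    within-genus-unclassified row) and the per-sample fraction of
    genus-assigned reads that failed to reach clade consensus.
    """
    if clade_map is None:
        clade_map = {}
        for gid, (_p, _f, genus, clade) in ba.taxonomy.items():
            if genus == focal_genus and clade:
                clade_map.setdefault(clade, set()).add(gid)
    names = sorted(clade_map)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            overlap = clade_map[a] & clade_map[b]
            if overlap:
                raise ValueError(f"overlapping clade subtrees {a}/{b}: {sorted(overlap)}")
    genome_clade = {g: c for c, gs in clade_map.items() for g in gs}

    # per-marker edge -> clade maps (pure subtrees only)
    clade_taxa: dict[int, list[str | None]] = {}
    for m, leaf_sets in ba.edge_leaves.items():
        out: list[str | None] = []
        for leaves in leaf_sets:
            cl = {genome_clade.get(g) for g in leaves}
            out.append(cl.pop() if len(cl) == 1 and None not in cl else None)
        clade_taxa[m] = out

    counts: dict[tuple[str, int], dict[str, float]] = {}
    genus_only: dict[str, float] = {}
    genus_total: dict[str, float] = {}
    for rec in sorted(ba.records, key=lambda r: (r.sample_id, r.marker_id, r.read_id)):
        gtaxa = ba.edge_taxa(rec.marker_id, "genus")
        if _assign_read(rec, gtaxa, consensus_frac) != focal_genus:
            continue
        genus_total[rec.sample_id] = genus_total.get(rec.sample_id, 0.0) + 1.0
        label = _assign_read(rec, clade_taxa[rec.marker_id], consensus_frac)
        if label == UNCLASSIFIED:
            genus_only[rec.sample_id] = genus_only.get(rec.sample_id, 0.0) + 1.0
        d = counts.setdefault((rec.sample_id, rec.marker_id), {})
        d[label] = d.get(label, 0.0) + 1.0
    samples = sorted(genus_total)
    rows = names + [UNCLASSIFIED]
    data = pd.DataFrame(0.0, index=rows, columns=samples)
    for s in samples:
        frames = [pd.Series(d) / sum(d.values()) for (ss, m), d in counts.items() if ss == s]
        if frames:
            profile = pd.concat(frames, axis=1).fillna(0.0).mean(axis=1)
            data.loc[profile.index, s] = profile.values
    failed = pd.Series({s: genus_only.get(s, 0.0) / genus_total[s] for s in samples},
                       name="clade_unclassified_frac")
    return AbundanceProfile(rank="clade", data=data), failed


def aggregate_timecourse(profile: AbundanceProfile, metadata: pd.DataFrame) -> pd.DataFrame:
    """Tidy long table (sample, date, treatment, taxon, abundance)."""
    meta = metadata.set_index("sample_id")
    missing = [s for s in profile.data.columns if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing[:5]}")
    rows = []
    for s in profile.data.columns:
        for taxon, ab in profile.data[s].items():
            rows.append({"sample_id": s, "date": meta.loc[s, "date"],
                         "treatment": meta.loc[s, "treatment"],
                         "taxon": taxon, "abundance": float(ab)})
    return pd.DataFrame(rows)
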