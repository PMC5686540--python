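"""Seeded generators for every input the pipeline consumes.

The generator emulates the structure of a leaf-litter metagenomics study:

* a multi-phylum reference universe in which every genome carries one copy of
  each of 29 single-copy protein marker genes plus unrelated "decoy" genes;
* a focal genus whose members fall into six well-separated clades that
  nevertheless share >=97% 16S rRNA identity (one OTU hiding microdiversity);
* protein read sets drawn as contiguous windows of marker genes, with a known
  truth table per read;
* an "8 time points x 3 treatments x 2 replicates" sampling design in which
  the focal genus responds multiplicatively to treatment and season;
* trait tables (GH/CBM domain counts with Brownian phylogenetic signal, and
  plate-assay degradation areas at two temperatures).

All randomness flows from one root seed through named substreams
(:func:`microdiv.util.rng_for`), so identical configurations give
byte-identical outputs.

Sequence evolution uses per-branch Poisson substitution counts (expected
events = branch length x sequence length) with a uniform replacement kernel:
enough to create phylogenetic signal without modelling rate heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import phylo
from .util import NUCLEOTIDES, decode_protein, rng_for

FOCAL_GENUS = "focal_genus"
CLADE_NAMES = ["IA", "IB", "IC", "IIA", "IIB", "III", "IV", "V", "VI", "VII"]
SIXTEEN_S_LEN = 1300

#: default GH/CBM family -> substrate-category map (example mapping; the real
#: Pfam family lists are an input in any non-synthetic analysis)
DEFAULT_FAMILY_MAP = {
    "GH5": "cellulose",
    "GH6": "cellulose",
    "GH9": "cellulose",
    "CBM2": "cellulose",
    "CBM3": "cellulose",
    "GH10": "xylan",
    "GH11": "xylan",
    "CBM4": "xylan",
    "GH3": "other",
    "GH13": "other",
}

DEFAULT_TREATMENT_EFFECT = {"control": 1.0, "drought": 1.202, "nitrogen": 0.828}

# branch-length scales (expected substitutions/site) for the background
# hierarchy.  Markers are conserved single-copy genes, so even cross-phylum
# sequences retain clear homology (~30-40% identity at these depths).
WITHIN_GENUS_STEM = 0.05
GENUS_STEM = 0.12
PHYLUM_STEM = 0.30


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class UniverseConfig:
    n_phyla: int = 3
    genera_per_phylum: int = 4
    genomes_per_genus: int = 3
    n_markers: int = 29
    marker_len: int = 120
    focal_clades: int = 6
    within_clade_div: float = 0.02
    between_clade_div: float = 0.20
    decoy_genes_per_genome: int = 5
    seed: int = 0

    def __post_init__(self):
        for name in ("n_phyla", "genera_per_phylum", "genomes_per_genus",
                     "n_markers", "marker_len", "focal_clades"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.decoy_genes_per_genome < 0:
            raise ValueError("decoy_genes_per_genome must be >= 0")
        if self.within_clade_div < 0 or self.between_clade_div <= 0:
            raise ValueError("divergences must be positive")
        if self.within_clade_div >= self.between_clade_div:
            raise ValueError("within_clade_div must be < between_clade_div")


@dataclass
class DesignConfig:
    time_points: int = 8
    treatments: tuple[str, ...] = ("control", "drought", "nitrogen")
    replicates: int = 2
    treatment_effect: dict = field(default_factory=lambda: dict(DEFAULT_TREATMENT_EFFECT))
    seasonal_amplitude: float = 0.0
    focal_baseline: float = 0.078
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.time_points < 1 or self.replicates < 1 or len(self.treatments) < 1:
            raise ValueError("counts must be >= 1")
        missing = [t for t in self.treatments if t not in self.treatment_effect]
        if missing:
            raise ValueError(f"treatment_effect missing entries for {missing}")
        if not 0 < self.focal_baseline < 1:
            raise ValueError("focal_baseline must be in (0, 1)")


@dataclass
class ReferenceUniverse:
    config: UniverseConfig
    genomes: list  # list[refdb.GenomeRecord]
    true_tree: phylo.Node
    taxonomy: dict[str, tuple[str, str, str, str | None]]
    marker_truth: dict[tuple[str, int], str]
    sixteen_s: dict[str, str]

    @property
    def genome_ids(self) -> list[str]:
        return [g.genome_id for g in self.genomes]

    @property
    def focal_ids(self) -> list[str]:
        return [gid for gid, tax in self.taxonomy.items() if tax[2] == FOCAL_GENUS]

    def clade_of(self, genome_id: str) -> str | None:
        return self.taxonomy[genome_id][3]

    def taxonomy_frame(self) -> pd.DataFrame:
        rows = [
            {"genome_id": gid, "phylum": t[0], "family": t[1], "genus": t[2],
             "clade": t[3] if t[3] is not None else ""}
            for gid, t in self.taxonomy.items()
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sequence evolution helpers
# ---------------------------------------------------------------------------

def random_protein(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 20, size=length).astype(np.int8)


def poisson_substitute(codes: np.ndarray, branch_len: float, rng: np.random.Generator,
                       k: int = 20) -> np.ndarray:
    """Apply ``Poisson(branch_len * L)`` substitution events, each replacing a
    uniformly chosen site with one of the other ``k - 1`` states."""
    out = codes.copy()
    n_events = rng.poisson(branch_len * len(codes))
    for _ in range(n_events):
        pos = int(rng.integers(len(codes)))
        shift = int(rng.integers(1, k))
        out[pos] = (out[pos] + shift) % k
    return out


def _evolve_on_tree(root: phylo.Node, root_seq: np.ndarray, rng: np.random.Generator,
                    rate_scale: float = 1.0, k: int = 20) -> dict[str, np.ndarray]:
    """Evolve a sequence down a tree; returns leaf-name -> codes."""
    seqs: dict[str, np.ndarray] = {}

    def walk(node: phylo.Node, seq: np.ndarray) -> None:
        if node.is_leaf:
            seqs[node.name] = seq
            return
        for child in node.children:
            walk(child, poisson_substitute(seq, child.length * rate_scale, rng, k=k))

    walk(root, root_seq)
    return seqs


def _join_random(subtrees: list[phylo.Node], stem: float, rng: np.random.Generator) -> phylo.Node:
    """Random sequential pairing of subtrees (birth-death-style topology)."""
    pool = list(subtrees)
    for t in pool:
        t.length = stem * float(rng.uniform(0.8, 1.2))
    while len(pool) > 1:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        joint = phylo.Node(length=0.3 * stem * float(rng.uniform(0.5, 1.5)))
        joint.add_child(pool[i])
        joint.add_child(pool[j])
        pool = [p for idx, p in enumerate(pool) if idx not in (i, j)] + [joint]
    return pool[0]


# ---------------------------------------------------------------------------
# universe
# ---------------------------------------------------------------------------

def simulate_universe(cfg: UniverseConfig) -> ReferenceUniverse:
    """Generate genomes, a true phylogeny, taxonomy, markers, 16S, and decoys."""
    from .refdb import GenomeRecord  # deferred: refdb owns the record type

    rng_topo = rng_for(cfg.seed, "topology")

    taxonomy: dict[str, tuple[str, str, str, str | None]] = {}
    phylum_trees = []
    for p in range(1, cfg.n_phyla + 1):
        phylum = f"phylum{p}"
        genus_trees = []
        for g in range(1, cfg.genera_per_phylum + 1):
            genus = f"genus_p{p}g{g}"
            family = f"family_p{p}f{(g - 1) // 2 + 1}"
            leaves = []
            for k in range(1, cfg.genomes_per_genus + 1):
                gid = f"P{p}G{g}N{k}"
                leaves.append(phylo.Node(name=gid))
                taxonomy[gid] = (phylum, family, genus, None)
            genus_trees.append(_join_random(leaves, WITHIN_GENUS_STEM, rng_topo))
        if p == 1:
            # focal genus: focal_clades well-separated clades in one genus
            clade_trees = []
            for c in range(cfg.focal_clades):
                clade = CLADE_NAMES[c] if c < len(CLADE_NAMES) else f"C{c + 1}"
                leaves = []
                for k in range(1, cfg.genomes_per_genus + 1):
                    gid = f"F{clade}N{k}"
                    leaves.append(phylo.Node(name=gid))
                    taxonomy[gid] = (phylum, "family_focal", FOCAL_GENUS, clade)
                clade_trees.append(_join_random(leaves, cfg.within_clade_div / 2, rng_topo))
            genus_trees.append(_join_random(clade_trees, cfg.between_clade_div / 2, rng_topo))
        phylum_trees.append(_join_random(genus_trees, GENUS_STEM, rng_topo))
    true_tree = _join_random(phylum_trees, PHYLUM_STEM, rng_topo)
    true_tree.length = 0.0
    true_tree.number_edges()

    # marker sequences
    rng_seq = rng_for(cfg.seed, "markers")
    marker_truth: dict[tuple[str, int], str] = {}
    per_marker: list[dict[str, np.ndarray]] = []
    for m in range(1, cfg.n_markers + 1):
        root_seq = random_protein(cfg.marker_len, rng_seq)
        leaf_seqs = _evolve_on_tree(true_tree, root_seq, rng_seq)
        per_marker.append(leaf_seqs)
        for gid, codes in leaf_seqs.items():
            marker_truth[(gid, m)] = decode_protein(codes)

    # 16S: slow nucleotide locus, rate scaled so the focal genus stays one OTU
    D, names = phylo.leaf_distance_matrix(true_tree)
    focal_idx = [i for i, n in enumerate(names) if taxonomy[n][2] == FOCAL_GENUS]
    max_focal_path = float(D[np.ix_(focal_idx, focal_idx)].max()) if len(focal_idx) > 1 else 0.0
    rate_16s = 0.01 / max_focal_path if max_focal_path > 0 else 0.02
    rng_16s = rng_for(cfg.seed, "16S")
    root_16s = rng_16s.integers(0, 4, size=SIXTEEN_S_LEN).astype(np.int8)
    seqs_16s = _evolve_on_tree(true_tree, root_16s, rng_16s, rate_scale=rate_16s, k=4)
    sixteen_s = {gid: "".join(NUCLEOTIDES[c] for c in codes) for gid, codes in seqs_16s.items()}
    if len(focal_idx) > 1:
        fi = [names[i] for i in focal_idx]
        arr = np.stack([seqs_16s[g] for g in fi])
        pid = np.array([[np.mean(arr[i] == arr[j]) for j in range(len(fi))] for i in range(len(fi))])
        if pid.min() < 0.97:
            raise ValueError(
                "constraint violated: focal-genus 16S identity fell below 97% "
                f"(min {pid.min():.3f}); between_clade_div={cfg.between_clade_div} too large"
            )

    # assemble genome records (markers + i.i.d. decoy genes, neutral gene ids)
    rng_decoy = rng_for(cfg.seed, "decoys")
    genomes = []
    for gid in names:
        proteins = []
        for m in range(1, cfg.n_markers + 1):
            proteins.append((f"{gid}_g{m:03d}", decode_protein(per_marker[m - 1][gid])))
        for d in range(cfg.decoy_genes_per_genome):
            seq = decode_protein(random_protein(cfg.marker_len, rng_decoy))
            proteins.append((f"{gid}_g{cfg.n_markers + d + 1:03d}", seq))
        phylum, family, genus, _ = taxonomy[gid]
        genomes.append(GenomeRecord(genome_id=gid, proteins=proteins,
                                    taxonomy=(phylum, family, genus),
                                    complete=True, soil=True))
    return ReferenceUniverse(config=cfg, genomes=genomes, true_tree=true_tree,
                             taxonomy=taxonomy, marker_truth=marker_truth,
                             sixteen_s=sixteen_s)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def simulate_reads(universe: ReferenceUniverse, composition: dict[str, float],
                   n_reads: int, read_len: int = 40, decoy_frac: float = 0.0,
                   seed: int = 0, sample_id: str = "S1") -> tuple[dict[str, str], pd.DataFrame]:
    """Draw protein reads as contiguous windows of marker (or decoy) genes.

    Genome is chosen proportional to ``composition`` weight, marker uniformly,
    start position uniformly.  A fraction ``decoy_frac`` of reads comes from
    the genome's decoy genes instead of a marker.  Returns the reads and a
    truth table with one row per read.
    """
    cfg = universe.config
    if not composition:
        raise ValueError("composition map is empty")
    gids = list(composition)
    weights = np.array([composition[g] for g in gids], dtype=float)
    if (weights < 0).any() or weights.sum() <= 0:
        raise ValueError("composition weights must be non-negative and not all zero")
    if not 0 <= decoy_frac <= 1:
        raise ValueError("decoy_frac must be in [0, 1]")
    if read_len > cfg.marker_len:
        raise ValueError(f"read_len {read_len} exceeds marker_len {cfg.marker_len}")
    unknown = [g for g in gids if g not in universe.taxonomy]
    if unknown:
        raise ValueError(f"composition references unknown genomes: {unknown[:3]}")
    weights = weights / weights.sum()

    rng = rng_for(seed, "reads", sample_id)
    decoys_by_genome = {
        g.genome_id: [seq for gene_id, seq in g.proteins[cfg.n_markers:]] for g in universe.genomes
    }
    reads: dict[str, str] = {}
    rows = []
    genome_draws = rng.choice(len(gids), size=n_reads, p=weights)
    is_decoy = rng.random(n_reads) < decoy_frac
    for i in range(n_reads):
        gid = gids[int(genome_draws[i])]
        rid = f"{sample_id}_r{i:06d}"
        if is_decoy[i] and decoys_by_genome[gid]:
            src = decoys_by_genome[gid][int(rng.integers(len(decoys_by_genome[gid])))]
            marker: int | str = "decoy"
        else:
            m = int(rng.integers(1, cfg.n_markers + 1))
            src = universe.marker_truth[(gid, m)]
            marker = m
        start = int(rng.integers(0, len(src) - read_len + 1))
        reads[rid] = src[start : start + read_len]
        rows.append({"read_id": rid, "genome_id": gid, "marker_id": marker,
                     "clade": universe.clade_of(gid) or "", "sample_id": sample_id})
    truth = pd.DataFrame(rows)
    return reads, truth


# ---------------------------------------------------------------------------
# experimental design
# ---------------------------------------------------------------------------

def simulate_design(universe: ReferenceUniverse, dcfg: DesignConfig
                    ) -> tuple[dict[str, dict[str, float]], pd.DataFrame]:
    """Per-sample composition maps plus a metadata table.

    Focal-genus total weight = baseline x seasonal term x treatment multiplier
    x lognormal noise; background genomes share the remaining weight with
    lognormal variation.  Weights per sample sum to 1.
    """
    rng = rng_for(dcfg.seed, "design")
    focal = set(universe.focal_ids)
    background = [g for g in universe.genome_ids if g not in focal]
    compositions: dict[str, dict[str, float]] = {}
    meta_rows = []
    for t in range(1, dcfg.time_points + 1):
        season = float(np.exp(dcfg.seasonal_amplitude * np.sin(2 * np.pi * t / dcfg.time_points)))
        for treatment in dcfg.treatments:
            for rep in range(1, dcfg.replicates + 1):
                sid = f"t{t:02d}_{treatment}_r{rep}"
                noise = float(np.exp(rng.normal(0.0, dcfg.noise_sigma))) if dcfg.noise_sigma > 0 else 1.0
                focal_total = dcfg.focal_baseline * season * dcfg.treatment_effect[treatment] * noise
                if focal_total >= 1.0:
                    raise ValueError(f"focal weight reached {focal_total:.2f} >= 1 for {sid}")
                fw = np.exp(rng.normal(0.0, 0.3, size=len(focal)))
                fw = fw / fw.sum() * focal_total
                bw = np.exp(rng.normal(0.0, 1.0, size=len(background)))
                bw = bw / bw.sum() * (1.0 - focal_total)
                comp = {g: float(w) for g, w in zip(sorted(focal), fw)}
                comp.update({g: float(w) for g, w in zip(background, bw)})
                compositions[sid] = comp
                meta_rows.append({"sample_id": sid, "treatment": treatment,
                                  "date": f"d{t:02d}", "replicate": rep})
    metadata = pd.DataFrame(meta_rows)
    return compositions, metadata


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def brownian_on_tree(root: phylo.Node, sigma: float, rng: np.random.Generator,
                     root_value: float = 0.0) -> dict[str, float]:
    """Brownian-motion trait values at the leaves (variance = sigma^2 x branch)."""
    values: dict[str, float] = {}

    def walk(node: phylo.Node, x: float) -> None:
        if node.is_leaf:
            values[node.name] = x
            return
        for child in node.children:
            step = rng.normal(0.0, sigma * np.sqrt(max(child.length, 0.0))) if sigma > 0 else 0.0
            walk(child, x + step)

    walk(root, root_value)
    return values


def simulate_traits(clade_tree: phylo.Node, clade_map: dict[str, str],
                    bm_sigma: float = 20.0,
                    clade_temp_effects: dict[str, tuple[float, float]] | None = None,
                    count_range: tuple[int, int] = (58, 98),
                    area_sd: float = 2.0, seed: int = 0,
                    family_map: dict[str, str] | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate GH/CBM domain counts and plate degradation areas.

    Counts evolve by Brownian motion on ``clade_tree`` (rounded, clipped to
    ``count_range``, default 58-98) and are spread over GH/CBM families with
    clade-specific substrate propensities.  Areas are normal around
    clade x temperature means, for two substrates in triplicate.
    """
    if bm_sigma < 0:
        raise ValueError("bm_sigma must be >= 0")
    if len(clade_tree.leaves()) < 2:
        raise ValueError("need at least 2 isolates")
    fam_map = family_map or DEFAULT_FAMILY_MAP
    families = list(fam_map)
    rng = rng_for(seed, "traits")
    lo, hi = count_range
    root_value = (lo + hi) / 2.0
    totals = brownian_on_tree(clade_tree, bm_sigma, rng, root_value=root_value)
    clades = sorted(set(clade_map.values()))
    if clade_temp_effects is None:
        # one clade gains activity at the warm assay, one loses it entirely
        clade_temp_effects = {}
        for i, c in enumerate(clades):
            if i == 0:
                clade_temp_effects[c] = (8.0, 14.0)
            elif i == len(clades) - 1:
                clade_temp_effects[c] = (10.0, 0.0)
            else:
                clade_temp_effects[c] = (10.0, 8.0)

    count_rows = []
    for iso in sorted(totals):
        total = int(np.clip(round(totals[iso]), lo, hi))
        clade = clade_map.get(iso, "")
        # substrate propensities: clade at index 1 mirrors the cellulose-only
        # pattern (no xylan-targeting families)
        props = np.ones(len(families))
        if clades and clade == clades[min(1, len(clades) - 1)]:
            props = np.array([0.0 if fam_map[f] == "xylan" else 1.0 for f in families])
        props = props / props.sum()
        counts = rng.multinomial(total, props)
        for fam, c in zip(families, counts):
            for _ in range(int(c)):
                count_rows.append({"genome_id": iso, "gene_id": f"{iso}_orf{len(count_rows):05d}",
                                   "family": fam})
    domain_hits = pd.DataFrame(count_rows, columns=["genome_id", "gene_id", "family"])

    area_rows = []
    for iso in sorted(totals):
        clade = clade_map.get(iso, "")
        m22, m37 = clade_temp_effects.get(clade, (10.0, 8.0))
        for substrate in ("cellulose", "xylan"):
            for temp, mean in ((22, m22), (37, m37)):
                for rep in range(1, 4):
                    area = max(0.0, float(rng.normal(mean, area_sd))) if area_sd > 0 else max(0.0, mean)
                    area_rows.append({"isolate": iso, "clade": clade, "substrate": substrate,
                                      "temperature": temp, "replicate": rep, "area": area})
    areas = pd.DataFrame(area_rows)
    return domain_hits, areas
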