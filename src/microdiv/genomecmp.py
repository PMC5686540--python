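"""Genome-scale comparison metrics.

* 16S OTU clustering: greedy centroid clustering at a fractional-identity
  threshold (default 0.97), identity computed from a semi-global alignment
  excluding terminal gaps — the convention that makes the 97% boundary
  well-defined.
* ANI: Goris-style fragment scheme; the query genome is cut into 1-kb
  windows, each aligned to the subject (both strands) and the mean identity
  of qualifying hits reported as a percentage.
* AAI: reciprocal best hits by global alignment (BLOSUM62); mean percent
  identity over RBH pairs, optionally restricted to the marker proteins.
* Ortholog groups: Markov clustering (MCL) of the similarity graph.
* GH/CBM trait profiling: counts of glycoside-hydrolase / carbohydrate-
  binding-module domain hits per genome, with per-substrate genomic
  potential flags.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# identity helpers
# ---------------------------------------------------------------------------

def _nt_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = -1.0
    a.open_gap_score = -2.0
    a.extend_gap_score = -1.0
    try:
        a.end_insertion_score = 0.0
        a.end_deletion_score = 0.0
    except AttributeError:  # older Biopython naming
        a.target_end_gap_score = 0.0
        a.query_end_gap_score = 0.0
    return a


def _aa_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -10.0
    a.extend_gap_score = -1.0
    return a


def _alignment_identity(alignment, seq_a: str, seq_b: str) -> float:
    """Matches / alignment-columns-excluding-terminal-gaps."""
    blocks_a, blocks_b = alignment.aligned
    if len(blocks_a) == 0:
        return 0.0
    matches = 0
    npairs = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        sa, sb = seq_a[a0:a1], seq_b[b0:b1]
        matches += sum(x == y for x, y in zip(sa, sb))
        npairs += a1 - a0
    span_a = blocks_a[-1][1] - blocks_a[0][0]
    span_b = blocks_b[-1][1] - blocks_b[0][0]
    cols = span_a + span_b - npairs
    return matches / cols if cols else 0.0


def pairwise_identity(seq_a: str, seq_b: str, aligner=None) -> float:
    """Semi-global nucleotide identity excluding terminal gaps."""
    aligner = aligner or _nt_aligner()
    aln = aligner.align(seq_a, seq_b)[0]
    return _alignment_identity(aln, seq_a, seq_b)


# ---------------------------------------------------------------------------
# OTU clustering
# ---------------------------------------------------------------------------

@dataclass
class OtuClustering:
    threshold: float
    clusters: list[tuple[str, list[str]]]  # (centroid_id, member_ids incl. centroid)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def cluster_of(self, seq_id: str) -> str:
        for centroid, members in self.clusters:
            if seq_id in members:
                return centroid
        raise KeyError(seq_id)


def cluster_otus(seqs: dict[str, str], threshold: float = 0.97) -> OtuClustering:
    """Greedy centroid clustering (UCLUST-style).

    Sequences are processed in decreasing length (ties by id); each joins the
    first centroid with identity >= threshold, else founds a new cluster.
    The fixed processing order makes the clustering input-order invariant.
    """
    if not seqs:
        raise ValueError("empty input")
    order = sorted(seqs, key=lambda i: (-len(seqs[i]), i))
    aligner = _nt_aligner()
    clusters: list[tuple[str, list[str]]] = []
    for sid in order:
        placed = False
        for ci, (centroid, members) in enumerate(clusters):
            if pairwise_identity(seqs[sid], seqs[centroid], aligner) >= threshold:
                members.append(sid)
                placed = True
                break
        if not placed:
            clusters.append((sid, [sid]))
    return OtuClustering(threshold=threshold, clusters=clusters)


# ---------------------------------------------------------------------------
# ANI
# ---------------------------------------------------------------------------

@dataclass
class AniResult:
    genome_a: str
    genome_b: str
    value: float | None  # percent identity; None when undefined
    n_fragments_used: int
    coverage: float
    defined: bool = True


def compute_ani(genome_a: str, genome_b: str, frag_len: int = 1000,
                min_id: float = 0.3, min_cov: float = 0.7,
                name_a: str = "A", name_b: str = "B") -> AniResult:
    """Fragment-based average nucleotide identity (percent).

    ``genome_a`` is cut into non-overlapping ``frag_len`` windows; each is
    aligned to ``genome_b`` on both strands (semi-global, full fragment
    coverage) and the best identity kept.  Fragments with identity below
    ``min_id`` are discarded; ANI is the mean identity of kept fragments
    x 100.  With no qualifying fragments the result is flagged undefined.
    """
    if len(genome_a) < frag_len or len(genome_b) < frag_len:
        raise ValueError(f"both genomes must be at least frag_len={frag_len} long")
    rc_b = reverse_complement(genome_b)
    identities = []
    n_frags = len(genome_a) // frag_len
    for i in range(n_frags):
        frag = genome_a[i * frag_len : (i + 1) * frag_len]
        best = 0.0
        for target in (genome_b, rc_b):
            res = edlib.align(frag, target, mode="HW", task="distance")
            if res["editDistance"] >= 0:
                best = max(best, 1.0 - res["editDistance"] / frag_len)
        # fragments align end-to-end in HW mode, so query coverage is 1
        if best >= min_id and 1.0 >= min_cov:
            identities.append(best)
    if not identities:
        return AniResult(name_a, name_b, None, 0, 0.0, defined=False)
    return AniResult(name_a, name_b, float(np.mean(identities) * 100.0),
                     len(identities), len(identities) / n_frags)


# ---------------------------------------------------------------------------
# AAI
# ---------------------------------------------------------------------------

@dataclass
class AaiResult:
    genome_a: str
    genome_b: str
    value: float | None
    n_rbh_pairs: int
    defined: bool = True


def compute_aai(proteome_a: dict[str, str], proteome_b: dict[str, str],
                name_a: str = "A", name_b: str = "B") -> AaiResult:
    """Mean percent identity over reciprocal best hits (global BLOSUM62).

    Restrict the input dicts to marker proteins for the marker-gene AAI.
    RBH is symmetric, so AAI(A,B) == AAI(B,A) exactly.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("proteomes must be nonempty")
    aligner = _aa_aligner()
    ids_a, ids_b = sorted(proteome_a), sorted(proteome_b)
    score = np.full((len(ids_a), len(ids_b)), -np.inf)
    ident = np.zeros((len(ids_a), len(ids_b)))
    for i, ia in enumerate(ids_a):
        for j, ib in enumerate(ids_b):
            aln = aligner.align(proteome_a[ia], proteome_b[ib])[0]
            score[i, j] = aln.score
            ident[i, j] = _alignment_identity(aln, proteome_a[ia], proteome_b[ib])
    best_ab = score.argmax(axis=1)
    best_ba = score.argmax(axis=0)
    pairs = [(i, best_ab[i]) for i in range(len(ids_a)) if best_ba[best_ab[i]] == i]
    if not pairs:
        return AaiResult(name_a, name_b, None, 0, defined=False)
    value = float(np.mean([ident[i, j] for i, j in pairs]) * 100.0)
    return AaiResult(name_a, name_b, value, len(pairs))


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------

def cluster_orthologs(similarity: pd.DataFrame, inflation: float = 2.0,
                      max_iter: int = 100, tol: float = 1e-6
                      ) -> tuple[list[set[str]], bool]:
    """Markov clustering of an undirected weighted similarity graph.

    ``similarity``: symmetric non-negative DataFrame (nodes x nodes).
    Returns (clusters, converged).  Iterates expansion (matrix square) and
    inflation (elementwise power + column renormalization) until the max
    elementwise change is < ``tol`` or ``max_iter`` sweeps.
    """
    nodes = list(similarity.index)
    A = similarity.to_numpy(dtype=float).copy()
    if A.shape[0] != A.shape[1]:
        raise ValueError("similarity matrix must be square")
    A = 0.5 * (A + A.T)
    np.fill_diagonal(A, np.maximum(A.diagonal(), np.maximum(A.max(axis=0), 1e-12)))
    M = A / A.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        new = M @ M
        new = new ** inflation
        colsum = new.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        new = new / colsum
        new[new < 1e-12] = 0.0
        if np.max(np.abs(new - M)) < tol:
            M = new
            converged = True
            break
        M = new
    if not converged:
        import warnings

        warnings.warn("MCL did not converge within the iteration limit")
    support = (M + M.T) > 1e-8
    np.fill_diagonal(support, True)
    seen = np.zeros(len(nodes), dtype=bool)
    clusters: list[set[str]] = []
    for i in range(len(nodes)):
        if seen[i]:
            continue
        stack, comp = [i], set()
        while stack:
            u = stack.pop()
            if seen[u]:
                continue
            seen[u] = True
            comp.add(nodes[u])
            stack.extend(np.where(support[u])[0])
        clusters.append(comp)
    clusters.sort(key=lambda c: sorted(c)[0])
    return clusters, converged


def rbh_graph(proteomes: dict[str, dict[str, str]]) -> pd.DataFrame:
    """All-vs-all reciprocal-best-hit similarity graph over proteomes.

    Nodes are ``genome:gene`` ids; edge weight is the RBH percent identity.
    """
    aligner = _aa_aligner()
    names = sorted(proteomes)
    node_ids = [f"{g}:{p}" for g in names for p in sorted(proteomes[g])]
    W = pd.DataFrame(0.0, index=node_ids, columns=node_ids)
    for x in range(len(names)):
        for y in range(x + 1, len(names)):
            ga, gb = names[x], names[y]
            ids_a, ids_b = sorted(proteomes[ga]), sorted(proteomes[gb])
            score = np.zeros((len(ids_a), len(ids_b)))
            ident = np.zeros_like(score)
            for i, ia in enumerate(ids_a):
                for j, ib in enumerate(ids_b):
                    aln = aligner.align(proteomes[ga][ia], proteomes[gb][ib])[0]
                    score[i, j] = aln.score
                    ident[i, j] = _alignment_identity(aln, proteomes[ga][ia], proteomes[gb][ib])
            best_ab = score.argmax(axis=1)
            best_ba = score.argmax(axis=0)
            for i in range(len(ids_a)):
                j = best_ab[i]
                if best_ba[j] == i:
                    na, nb = f"{ga}:{ids_a[i]}", f"{gb}:{ids_b[j]}"
                    W.loc[na, nb] = W.loc[nb, na] = ident[i, j] * 100.0
    return W


# ---------------------------------------------------------------------------
# GH/CBM trait counting
# ---------------------------------------------------------------------------

@dataclass
class DomainCountTable:
    counts: pd.DataFrame          # genomes x families (integer counts)
    family_map: dict[str, str]    # family -> substrate category
    substrate_flags: pd.DataFrame  # genomes x substrates (bool)
    n_ignored: int


def count_gh_cbm(domain_hits: pd.DataFrame, family_map: dict[str, str],
                 genomes: list[str] | None = None) -> DomainCountTable:
    """Count GH/CBM domain hits per genome per family.

    ``domain_hits`` columns: genome_id, gene_id, family.  Families absent
    from ``family_map`` are ignored (their row count reported).  Substrate
    flags mark genomes with at least one family targeting the substrate.
    """
    families = sorted(family_map)
    if len(domain_hits):
        known = domain_hits["family"].isin(families)
        n_ignored = int((~known).sum())
        hits = domain_hits[known]
    else:
        n_ignored = 0
        hits = domain_hits
    idx = sorted(set(hits["genome_id"]) | set(genomes or []))
    counts = pd.DataFrame(0, index=idx, columns=families, dtype=int)
    if len(hits):
        pivot = hits.groupby(["genome_id", "family"]).size().unstack(fill_value=0)
        counts.loc[pivot.index, pivot.columns] = pivot
    substrates = sorted({s for s in family_map.values() if s != "other"})
    flags = pd.DataFrame(False, index=idx, columns=substrates)
    for sub in substrates:
        fam_sub = [f for f in families if family_map[f] == sub]
        flags[sub] = counts[fam_sub].sum(axis=1) > 0
    return DomainCountTable(counts=counts, family_map=dict(family_map),
                            substrate_flags=flags, n_ignored=n_ignored)
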