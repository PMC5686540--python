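"""Build and curate per-marker reference packages.

The reference side of the pipeline: screen genomes for the 29 single-copy
marker genes, subsample to two genomes per genus, align each marker,
concatenate into a supermatrix, build distance trees (neighbor joining on
Poisson-corrected distances), purge genomes with aberrant terminal branches,
derive per-column log-odds profiles, and serialize everything as a
hash-verified reference package.

Tree inference is deliberately distance-based: the placement machinery only
needs a reasonable reference topology with branch lengths, and NJ on
maximum-likelihood-corrected distances is deterministic and fast at desk
scale.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np

from . import phylo
from .align import GAP, Alignment, progressive_align
from .util import N_AA, encode_protein, read_fasta

# affine transition costs (bits) for profile Viterbi scoring
INSERT_OPEN = -3.0
INSERT_EXTEND = -1.0
DELETE_OPEN = -3.0
DELETE_EXTEND = -1.0

NEG = -1e30


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeRecord:
    genome_id: str
    proteins: list[tuple[str, str]]
    taxonomy: tuple[str, str, str]  # (phylum, family, genus)
    complete: bool = False
    soil: bool = False


@dataclass
class MarkerHit:
    genome_id: str
    marker_id: int
    gene_id: str
    score: float
    copy_number: int = 1


@dataclass
class Profile:
    """Per-column log-odds scoring matrix over the 20-residue alphabet.

    ``match_cols`` indexes the alignment columns with <50% gaps; scores are
    bits against a uniform background.  ``score_threshold`` is the marker's
    screening threshold (minimum training score minus 2 bits).  ``gumbel``
    holds the (loc, scale, read_len) of the cached decoy-score calibration
    used for stage-2 E-values.
    """

    marker_id: int
    log_odds: np.ndarray           # (n_match, 20)
    match_cols: np.ndarray         # indices into the source alignment columns
    n_alignment_cols: int
    score_threshold: float = float("-inf")
    gumbel: tuple[float, float, int] | None = None

    def to_dict(self) -> dict:
        return {
            "marker_id": self.marker_id,
            "log_odds": np.round(self.log_odds, 9).tolist(),
            "match_cols": self.match_cols.tolist(),
            "n_alignment_cols": int(self.n_alignment_cols),
            "score_threshold": self.score_threshold,
            "gumbel": list(self.gumbel) if self.gumbel else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Profile":
        return cls(
            marker_id=d["marker_id"],
            log_odds=np.array(d["log_odds"], dtype=float),
            match_cols=np.array(d["match_cols"], dtype=int),
            n_alignment_cols=d["n_alignment_cols"],
            score_threshold=d["score_threshold"],
            gumbel=tuple(d["gumbel"]) if d.get("gumbel") else None,
        )


# ---------------------------------------------------------------------------
# profile construction and scoring
# ---------------------------------------------------------------------------

def build_profiles(alignment: Alignment, pseudocount: float = 0.5,
                   marker_id: int = 0) -> Profile:
    """Per-column log-odds (bits) of residue frequency vs uniform background.

    Match columns are those with <50% gaps.  The screening threshold is set
    from the training rows afterwards (min score - 2 bits).
    """
    if alignment.n_rows == 0 or alignment.n_cols == 0:
        raise ValueError("empty alignment")
    gap_frac = alignment.gap_fraction()
    match_cols = np.where(gap_frac < 0.5)[0]
    bg = 1.0 / N_AA
    counts = np.zeros((len(match_cols), N_AA))
    for a in range(N_AA):
        counts[:, a] = (alignment.codes[:, match_cols] == a).sum(axis=0)
    tot = counts.sum(axis=1, keepdims=True)
    freq = (counts + pseudocount * bg) / (tot + pseudocount)
    log_odds = np.log2(freq / bg)
    prof = Profile(marker_id=marker_id, log_odds=log_odds, match_cols=match_cols,
                   n_alignment_cols=alignment.n_cols)
    # screening threshold from the training sequences themselves
    train = [encode_protein(alignment.row(r).replace("-", "")) for r in range(alignment.n_rows)]
    by_len: dict[int, list[np.ndarray]] = {}
    for s in train:
        by_len.setdefault(len(s), []).append(s)
    scores: list[float] = []
    for group in by_len.values():
        scores.extend(score_profile_many(prof, np.stack(group)).tolist())
    prof.score_threshold = float(min(scores) - 2.0)
    return prof


def score_profile_many(profile: Profile, codes: np.ndarray) -> np.ndarray:
    """Viterbi-style best-path scores of many equal-length sequences.

    Read-global / profile-local: every residue is consumed (match or insert),
    profile columns are free at both ends, internal skips pay affine deletion
    costs.  ``codes``: (n_seqs, L) int array.  Returns bits, shape (n_seqs,).
    """
    codes = np.atleast_2d(codes)
    R, L = codes.shape
    M = profile.log_odds.shape[0]
    ar = np.arange(M + 1)
    # state arrays over j = columns consumed, j in 0..M
    Mprev = np.full((R, M + 1), NEG)
    Iprev = np.full((R, M + 1), NEG)
    for i in range(L):
        a = codes[:, i].astype(int)
        emit = np.where(a[:, None] >= 0, profile.log_odds[:, np.maximum(a, 0)].T, 0.0)  # (R, M)
        if i == 0:
            Mcur = np.full((R, M + 1), NEG)
            Mcur[:, 1:] = emit  # free start at any column
            Icur = np.full((R, M + 1), INSERT_OPEN)
        else:
            best_prev = np.maximum(Mprev, Iprev)
            # affine deletion scan via running max of u[j] = best_prev[j] - EXT*j
            u = best_prev - DELETE_EXTEND * ar
            run = np.maximum.accumulate(u, axis=1)
            dstate = np.full((R, M + 1), NEG)
            dstate[:, 1:] = DELETE_OPEN + DELETE_EXTEND * (ar[1:] - 1) + run[:, :-1]
            Mcur = np.full((R, M + 1), NEG)
            Mcur[:, 1:] = emit + np.maximum(best_prev[:, :-1], dstate[:, :-1])
            Icur = np.maximum(Mprev + INSERT_OPEN, Iprev + INSERT_EXTEND)
        Mprev, Iprev = Mcur, Icur
    return np.maximum(Mprev, Iprev).max(axis=1)


def score_profile(profile: Profile, codes: np.ndarray) -> float:
    return float(score_profile_many(profile, np.asarray(codes, dtype=int)[None, :])[0])


def align_profile(profile: Profile, codes: np.ndarray) -> tuple[float, np.ndarray]:
    """Single-sequence Viterbi with traceback.

    Returns (score_bits, col_map) where ``col_map[i]`` is the source-alignment
    column index of residue ``i`` or -1 for an insertion.
    """
    a = np.asarray(codes, dtype=int)
    L, M = len(a), profile.log_odds.shape[0]
    if L == 0:
        raise ValueError("empty sequence")
    Mmat = np.full((L + 1, M + 1), NEG)
    Imat = np.full((L + 1, M + 1), NEG)
    ptrM = np.zeros((L + 1, M + 1), dtype=np.int8)  # 0 diag-from-best, 1 from-del
    ptrI = np.zeros((L + 1, M + 1), dtype=np.int8)  # 0 from M, 1 from I
    dfrom = np.zeros((L + 1, M + 1), dtype=np.int32)  # column where the del run started
    for i in range(1, L + 1):
        ai = a[i - 1]
        emit = profile.log_odds[:, ai] if ai >= 0 else np.zeros(M)
        if i == 1:
            Mmat[1, 1:] = emit
            Imat[1, :] = INSERT_OPEN
            continue
        best_prev = np.maximum(Mmat[i - 1], Imat[i - 1])
        dstate = np.full(M + 1, NEG)
        dstart = np.zeros(M + 1, dtype=np.int32)
        for j in range(1, M + 1):
            open_sc = best_prev[j - 1] + DELETE_OPEN
            ext_sc = dstate[j - 1] + DELETE_EXTEND
            if open_sc >= ext_sc:
                dstate[j] = open_sc
                dstart[j] = j - 1
            else:
                dstate[j] = ext_sc
                dstart[j] = dstart[j - 1]
        for j in range(1, M + 1):
            if best_prev[j - 1] >= dstate[j - 1]:
                Mmat[i, j] = emit[j - 1] + best_prev[j - 1]
                ptrM[i, j] = 0
                dfrom[i, j] = j - 1
            else:
                Mmat[i, j] = emit[j - 1] + dstate[j - 1]
                ptrM[i, j] = 1
                dfrom[i, j] = dstart[j - 1]
        Imat[i, :] = np.maximum(Mmat[i - 1] + INSERT_OPEN, Imat[i - 1] + INSERT_EXTEND)
        ptrI[i, :] = (Imat[i, :] == Imat[i - 1] + INSERT_EXTEND).astype(np.int8)
    # terminal
    endM = int(np.argmax(np.maximum(Mmat[L], Imat[L])))
    in_insert = Imat[L, endM] > Mmat[L, endM]
    score = max(Mmat[L, endM], Imat[L, endM])
    col_map = np.full(L, -1, dtype=int)
    i, j = L, endM
    while i > 0:
        if in_insert:
            in_insert = bool(ptrI[i, j]) if i > 1 else False
            i -= 1
        else:
            col_map[i - 1] = int(profile.match_cols[j - 1])
            if i == 1:
                break
            jprev = int(dfrom[i, j])
            prevM, prevI = Mmat[i - 1, jprev], Imat[i - 1, jprev]
            in_insert = prevI > prevM
            i, j = i - 1, jprev
    return float(score), col_map


# ---------------------------------------------------------------------------
# screening and curation
# ---------------------------------------------------------------------------

def screen_markers(genomes: list[GenomeRecord], marker_profiles: dict[int, Profile]
                   ) -> tuple[list[MarkerHit], dict[str, list[str]]]:
    """Retain genomes with exactly one gene per marker above threshold.

    Returns the retained hits and a map of discarded genome -> reasons
    ("missing marker 5", "marker 12 not single-copy").
    """
    if not genomes:
        raise ValueError("empty genome list")
    hits: list[MarkerHit] = []
    discarded: dict[str, list[str]] = {}
    for genome in genomes:
        gene_ids = [gid for gid, _ in genome.proteins]
        codes = [encode_protein(seq) for _, seq in genome.proteins]
        by_len: dict[int, list[int]] = {}
        for idx, c in enumerate(codes):
            by_len.setdefault(len(c), []).append(idx)
        reasons: list[str] = []
        genome_hits: list[MarkerHit] = []
        for m, prof in sorted(marker_profiles.items()):
            scores = np.full(len(codes), NEG)
            for ln, idxs in by_len.items():
                batch = np.stack([codes[i] for i in idxs])
                scores[idxs] = score_profile_many(prof, batch)
            above = np.where(scores >= prof.score_threshold)[0]
            if len(above) == 0:
                reasons.append(f"missing marker {m}")
            elif len(above) > 1:
                reasons.append(f"marker {m} not single-copy ({len(above)} genes)")
            else:
                i = int(above[0])
                genome_hits.append(MarkerHit(genome.genome_id, m, gene_ids[i],
                                             float(scores[i]), 1))
        if reasons:
            discarded[genome.genome_id] = reasons
        else:
            hits.extend(genome_hits)
    return hits, discarded


def subsample_genera(genomes: list[GenomeRecord],
                     taxonomy: dict[str, tuple] | None = None,
                     k: int = 2, keep_genera: set[str] | frozenset = frozenset()
                     ) -> list[GenomeRecord]:
    """Keep at most ``k`` genomes per genus, preferring complete+soil >
    complete > soil > neither, ties broken by lexicographic genome id.
    Genera in ``keep_genera`` are exempt (all members kept)."""
    by_genus: dict[str, list[GenomeRecord]] = {}
    for g in genomes:
        genus = taxonomy[g.genome_id][2] if taxonomy else g.taxonomy[2]
        by_genus.setdefault(genus, []).append(g)
    out: list[GenomeRecord] = []
    for genus in by_genus:
        members = by_genus[genus]
        if genus in keep_genera:
            out.extend(sorted(members, key=lambda g: g.genome_id))
            continue
        members.sort(key=lambda g: (-(g.complete and g.soil), -g.complete, -g.soil, g.genome_id))
        out.extend(members[:k])
    out.sort(key=lambda g: g.genome_id)
    return out


def align_marker(sequences: dict[str, str]) -> Alignment:
    """Align one marker's sequences (progressive; see :mod:`microdiv.align`)."""
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    return progressive_align(sequences)


def concatenate(alignments: list[Alignment]) -> Alignment:
    """Concatenate marker alignments in order; genomes missing a marker get
    gap blocks spanning that marker's columns."""
    if not alignments:
        raise ValueError("no alignments to concatenate")
    ids: list[str] = []
    for aln in alignments:
        for i in aln.ids:
            if i not in ids:
                ids.append(i)
    total = sum(a.n_cols for a in alignments)
    codes = np.full((len(ids), total), GAP, dtype=np.int8)
    offset = 0
    for aln in alignments:
        for r, i in enumerate(aln.ids):
            codes[ids.index(i), offset : offset + aln.n_cols] = aln.codes[r]
        offset += aln.n_cols
    return Alignment(ids, codes)


def alignment_distances(aln: Alignment) -> tuple[np.ndarray, list[str]]:
    """Poisson-corrected pairwise distances with pairwise deletion of gaps."""
    n = aln.n_rows
    valid = aln.codes >= 0
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            if both.sum() == 0:
                D[i, j] = D[j, i] = 10.0
                continue
            p = float((aln.codes[i, both] != aln.codes[j, both]).mean())
            D[i, j] = D[j, i] = float(phylo.poisson_correct(p))
    return D, list(aln.ids)


def build_tree_nj(dist: np.ndarray, labels: list[str]) -> phylo.Node:
    """Neighbor joining with deterministic tie-breaking (see :mod:`microdiv.phylo`)."""
    return phylo.neighbor_joining(dist, labels)


def marker_tree(aln: Alignment) -> phylo.Node:
    D, labels = alignment_distances(aln)
    return build_tree_nj(D, labels)


def curate_by_branch_length(alignments: dict[int, Alignment], threshold: float = 5.0
                            ) -> tuple[list[str], dict[int, phylo.Node], list[set[str]]]:
    """Iteratively remove genomes whose terminal branch exceeds ``threshold``
    in ANY marker tree, rebuilding all trees, until a fixed point.

    Returns (kept genome ids, final trees per marker, per-iteration removal log).
    """
    current = {m: a for m, a in alignments.items()}
    kept = list(next(iter(current.values())).ids)
    removal_log: list[set[str]] = []
    while True:
        trees = {m: marker_tree(a) for m, a in current.items()}
        rogue: set[str] = set()
        for t in trees.values():
            for leaf in t.leaves():
                if leaf.length > threshold:
                    rogue.add(leaf.name)
        if not rogue:
            return kept, trees, removal_log
        if len(kept) - len(rogue) < 3:
            raise ValueError(f"removing {sorted(rogue)} would leave fewer than 3 genomes")
        removal_log.append(rogue)
        kept = [g for g in kept if g not in rogue]
        new = {}
        for m, a in current.items():
            keep_rows = [r for r, i in enumerate(a.ids) if i not in rogue]
            new[m] = Alignment([a.ids[r] for r in keep_rows], a.codes[keep_rows])
        current = new


# ---------------------------------------------------------------------------
# reference package
# ---------------------------------------------------------------------------

@dataclass
class MarkerPackage:
    marker_id: int
    alignment: Alignment
    profile: Profile
    tree: phylo.Node


@dataclass
class ReferencePackage:
    markers: dict[int, MarkerPackage]
    taxonomy: dict[str, tuple[str, str, str, str | None]]
    calibration: dict = field(default_factory=dict)  # stage-1 Karlin-Altschul etc.
    seed: int = 0

    def genome_ids(self) -> list[str]:
        return sorted({i for mp in self.markers.values() for i in mp.alignment.ids})

    # -- serialization ----------------------------------------------------
    def save(self, path: str) -> None:
        os.makedirs(path, exist_ok=True)
        files: dict[str, str] = {}

        def emit(rel: str, text: str) -> None:
            full = os.path.join(path, rel)
            os.makedirs(os.path.dirname(full), exist_ok=True)
            with open(full, "w") as fh:
                fh.write(text)
            files[rel] = hashlib.sha256(text.encode()).hexdigest()

        tax_lines = ["genome_id\tphylum\tfamily\tgenus\tclade"]
        for gid in sorted(self.taxonomy):
            p, f, g, c = self.taxonomy[gid]
            tax_lines.append(f"{gid}\t{p}\t{f}\t{g}\t{c or ''}")
        emit("taxonomy.tsv", "\n".join(tax_lines) + "\n")
        emit("calibration.json", json.dumps(self.calibration, sort_keys=True, indent=1))
        for m, mp in sorted(self.markers.items()):
            base = f"markers/m{m:02d}"
            fasta_txt = "".join(
                f">{i}\n" + "\n".join(
                    mp.alignment.row(r)[c : c + 80] for c in range(0, mp.alignment.n_cols, 80)
                ) + "\n"
                for r, i in enumerate(mp.alignment.ids)
            )
            emit(f"{base}/alignment.fasta", fasta_txt)
            emit(f"{base}/tree.nwk", mp.tree.to_newick(edge_numbers=True) + "\n")
            emit(f"{base}/profile.json", json.dumps(mp.profile.to_dict(), sort_keys=True))
        manifest = {"format": "microdiv-refpkg-1", "seed": self.seed, "files": files}
        with open(os.path.join(path, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, sort_keys=True, indent=1)

    @classmethod
    def load(cls, path: str) -> "ReferencePackage":
        with open(os.path.join(path, "manifest.json")) as fh:
            manifest = json.load(fh)
        for rel, digest in manifest["files"].items():
            full = os.path.join(path, rel)
            if not os.path.exists(full):
                raise ValueError(f"reference package missing component: {rel}")
            with open(full) as f2:
                actual = hashlib.sha256(f2.read().encode()).hexdigest()
            if actual != digest:
                raise ValueError(f"reference package hash mismatch for {rel}")
        taxonomy: dict[str, tuple] = {}
        with open(os.path.join(path, "taxonomy.tsv")) as fh:
            next(fh)
            for line in fh:
                gid, p, f, g, c = (line.rstrip("\n").split("\t") + [""])[:5]
                taxonomy[gid] = (p, f, g, c or None)
        with open(os.path.join(path, "calibration.json")) as fh:
            calibration = json.load(fh)
        markers: dict[int, MarkerPackage] = {}
        mdir = os.path.join(path, "markers")
        for name in sorted(os.listdir(mdir)):
            m = int(name[1:])
            aln = Alignment.from_sequences(read_fasta(os.path.join(mdir, name, "alignment.fasta")))
            with open(os.path.join(mdir, name, "tree.nwk")) as fh:
                tree = phylo.parse_newick(fh.read())
            with open(os.path.join(mdir, name, "profile.json")) as fh:
                profile = Profile.from_dict(json.load(fh))
            markers[m] = MarkerPackage(m, aln, profile, tree)
        return cls(markers=markers, taxonomy=taxonomy, calibration=calibration,
                   seed=manifest.get("seed", 0))


def build_reference_package(marker_alignments: dict[int, Alignment],
                            trees: dict[int, phylo.Node],
                            taxonomy: dict[str, tuple],
                            calibration: dict | None = None,
                            seed: int = 0,
                            pseudocount: float = 0.5) -> ReferencePackage:
    """Assemble a ReferencePackage from consistent per-marker components."""
    markers: dict[int, MarkerPackage] = {}
    for m, aln in sorted(marker_alignments.items()):
        tree = trees[m]
        if set(tree.leaf_names()) != set(aln.ids):
            raise ValueError(f"marker {m}: tree leaves and alignment rows disagree")
        if tree.edges() and any(e.edge_num is None for e in tree.edges()):
            tree.number_edges()
        markers[m] = MarkerPackage(m, aln, build_profiles(aln, pseudocount, marker_id=m), tree)
    return ReferencePackage(markers=markers, taxonomy=taxonomy,
                            calibration=calibration or {}, seed=seed)
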