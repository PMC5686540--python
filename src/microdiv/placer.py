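"""Two-stage homology filtering and likelihood placement of protein reads.

Stage 1 mirrors a BLASTP prefilter: 3-mer seeded, two-hit, ungapped
extension scored with BLOSUM62, E-values from a Karlin-Altschul (Gumbel)
calibration estimated once from seeded random sequence pairs (E <= 1e-5 by
default).  Stage 2 mirrors a profile-HMM refilter: Viterbi best-path score
of the read against the marker's log-odds profile, E-values from a Gumbel
fit to shuffled decoy scores cached per marker (E <= 1e-10).

Surviving reads are aligned to the marker's reference columns and placed on
every edge of the reference tree: the read attaches at the edge midpoint by
a pendant branch whose length is optimized by golden-section search on
[0, 5], under the same Poisson substitution model used for the reference
distances.  Likelihood weight ratios are normalized over all edges and the
top 20 records kept; these serve as the placement's posterior weights.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from . import phylo
from .align import blosum62
from .refdb import (DELETE_EXTEND, DELETE_OPEN, INSERT_EXTEND, INSERT_OPEN,
                    MarkerPackage, Profile, ReferencePackage, score_profile_many)
from .util import decode_protein, encode_protein, rng_for

NEG = -1e30
EULER_GAMMA = 0.5772156649015329

JPLACE_FIELDS = ["edge_num", "likelihood", "like_weight_ratio",
                 "distal_length", "pendant_length"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class FilterHit:
    read_id: str
    marker_id: int
    stage1_evalue: float
    stage2_score: float
    stage2_evalue: float
    aligned_columns: tuple[int, int] | None = None  # [start, end) profile cols


@dataclass
class Placement:
    read_id: str
    records: list[tuple[int, float, float, float, float]] = field(default_factory=list)
    # (edge_num, log_likelihood, like_weight_ratio, distal_length, pendant_length)


@dataclass
class AlignedRead:
    read_id: str
    marker_id: int
    codes: np.ndarray      # residue codes, length L
    col_map: np.ndarray    # alignment column per residue, -1 for insertions

    def unalign(self) -> str:
        return decode_protein(self.codes)


# ---------------------------------------------------------------------------
# stage 1: seeded ungapped search
# ---------------------------------------------------------------------------

def calibrate_karlin_altschul(seed: int = 0, m0: int = 40, n0: int = 150,
                              n_pairs: int = 10000) -> dict:
    """Estimate Gumbel (lambda, K) for ungapped BLOSUM62 segment scores from
    random i.i.d. sequence pairs; cached in the reference package."""
    rng = rng_for(seed, "karlin-altschul")
    B = blosum62()
    best = np.empty(n_pairs)
    chunk = 1000
    for c0 in range(0, n_pairs, chunk):
        c = min(chunk, n_pairs - c0)
        A = rng.integers(0, 20, size=(c, m0))
        Bb = rng.integers(0, 20, size=(c, n0))
        S = B[A[:, :, None], Bb[:, None, :]]  # (c, m0, n0)
        mx = np.full(c, -np.inf)
        for d in range(-(m0 - 1), n0):
            diag = np.diagonal(S, offset=d, axis1=1, axis2=2)  # (c, len)
            run = np.zeros(c)
            for k in range(diag.shape[1]):
                run = np.maximum(run + diag[:, k], diag[:, k])
                mx = np.maximum(mx, run)
        best[c0 : c0 + c] = mx
    sd = float(best.std(ddof=1))
    lam = math.pi / (sd * math.sqrt(6.0))
    loc = float(best.mean()) - EULER_GAMMA / lam
    K = math.exp(lam * loc) / (m0 * n0)
    return {"lambda": lam, "K": K, "m0": m0, "n0": n0, "n_pairs": n_pairs, "seed": seed}


class Stage1Database:
    """Reference protein database with a 3-mer index for seeded search."""

    K = 3

    def __init__(self, proteins: list[tuple[str, int | None, str]],
                 calibration: dict | None = None, seed: int = 0):
        if calibration is None:
            calibration = calibrate_karlin_altschul(seed=seed)
        self.calibration = calibration
        self.names = [p[0] for p in proteins]
        self.markers = [p[1] for p in proteins]
        codes = [encode_protein(p[2]) for p in proteins]
        self.offsets = np.zeros(len(codes) + 1, dtype=np.int64)
        for i, c in enumerate(codes):
            self.offsets[i + 1] = self.offsets[i] + len(c)
        self.concat = np.concatenate(codes) if codes else np.zeros(0, dtype=np.int8)
        self.n_residues = int(len(self.concat))
        # 3-mer index over valid positions
        valid = np.ones(max(self.n_residues - 2, 0), dtype=bool)
        for i in range(len(codes)):
            # kill k-mers spanning protein boundaries
            end = self.offsets[i + 1]
            valid[max(end - 2, 0) : end] = False
        c = self.concat.astype(np.int64)
        if self.n_residues >= 3:
            kcodes = c[:-2] * 400 + c[1:-1] * 20 + c[2:]
            kcodes[(self.concat[:-2] < 0) | (self.concat[1:-1] < 0) | (self.concat[2:] < 0)] = -1
            kcodes[~valid] = -1
        else:
            kcodes = np.zeros(0, dtype=np.int64)
        order = np.argsort(kcodes, kind="stable")
        self._sorted_pos = order.astype(np.int64)
        self._sorted_codes = kcodes[order]
        self._prot_of_pos = np.searchsorted(self.offsets, np.arange(self.n_residues), side="right") - 1
        self._B = blosum62()

    def _seed_hits(self, rcodes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        c = rcodes.astype(np.int64)
        q = c[:-2] * 400 + c[1:-1] * 20 + c[2:]
        q[(rcodes[:-2] < 0) | (rcodes[1:-1] < 0) | (rcodes[2:] < 0)] = -1
        qpos_all, dbpos_all = [], []
        for qp, code in enumerate(q):
            if code < 0:
                continue
            lo = np.searchsorted(self._sorted_codes, code, side="left")
            hi = np.searchsorted(self._sorted_codes, code, side="right")
            if hi > lo:
                dbpos_all.append(self._sorted_pos[lo:hi])
                qpos_all.append(np.full(hi - lo, qp, dtype=np.int64))
        if not dbpos_all:
            return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
        return np.concatenate(qpos_all), np.concatenate(dbpos_all)

    def search_read(self, rcodes: np.ndarray) -> tuple[int | None, float, float] | None:
        """Best marker-labelled hit for one read: (marker, raw_score, evalue)."""
        m = len(rcodes)
        qpos, dbpos = self._seed_hits(rcodes)
        if len(qpos) == 0:
            return None
        prot = self._prot_of_pos[dbpos]
        diag = (dbpos - self.offsets[prot]) - qpos
        key = prot * 4096 + (diag + 2048)
        uniq, counts = np.unique(key, return_counts=True)
        cand = uniq[counts >= 2]  # two-hit rule
        if len(cand) == 0:
            return None
        p_arr = (cand // 4096).astype(np.int64)
        labelled = np.array([self.markers[int(p)] is not None for p in p_arr])
        if not labelled.any():
            return None
        cand, p_arr = cand[labelled], p_arr[labelled]
        d_arr = (cand % 4096).astype(np.int64) - 2048
        starts, ends = self.offsets[p_arr], self.offsets[p_arr + 1]
        q0 = np.maximum(0, -d_arr)
        q1 = np.minimum(m, (ends - starts) - d_arr)
        keep = (q1 - q0) >= self.K
        if not keep.any():
            return None
        p_arr, d_arr, starts, q0, q1 = p_arr[keep], d_arr[keep], starts[keep], q0[keep], q1[keep]
        # padded per-diagonal score rows, then cumsum-based max-subarray
        C = len(p_arr)
        pos = q0[:, None] + np.arange(m)[None, :]
        valid = pos < q1[:, None]
        qidx = np.minimum(pos, m - 1)
        didx = np.minimum(starts[:, None] + d_arr[:, None] + pos, self.n_residues - 1)
        r = rcodes[qidx]
        sub = self.concat[didx]
        ok = valid & (r >= 0) & (sub >= 0)
        sc = np.where(ok, self._B[np.maximum(r, 0), np.maximum(sub, 0)], 0.0)
        cum = np.cumsum(sc, axis=1)
        prev_min = np.minimum.accumulate(np.hstack([np.zeros((C, 1)), cum[:, :-1]]), axis=1)
        best_per = (cum - prev_min).max(axis=1)
        ci = int(np.argmax(best_per))
        best_score, best_prot = float(best_per[ci]), int(p_arr[ci])
        lam, K = self.calibration["lambda"], self.calibration["K"]
        evalue = K * m * self.n_residues * math.exp(-lam * best_score)
        return self.markers[best_prot], float(best_score), float(evalue)


def stage1_search(reads: dict[str, str], db: Stage1Database,
                  evalue_max: float = 1e-5) -> dict[str, tuple[int, float]]:
    """Best-marker candidates per read: ``{read_id: (marker_id, evalue)}``."""
    if not reads:
        raise ValueError("empty read set")
    if db.n_residues == 0:
        import warnings

        warnings.warn("stage-1 database is empty; no hits possible")
        return {}
    out: dict[str, tuple[int, float]] = {}
    for rid, seq in reads.items():
        bad = set(seq.upper()) - set("ACDEFGHIKLMNPQRSTVWYX")
        if bad:
            raise ValueError(f"read {rid} contains non-residue characters: {sorted(bad)}")
        hit = db.search_read(encode_protein(seq))
        if hit is not None and hit[2] <= evalue_max:
            out[rid] = (int(hit[0]), hit[2])
    return out


# ---------------------------------------------------------------------------
# stage 2: profile filter
# ---------------------------------------------------------------------------

def calibrate_gumbel(profile: Profile, read_len: int, seed: int = 0,
                     n_decoys: int = 1000) -> tuple[float, float, int]:
    """Fit a Gumbel to profile scores of seeded i.i.d. decoy reads."""
    rng = rng_for(seed, "gumbel", profile.marker_id, read_len)
    decoys = rng.integers(0, 20, size=(n_decoys, read_len))
    scores = score_profile_many(profile, decoys)
    sd = float(scores.std(ddof=1))
    lam = math.pi / (sd * math.sqrt(6.0))
    loc = float(scores.mean()) - EULER_GAMMA / lam
    return (loc, 1.0 / lam, read_len)


def gumbel_sf(score: np.ndarray, loc: float, scale: float) -> np.ndarray:
    z = (np.asarray(score, dtype=float) - loc) / scale
    # 1 - exp(-exp(-z)), stable for large z
    return -np.expm1(-np.exp(-z))


def stage2_profile_filter(candidates: dict[str, tuple[int, float]],
                          reads: dict[str, str],
                          package: ReferencePackage,
                          evalue_max: float = 1e-10,
                          seed: int = 0) -> list[FilterHit]:
    """Viterbi profile scores with Gumbel E-values; retains E <= ``evalue_max``.

    Stage-2 survivors are by construction a subset of stage-1 candidates.
    """
    n_markers = len(package.markers)
    by_marker: dict[int, list[str]] = {}
    for rid, (m, _e1) in candidates.items():
        if m not in package.markers:
            raise ValueError(f"candidate references unknown marker {m}")
        by_marker.setdefault(m, []).append(rid)
    hits: list[FilterHit] = []
    for m, rids in sorted(by_marker.items()):
        prof = package.markers[m].profile
        by_len: dict[int, list[str]] = {}
        for rid in rids:
            by_len.setdefault(len(reads[rid]), []).append(rid)
        for ln, group in sorted(by_len.items()):
            if prof.gumbel is None:
                prof.gumbel = calibrate_gumbel(prof, ln, seed=seed)
            loc, scale, _cal_len = prof.gumbel
            codes = np.stack([encode_protein(reads[rid]) for rid in group])
            scores = score_profile_many(prof, codes)
            evals = gumbel_sf(scores, loc, scale) * n_markers
            for rid, s, e in zip(group, scores, evals):
                if e <= evalue_max:
                    hits.append(FilterHit(rid, m, candidates[rid][1], float(s), float(e)))
    hits.sort(key=lambda h: h.read_id)
    return hits


# ---------------------------------------------------------------------------
# alignment of reads to reference columns
# ---------------------------------------------------------------------------

def align_to_profile(read_id: str, seq: str, profile: Profile,
                     marker_id: int | None = None) -> AlignedRead:
    """Glocal alignment of a read to the profile's match columns.

    The read is global (every residue consumed), the profile local (free
    terminal columns); inserted residues get column -1.  Vectorized Gotoh
    with an affine deletion scan.
    """
    codes = encode_protein(seq)
    L = len(codes)
    M = profile.log_odds.shape[0]
    if L == 0:
        raise ValueError("empty read")
    Mmat = np.full((L + 1, M + 1), NEG)
    Imat = np.full((L + 1, M + 1), NEG)
    fromM = np.zeros((L + 1, M + 1), dtype=np.int32)   # previous column index for M
    insM = np.zeros((L + 1, M + 1), dtype=bool)        # predecessor of M was insert state
    insI = np.zeros((L + 1, M + 1), dtype=bool)        # predecessor of I was insert state
    ar = np.arange(M + 1)
    for i in range(1, L + 1):
        ai = int(codes[i - 1])
        emit = profile.log_odds[:, ai] if ai >= 0 else np.zeros(M)
        if i == 1:
            Mmat[1, 1:] = emit
            fromM[1, 1:] = 0
            Imat[1, :] = INSERT_OPEN
            continue
        prevM, prevI = Mmat[i - 1], Imat[i - 1]
        best_prev = np.maximum(prevM, prevI)
        # affine deletion via running max of u[j] = best_prev[j] - EXT*j
        u = best_prev - DELETE_EXTEND * ar
        run = np.maximum.accumulate(u)
        runidx = np.maximum.accumulate(np.where(u >= run, ar, 0))
        dstate = np.full(M + 1, NEG)
        dstate[1:] = DELETE_OPEN + DELETE_EXTEND * (ar[1:] - 1) + run[:-1]
        dsrc = np.zeros(M + 1, dtype=np.int64)
        dsrc[1:] = runidx[:-1]
        direct = best_prev[:-1]
        use_del = dstate[:-1] > direct
        Mmat[i, 1:] = emit + np.where(use_del, dstate[:-1], direct)
        fromM[i, 1:] = np.where(use_del, dsrc[:-1], ar[:-1])
        insM[i, 1:] = np.where(use_del, False,
                               prevI[:-1] > prevM[:-1])
        ins_ext = prevI + INSERT_EXTEND
        ins_open = prevM + INSERT_OPEN
        Imat[i] = np.maximum(ins_open, ins_ext)
        insI[i] = ins_ext > ins_open
    endj = int(np.argmax(np.maximum(Mmat[L], Imat[L])))
    in_insert = bool(Imat[L, endj] > Mmat[L, endj])
    col_map = np.full(L, -1, dtype=int)
    i, j = L, endj
    while i > 0:
        if in_insert:
            in_insert = bool(insI[i, j]) if i > 1 else False
            i -= 1
        else:
            col_map[i - 1] = int(profile.match_cols[j - 1])
            in_insert = bool(insM[i, j])
            j = int(fromM[i, j])
            i -= 1
    if (col_map >= 0).sum() == 0:
        raise ValueError(f"read {read_id}: empty alignment interval")
    return AlignedRead(read_id=read_id, marker_id=marker_id or profile.marker_id,
                       codes=codes, col_map=col_map)


# ---------------------------------------------------------------------------
# placement engine
# ---------------------------------------------------------------------------

class PlacementEngine:
    """Per-marker precomputation for edge-likelihood evaluation.

    For every edge the conditional likelihood vectors of the distal and
    proximal subtrees are propagated to the edge midpoint and combined with
    the stationary frequencies.  A read then costs O(edges x covered sites)
    per pendant-length evaluation.
    """

    def __init__(self, marker_pkg: MarkerPackage):
        self.marker_id = marker_pkg.marker_id
        tree = marker_pkg.tree
        if any(e.edge_num is None for e in tree.edges()):
            tree.number_edges()
        self.tree = tree
        aln = marker_pkg.alignment
        row_of = {gid: r for r, gid in enumerate(aln.ids)}
        S = aln.n_cols
        K = 20
        edges = tree.edges()
        self.n_edges = len(edges)
        self.edge_len = np.array([e.length for e in edges])

        def propagate(v: np.ndarray, t: float) -> np.ndarray:
            ps = float(phylo.p_same(t))
            pd = float(phylo.p_diff(t))
            return pd * v.sum(axis=-1, keepdims=True) + (ps - pd) * v

        # distal pass (postorder)
        D: dict[int, np.ndarray] = {}
        Dlog: dict[int, np.ndarray] = {}
        for node in tree.postorder():
            if node.is_leaf:
                codes = aln.codes[row_of[node.name]]
                v = np.ones((S, K))
                res = codes >= 0
                v[res] = 0.0
                v[np.where(res)[0], codes[res].astype(int)] = 1.0
                D[id(node)] = v
                Dlog[id(node)] = np.zeros(S)
            else:
                v = np.ones((S, K))
                lg = np.zeros(S)
                for c in node.children:
                    v = v * propagate(D[id(c)], c.length)
                    lg = lg + Dlog[id(c)]
                    mx = v.max(axis=1)
                    mx = np.where(mx > 0, mx, 1.0)
                    v = v / mx[:, None]
                    lg = lg + np.log(mx)
                D[id(node)] = v
                Dlog[id(node)] = lg
        # proximal pass (preorder)
        V: dict[int, np.ndarray] = {}
        Vlog: dict[int, np.ndarray] = {}
        for node in tree.preorder():
            if node.parent is None:
                continue
            parent = node.parent
            if parent.parent is None:
                v = np.ones((S, K))
                lg = np.zeros(S)
            else:
                v = propagate(V[id(parent)], parent.length)
                lg = Vlog[id(parent)].copy()
            for sib in parent.children:
                if sib is node:
                    continue
                v = v * propagate(D[id(sib)], sib.length)
                lg = lg + Dlog[id(sib)]
                mx = v.max(axis=1)
                mx = np.where(mx > 0, mx, 1.0)
                v = v / mx[:, None]
                lg = lg + np.log(mx)
            V[id(node)] = v
            Vlog[id(node)] = lg
        # combine at midpoints
        pi = 1.0 / K
        self.Cn = np.empty((self.n_edges, S, K), dtype=np.float32)
        self.logT = np.empty((self.n_edges, S))
        for e_idx, node in enumerate(edges):
            half = node.length / 2.0
            dmid = propagate(D[id(node)], half)
            vmid = propagate(V[id(node)], half)
            comb = pi * dmid * vmid
            T = comb.sum(axis=1)
            T = np.where(T > 0, T, 1e-300)
            self.Cn[e_idx] = (comb / T[:, None]).astype(np.float32)
            self.logT[e_idx] = np.log(T) + Dlog[id(node)] + Vlog[id(node)]
        # distal subtree leaf sets per edge (used by the profiler)
        self.edge_leaves: list[frozenset[str]] = []
        for node in edges:
            self.edge_leaves.append(frozenset(l.name for l in node.leaves()))

    # -- likelihood -------------------------------------------------------
    def _loglik(self, idx: np.ndarray, chars: np.ndarray, t: np.ndarray,
                base: np.ndarray, G: np.ndarray) -> np.ndarray:
        ps = phylo.p_same(t)[:, None]
        pd = phylo.p_diff(t)[:, None]
        return base + np.log(pd + (ps - pd) * G).sum(axis=1)

    def place(self, aligned: AlignedRead, max_keep: int = 20) -> Placement:
        mask = aligned.col_map >= 0
        mask &= aligned.codes >= 0
        idx = aligned.col_map[mask]
        chars = aligned.codes[mask].astype(int)
        if len(idx) == 0:
            raise ValueError(f"read {aligned.read_id}: no aligned match columns")
        base = self.logT[:, idx].sum(axis=1)
        G = np.take_along_axis(self.Cn[:, idx, :].astype(np.float64),
                               chars[None, :, None], axis=2)[:, :, 0]
        E = self.n_edges
        # vectorized golden-section on [0, 5] per edge
        gr = (math.sqrt(5.0) - 1.0) / 2.0
        a = np.zeros(E)
        b = np.full(E, 5.0)
        x1 = b - gr * (b - a)
        x2 = a + gr * (b - a)
        f1 = self._loglik(idx, chars, x1, base, G)
        f2 = self._loglik(idx, chars, x2, base, G)
        for _ in range(30):
            left = f1 >= f2  # maximum in [a, x2]
            b = np.where(left, x2, b)
            a = np.where(left, a, x1)
            x1n = np.where(left, b - gr * (b - a), x2)
            x2n = np.where(left, x1, a + gr * (b - a))
            xnew = np.where(left, x1n, x2n)
            fnew = self._loglik(idx, chars, xnew, base, G)
            f2 = np.where(left, f1, fnew)
            f1 = np.where(left, fnew, f1)
            x1, x2 = x1n, x2n
        t_opt = 0.5 * (a + b)
        ll = self._loglik(idx, chars, t_opt, base, G)
        # likelihood weight ratios over ALL edges
        w = np.exp(ll - ll.max())
        lwr = w / w.sum()
        order = np.argsort(-lwr, kind="stable")[:max_keep]
        records = [
            (int(e), float(ll[e]), float(lwr[e]), float(self.edge_len[e] / 2.0), float(t_opt[e]))
            for e in order
        ]
        return Placement(read_id=aligned.read_id, records=records)


def place_read(aligned: AlignedRead, engine: PlacementEngine,
               max_keep: int = 20) -> Placement:
    """Place one aligned read (see :class:`PlacementEngine`)."""
    return engine.place(aligned, max_keep=max_keep)


# ---------------------------------------------------------------------------
# branch mass
# ---------------------------------------------------------------------------

def accumulate_branch_mass(placements: list[Placement], n_edges: int) -> np.ndarray:
    """Per-edge placement mass; each read's kept mass renormalized to 1 so
    the total equals the number of placed reads."""
    mass = np.zeros(n_edges)
    if not placements:
        import warnings

        warnings.warn("no placements: empty branch-mass row")
        return mass
    for pl in placements:
        tot = sum(r[2] for r in pl.records)
        if tot <= 0:
            continue
        for e, _ll, lwr, _d, _p in pl.records:
            mass[e] += lwr / tot
    return mass


# ---------------------------------------------------------------------------
# jplace exchange
# ---------------------------------------------------------------------------

def write_jplace(path: str, placements: list[Placement], tree: phylo.Node,
                 metadata: dict | None = None) -> None:
    doc = {
        "version": 3,
        "tree": tree.to_newick(edge_numbers=True),
        "fields": list(JPLACE_FIELDS),
        "placements": [
            {"p": [[int(e), ll, lwr, d, p] for e, ll, lwr, d, p in pl.records],
             "n": [pl.read_id]}
            for pl in placements
        ],
        "metadata": metadata or {"invocation": "microdiv"},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_jplace(path: str) -> tuple[list[Placement], phylo.Node]:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("fields") != JPLACE_FIELDS:
        raise ValueError(f"unexpected jplace fields: {doc.get('fields')}")
    tree = phylo.parse_newick(doc["tree"])
    known = {e.edge_num for e in tree.edges()}
    placements = []
    for entry in doc["placements"]:
        name = entry["n"][0] if "n" in entry else entry["nm"][0][0]
        records = []
        for rec in entry["p"]:
            e = int(rec[0])
            if e not in known:
                raise ValueError(f"read {name}: placement on unknown edge {e}")
            records.append((e, float(rec[1]), float(rec[2]), float(rec[3]), float(rec[4])))
        placements.append(Placement(read_id=name, records=records))
    return placements, tree
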