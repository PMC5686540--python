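"""Progressive multiple alignment of protein sequences.

ClustalO-style pipeline at desk scale: k-mer distances feed a neighbor-joining
guide tree, and alignments are merged bottom-up by profile-profile global
alignment (BLOSUM62, affine gap penalties -10 open / -1 extend).  The whole
procedure is deterministic: ties in the dynamic program break
diagonal > up (gap in second profile) > left.
"""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np
from Bio.Align import substitution_matrices

from .phylo import neighbor_joining
from .util import AMINO_ACIDS, N_AA, encode_protein

GAP = -2
GAP_OPEN = -10.0
GAP_EXTEND = -1.0

_B62 = None


def blosum62() -> np.ndarray:
    """BLOSUM62 as a dense 20x20 array over the package residue order."""
    global _B62
    if _B62 is None:
        mat = substitution_matrices.load("BLOSUM62")
        out = np.zeros((N_AA, N_AA))
        for i, a in enumerate(AMINO_ACIDS):
            for j, b in enumerate(AMINO_ACIDS):
                out[i, j] = mat[a, b]
        _B62 = out
    return _B62


class Alignment:
    """A gapped alignment: ordered ids plus an ``n_rows x n_cols`` code matrix.

    Codes: 0..19 residues, -1 unknown (X), -2 gap.
    """

    def __init__(self, ids: list[str], codes: np.ndarray):
        self.ids = list(ids)
        self.codes = np.asarray(codes, dtype=np.int8)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.ids):
            raise ValueError("alignment shape mismatch")

    @classmethod
    def from_sequences(cls, seqs: dict[str, str]) -> "Alignment":
        lens = {len(s) for s in seqs.values()}
        if len(lens) != 1:
            raise ValueError("rows have unequal length")
        ids = list(seqs)
        lut = {a: k for k, a in enumerate(AMINO_ACIDS)}
        codes = np.full((len(ids), lens.pop()), GAP, dtype=np.int8)
        for r, i in enumerate(ids):
            for c, ch in enumerate(seqs[i].upper()):
                codes[r, c] = GAP if ch in "-." else lut.get(ch, -1)
        return cls(ids, codes)

    @property
    def n_cols(self) -> int:
        return self.codes.shape[1]

    @property
    def n_rows(self) -> int:
        return self.codes.shape[0]

    def row(self, idx: int) -> str:
        return "".join(
            "-" if c == GAP else ("X" if c == -1 else AMINO_ACIDS[c]) for c in self.codes[idx]
        )

    def to_dict(self) -> dict[str, str]:
        return {i: self.row(r) for r, i in enumerate(self.ids)}

    def gap_fraction(self) -> np.ndarray:
        return (self.codes == GAP).mean(axis=0)

    def drop_allgap_columns(self) -> "Alignment":
        keep = ~(self.codes == GAP).all(axis=0)
        return Alignment(self.ids, self.codes[:, keep])

    def profile(self) -> np.ndarray:
        """Per-column residue frequencies (cols x 20), normalized over
        non-gap, non-X entries; all-gap columns give a zero row."""
        freq = np.zeros((self.n_cols, N_AA))
        for a in range(N_AA):
            freq[:, a] = (self.codes == a).sum(axis=0)
        tot = freq.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            freq = np.where(tot > 0, freq / np.maximum(tot, 1), 0.0)
        return freq


# ---------------------------------------------------------------------------
# profile-profile Needleman-Wunsch (Gotoh affine)
# ---------------------------------------------------------------------------

def _profile_align(a: Alignment, b: Alignment) -> Alignment:
    fa, fb = a.profile(), b.profile()
    S = fa @ blosum62() @ fb.T  # column-pair expected substitution score
    la, lb = a.n_cols, b.n_cols
    NEG = -1e30
    ar = np.arange(lb + 1)
    # three-state Gotoh, row-vectorized; the within-row gap state (gap in a,
    # consuming b columns) is resolved with a running-max-with-decay scan.
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)  # gap in b (consume a column)
    Y = np.full((la + 1, lb + 1), NEG)  # gap in a (consume b column)
    M[0, 0] = 0.0
    X[1:, 0] = GAP_OPEN + GAP_EXTEND * np.arange(la)
    Y[0, 1:] = GAP_OPEN + GAP_EXTEND * np.arange(lb)
    tbM = np.zeros((la + 1, lb + 1), dtype=np.int8)   # predecessor state of M
    tbX = np.zeros((la + 1, lb + 1), dtype=np.int8)   # predecessor state of X
    ystart = np.zeros((la + 1, lb + 1), dtype=np.int32)  # b-column where Y run opened
    yfromx = np.zeros((la + 1, lb + 1), dtype=bool)      # Y run opened from X (else M)
    for i in range(1, la + 1):
        prevM, prevX, prevY = M[i - 1], X[i - 1], Y[i - 1]
        stacked = np.stack([prevM, prevX, prevY])
        tb_prev = np.argmax(stacked, axis=0).astype(np.int8)
        best_prev = stacked[tb_prev, ar]
        M[i, 1:] = S[i - 1] + best_prev[:-1]
        tbM[i, 1:] = tb_prev[:-1]
        candX = np.stack([prevM + GAP_OPEN, prevX + GAP_EXTEND, prevY + GAP_OPEN])
        tbX[i] = np.argmax(candX, axis=0)
        X[i] = candX[tbX[i], ar]
        # Y[i, j] = max_{j0 < j} max(M[i,j0], X[i,j0]) + OPEN + EXT*(j-1-j0)
        mx = np.maximum(M[i], X[i])
        u = mx - GAP_EXTEND * ar
        run = np.maximum.accumulate(u)
        runidx = np.maximum.accumulate(np.where(u >= run, ar, 0))
        Y[i, 1:] = GAP_OPEN + GAP_EXTEND * (ar[1:] - 1) + run[:-1]
        ystart[i, 1:] = runidx[:-1]
        yfromx[i, 1:] = X[i, ystart[i, 1:]] > M[i, ystart[i, 1:]]
    # traceback from best terminal state (prefer M > X > Y on ties)
    i, j = la, lb
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    cols_a: list[int] = []  # a-column index or -1 (gap) per merged column, reversed
    cols_b: list[int] = []
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            cols_a.append(i - 1)
            cols_b.append(j - 1)
            state = int(tbM[i, j])
            i, j = i - 1, j - 1
        elif state == 1 and i > 0:
            cols_a.append(i - 1)
            cols_b.append(-1)
            state = int(tbX[i, j])
            i -= 1
        else:
            if i == 0:
                for jj in range(j, 0, -1):
                    cols_a.append(-1)
                    cols_b.append(jj - 1)
                j = 0
                break
            j0 = int(ystart[i, j])
            for jj in range(j, j0, -1):
                cols_a.append(-1)
                cols_b.append(jj - 1)
            state = 1 if yfromx[i, j] else 0
            j = j0
            if j == 0 and i > 0 and state == 0:
                state = 1  # column 0 in a row > 0 can only be a gap-in-b state
    cols_a.reverse()
    cols_b.reverse()
    ncol = len(cols_a)
    codes = np.full((a.n_rows + b.n_rows, ncol), GAP, dtype=np.int8)
    for k, ca in enumerate(cols_a):
        if ca >= 0:
            codes[: a.n_rows, k] = a.codes[:, ca]
    for k, cb in enumerate(cols_b):
        if cb >= 0:
            codes[a.n_rows :, k] = b.codes[:, cb]
    return Alignment(a.ids + b.ids, codes)


def pairwise_global(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Global pairwise alignment with the same scoring as the profile merge."""
    aln = _profile_align(
        Alignment(["a"], encode_protein(seq_a)[None, :]),
        Alignment(["b"], encode_protein(seq_b)[None, :]),
    )
    d = aln.to_dict()
    return d["a"], d["b"]


# ---------------------------------------------------------------------------
# guide tree and progressive merge
# ---------------------------------------------------------------------------

def kmer_distance(seq_a: str, seq_b: str, k: int = 3) -> float:
    ca = Counter(seq_a[i : i + k] for i in range(len(seq_a) - k + 1))
    cb = Counter(seq_b[i : i + k] for i in range(len(seq_b) - k + 1))
    shared = sum(min(ca[w], cb[w]) for w in ca)
    denom = min(sum(ca.values()), sum(cb.values()))
    if denom <= 0:
        return 1.0
    return 1.0 - shared / denom


def progressive_align(seqs: dict[str, str]) -> Alignment:
    """Progressive multiple alignment (k-mer guide distances + NJ + profile NW)."""
    ids = list(seqs)
    if len(ids) < 2:
        raise ValueError("progressive alignment requires at least 2 sequences")
    for i in ids:
        if not seqs[i]:
            raise ValueError(f"empty sequence: {i}")
    if len(ids) == 2:
        return _profile_align(
            Alignment([ids[0]], encode_protein(seqs[ids[0]])[None, :]),
            Alignment([ids[1]], encode_protein(seqs[ids[1]])[None, :]),
        )
    n = len(ids)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        D[i, j] = D[j, i] = kmer_distance(seqs[ids[i]], seqs[ids[j]])
    guide = neighbor_joining(D, ids)

    def merge(node) -> Alignment:
        if node.is_leaf:
            return Alignment([node.name], encode_protein(seqs[node.name])[None, :])
        sub = [merge(c) for c in node.children]
        out = sub[0]
        for nxt in sub[1:]:
            out = _profile_align(out, nxt)
        return out

    merged = merge(guide)
    # restore input row order
    order = [merged.ids.index(i) for i in ids]
    return Alignment(ids, merged.codes[order])
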