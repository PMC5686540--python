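"""Shared low-level helpers: alphabets, seeded stream splitting, FASTA/TSV I/O."""

from __future__ import annotations

import zlib
from typing import Iterable, Mapping

import numpy as np

#: canonical 20-residue protein alphabet (order fixed package-wide)
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
N_AA = 20

NUCLEOTIDES = "ACGT"
NT_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}


def rng_for(seed: int, *tags) -> np.random.Generator:
    """Return a generator for a named substream of the root ``seed``.

    All randomness in the package flows from one root seed.  Substreams are
    identified by a tuple of tags (strings/ints); each tag is folded to a
    32-bit word with CRC32 so the rule is stable across sessions and
    platforms.  Identical ``(seed, tags)`` always yields the same stream.
    """
    words = [int(seed) & 0x7FFFFFFF]
    for t in tags:
        words.append(zlib.crc32(str(t).encode()) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(words))


def encode_protein(seq: str) -> np.ndarray:
    """Encode a protein string to int8 indices; ``X`` (or any non-residue) -> -1."""
    out = np.full(len(seq), -1, dtype=np.int8)
    for i, c in enumerate(seq.upper()):
        out[i] = AA_INDEX.get(c, -1)
    return out


def decode_protein(codes: Iterable[int]) -> str:
    return "".join(AMINO_ACIDS[c] if c >= 0 else "X" for c in codes)


def write_fasta(path, records: Mapping[str, str] | Iterable[tuple[str, str]], width: int = 80) -> None:
    """Write records as wrapped FASTA (80 columns by default)."""
    items = records.items() if hasattr(records, "items") else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    out: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        out[name] = "".join(chunks)
    return out
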