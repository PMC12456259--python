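"""FracMinHash (scaled MinHash) sketching of nucleotide assemblies.

A sketch retains every canonical k-mer hash below ``2**64 // scaled``,
i.e. an expected fraction ``1/scaled`` of all distinct k-mers. Because the
retained set is a uniform random subsample of the k-mer space, the Jaccard
index and containment of two sketches are unbiased estimators of the same
quantities on the full k-mer sets, with accuracy governed by sketch size.

k-mers are canonicalized as ``min(kmer, revcomp(kmer))`` so sketches are
strand-insensitive; windows containing non-ACGT characters are skipped.
Hashing packs each canonical k-mer into a 64-bit integer (2 bits per base,
hence k <= 31) and applies the splitmix64 finalizer seeded from the
configuration, so sketches are deterministic across runs and platforms.
Sketches make no claim of numeric compatibility with external sketching
tools; only the estimators are equivalent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

_CODES = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODES[_b] = _i
    _CODES[_b + 32] = _i  # lowercase

_MAX_HASH = np.uint64(2**64 - 1)


@dataclass
class Sketch:
    """FracMinHash sketch of one sample assembly or catalogue genome."""

    name: str
    k: int
    scaled: int
    hashes: frozenset

    def __post_init__(self) -> None:
        self.hashes = frozenset(int(h) for h in self.hashes)
        cap = 2**64 // self.scaled
        bad = [h for h in self.hashes if h >= cap]
        if bad:
            raise ValueError(f"sketch {self.name}: {len(bad)} hashes above cap")

    def __len__(self) -> int:
        return len(self.hashes)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "name": self.name,
            "k": self.k,
            "scaled": self.scaled,
            "hashes": sorted(self.hashes),
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "Sketch":
        doc = json.loads(Path(path).read_text())
        return cls(doc["name"], doc["k"], doc["scaled"], frozenset(doc["hashes"]))


def _splitmix64(x: np.ndarray) -> np.ndarray:
    # Finalizer of the splitmix64 generator; a strong 64-bit mixer.
    with np.errstate(over="ignore"):
        x = x + np.uint64(0x9E3779B97F4A7C15)
        x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        x = x ^ (x >> np.uint64(31))
    return x


def canonical_kmer_hashes(sequence: str, k: int, seed: int = 42) -> set[int]:
    """64-bit hashes of the distinct canonical k-mers of ``sequence``.

    Returns the empty set when the sequence is shorter than k. k-mers
    containing characters outside ACGT (case-insensitive) are skipped.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > 31:
        raise ValueError("k must be <= 31 for 2-bit packing")
    n = len(sequence)
    if n < k:
        return set()
    codes = _CODES[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    valid = codes < 4
    codes64 = codes.astype(np.uint64)
    comp64 = np.where(valid, np.uint64(3) - codes64, codes64)

    m = n - k + 1
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    with np.errstate(over="ignore"):
        for i in range(k):
            fwd = (fwd << np.uint64(2)) | codes64[i : i + m]
            # reverse complement reads positions k-1-i of each window
            rev = (rev << np.uint64(2)) | comp64[k - 1 - i : k - 1 - i + m]
    # windows free of non-ACGT characters
    ok = np.all(
        np.lib.stride_tricks.sliding_window_view(valid, k), axis=1
    )
    canon = np.minimum(fwd, rev)[ok]
    if canon.size == 0:
        return set()
    hashed = _splitmix64(canon ^ np.uint64(seed & (2**64 - 1)))
    return set(int(h) for h in np.unique(hashed))


def frac_sketch(hashes, scaled: int, name: str, k: int) -> Sketch:
    """Retain exactly the hashes below ``2**64 // scaled``."""
    if scaled < 1:
        raise ValueError("scaled must be >= 1")
    cap = 2**64 // scaled
    kept = frozenset(h for h in hashes if h < cap)
    return Sketch(name=name, k=k, scaled=scaled, hashes=kept)


def sketch_sequences(sequences, name: str, k: int, scaled: int, seed: int = 42) -> Sketch:
    """Sketch a collection of sequences (e.g. all contigs of one sample)."""
    hashes: set[int] = set()
    for seq in sequences:
        hashes |= canonical_kmer_hashes(seq, k, seed=seed)
    return frac_sketch(hashes, scaled, name, k)


def _check_compatible(a: Sketch, b: Sketch) -> None:
    if a.k != b.k or a.scaled != b.scaled:
        raise ValueError(
            f"incompatible sketches: ({a.k},{a.scaled}) vs ({b.k},{b.scaled})"
        )


def jaccard(a: Sketch, b: Sketch) -> float:
    """Estimated Jaccard index of the two k-mer sets; 0 when both empty."""
    _check_compatible(a, b)
    union = len(a.hashes | b.hashes)
    if union == 0:
        logger.warning("jaccard(%s, %s): both sketches empty, returning 0", a.name, b.name)
        return 0.0
    return len(a.hashes & b.hashes) / union


def containment(query: Sketch, subject: Sketch) -> float:
    """Estimated fraction of the query's k-mers present in the subject."""
    _check_compatible(query, subject)
    if len(query.hashes) == 0:
        logger.warning("containment(%s, %s): empty query, returning 0", query.name, subject.name)
        return 0.0
    return len(query.hashes & subject.hashes) / len(query.hashes)
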