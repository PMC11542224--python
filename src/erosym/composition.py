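"""Canonical k-mer composition analysis.

Pentanucleotide (5-mer) frequency vectors summarize the mutational signature
of a genome; a horizontally acquired region such as a biosynthetic gene
cluster retains its donor's signature for a long time, so its composition
vector sits far from the recipient chromosome's. Counting is canonical: a
k-mer and its reverse complement share one key (the lexicographic minimum),
making vectors strand-invariant. For odd k there are 4^k/2 canonical k-mers
(512 for k = 5; no odd-length DNA palindromes exist).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_model import Genome, IntervalSet

_BASE_LUT = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_LUT[ord(_b)] = _i
    _BASE_LUT[ord(_b.lower())] = _i

_CANON_CACHE: dict[int, tuple[np.ndarray, int]] = {}


def _canonical_map(k: int) -> tuple[np.ndarray, int]:
    """Map each of the 4^k k-mer codes to a canonical rank; returns (map, dim)."""
    if k in _CANON_CACHE:
        return _CANON_CACHE[k]
    n = 4**k
    codes = np.arange(n)
    rc = np.zeros(n, dtype=np.int64)
    tmp = codes.copy()
    for _ in range(k):
        rc = rc * 4 + (3 - (tmp % 4))
        tmp //= 4
    canon = np.minimum(codes, rc)
    uniq, ranks = np.unique(canon, return_inverse=True)
    _CANON_CACHE[k] = (ranks, len(uniq))
    return _CANON_CACHE[k]


def canonical_dim(k: int) -> int:
    return _canonical_map(k)[1]


@dataclass
class KmerVector:
    """Normalized canonical k-mer frequencies for a sequence region."""

    k: int
    frequencies: np.ndarray
    total_count: int
    source: str = ""

    def __post_init__(self) -> None:
        if self.total_count > 0 and abs(float(self.frequencies.sum()) - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")


def _count_codes(seq: str, k: int) -> np.ndarray:
    arr = _BASE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(arr) - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        win = arr[j : j + n]
        codes = codes * 4 + np.maximum(win, 0)
        valid &= win >= 0  # windows containing N (or other junk) are skipped
    return codes[valid]


def kmer_vector(source, k: int = 5, canonical: bool = True, label: str = "") -> KmerVector:
    """Canonical k-mer frequency vector of a sequence, genome, or interval set.

    ``source`` may be a DNA string, a :class:`Genome` (whole-genome vector),
    or a ``(genome, IntervalSet)`` pair restricting counting to the
    intervals. Windows containing N are skipped; sequences shorter than k
    are an error.
    """
    if isinstance(source, Genome):
        seqs = [r.sequence for r in source.replicons]
        label = label or source.genome_id
    elif isinstance(source, tuple) and isinstance(source[1], IntervalSet):
        genome, ivals = source
        ivals.validate_against(genome)
        seqs = [genome.replicon(r).sequence[s - 1 : e] for r, s, e in ivals]
        label = label or f"{genome.genome_id}:intervals"
    else:
        seqs = [str(source)]
    if all(len(s) < k for s in seqs):
        raise ValueError(f"usable sequence shorter than k={k}")

    ranks, dim = _canonical_map(k)
    counts = np.zeros(dim if canonical else 4**k, dtype=np.int64)
    for s in seqs:
        if len(s) < k:
            continue
        codes = _count_codes(s, k)
        if canonical:
            codes = ranks[codes]
        counts += np.bincount(codes, minlength=len(counts))
    total = int(counts.sum())
    if total == 0:
        raise ValueError("no valid k-mer windows (all contain N?)")
    return KmerVector(k=k, frequencies=counts / total, total_count=total, source=label)


def composition_distance(v1: KmerVector, v2: KmerVector, metric: str = "euclidean") -> float:
    if v1.k != v2.k:
        raise ValueError(f"mismatched k: {v1.k} vs {v2.k}")
    d = v1.frequencies - v2.frequencies
    if metric == "euclidean":
        return float(np.sqrt(np.dot(d, d)))
    if metric == "manhattan":
        return float(np.abs(d).sum())
    raise ValueError(f"unknown metric {metric!r}")


def ordinate(vectors: list[KmerVector]) -> np.ndarray:
    """Classical metric scaling (PCoA) of composition vectors into 2-D.

    Double-centers the squared Euclidean distance matrix and projects on the
    top two eigenvectors. Coordinates are defined only up to
    rotation/reflection; compare pairwise distances, not raw axes.
    """
    if len(vectors) < 3:
        raise ValueError("need at least 3 vectors")
    m = len(vectors)
    D2 = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            D2[i, j] = D2[j, i] = composition_distance(vectors[i], vectors[j]) ** 2
    J = np.eye(m) - np.ones((m, m)) / m
    B = -0.5 * J @ D2 @ J
    vals, vecs = np.linalg.eigh(B)
    idx = np.argsort(vals)[::-1][:2]
    coords = vecs[:, idx] * np.sqrt(np.maximum(vals[idx], 0.0))
    return coords


def bgc_anomaly_score(
    genome: Genome,
    bgc_interval: IntervalSet,
    k: int = 5,
    window: int = 20000,
    step: int = 10000,
) -> float:
    """Percentile rank of a BGC's compositional distance from its genome.

    The distance from the BGC's k-mer vector to the whole-genome vector is
    ranked against distances of background windows (``window`` bp every
    ``step`` bp) that do not overlap the BGC. Mid-ranks are used for ties, so
    under the null (BGC drawn from the genome's own composition) the
    percentile is approximately uniform on [0, 100]. High percentiles are
    evidence the region was horizontally acquired.
    """
    bgc_interval.validate_against(genome)
    bgc_bp = sum(e - s + 1 for _, s, e in bgc_interval)
    if bgc_bp >= genome.size:
        raise ValueError("BGC covers the whole genome")
    genome_vec = kmer_vector(genome, k=k)
    bgc_vec = kmer_vector((genome, bgc_interval), k=k)
    d_bgc = composition_distance(bgc_vec, genome_vec)

    background: list[float] = []
    for rep in genome.replicons:
        L = len(rep)
        pos = 1
        last_end = 0
        while pos + window - 1 <= L:
            end = pos + window - 1
            overlaps_bgc = any(
                r == rep.id and not (e < pos or s > end) for r, s, e in bgc_interval
            )
            if not overlaps_bgc and pos > last_end:  # non-overlapping background only
                wv = kmer_vector(rep.sequence[pos - 1 : end], k=k)
                background.append(composition_distance(wv, genome_vec))
                last_end = end
            pos += step
    if len(background) < 2:
        raise ValueError(
            f"only {len(background)} background windows outside the BGC; need >= 2"
        )
    arr = np.asarray(background)
    less = float((arr < d_bgc).sum())
    eq = float((arr == d_bgc).sum())
    return 100.0 * (less + 0.5 * eq) / len(arr)
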