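"""Subgenome assignment from subgenome-specific (differential) k-mers.

An allopolyploid's two progenitor genomes each carry private repeat families;
canonical k-mers enriched in one member of every homoeologous chromosome pair
therefore separate the chromosomes into subgenomes.  The filters follow the
published convention: odd k (default 13), a minimum total count (default 100)
and a minimum between-homoeolog fold change (default 2).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .genome import AnnotatedGenome

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


class PhasingSignalError(RuntimeError):
    """Raised when no k-mer survives the differential filters.

    Either the subgenomes carry no subgenome-specific repeats at the requested
    fold, or the thresholds are too strict for the amount of sequence; try a
    lower ``min_total``/``min_fold`` or a different k.
    """


def kmer_to_string(code: int, k: int) -> str:
    return "".join("ACGT"[(code >> (2 * (k - 1 - i))) & 3] for i in range(k))


def canonical_kmer_codes(seq: str, k: int) -> np.ndarray:
    """Canonical (lexicographic min of strand pair) k-mer codes of a sequence.

    Windows containing non-ACGT characters are skipped.  Codes pack bases
    A=0, C=1, G=2, T=3 into 2 bits each, most significant base first.
    """
    arr = _CODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
    n = arr.size - k + 1
    if n <= 0:
        raise ValueError(f"sequence shorter than k={k}")
    valid = arr < 4
    ok = np.ones(n, dtype=bool)
    bad = np.flatnonzero(~valid)
    for b in bad:
        ok[max(0, b - k + 1):b + 1] = False
    a64 = arr.astype(np.int64)
    fwd = np.zeros(n, dtype=np.int64)
    rev = np.zeros(n, dtype=np.int64)
    for i in range(k):
        window = np.where(valid[i:i + n], a64[i:i + n], 0)
        fwd += window << (2 * (k - 1 - i))
        rev += (3 - window) << (2 * i)
    return np.minimum(fwd, rev)[ok]


@dataclass
class KmerMatrix:
    """Per-chromosome canonical k-mer counts (sparse, one array pair per row)."""

    k: int
    codes: dict[str, np.ndarray]      # chromosome -> sorted unique codes
    counts: dict[str, np.ndarray]     # chromosome -> counts aligned to codes
    lengths: dict[str, int]

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.codes)

    def total_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """(codes, summed counts) aggregated over all chromosomes."""
        all_codes = np.concatenate([self.codes[c] for c in self.chromosomes])
        all_counts = np.concatenate([self.counts[c] for c in self.chromosomes])
        uniq, inv = np.unique(all_codes, return_inverse=True)
        sums = np.zeros(uniq.size, dtype=np.int64)
        np.add.at(sums, inv, all_counts)
        return uniq, sums

    def count_matrix(self, codes: np.ndarray, normalize: bool = False) -> pd.DataFrame:
        """Dense chromosomes x codes count matrix for the given codes."""
        rows = {}
        for chrom in self.chromosomes:
            idx = np.searchsorted(self.codes[chrom], codes)
            idx = np.clip(idx, 0, self.codes[chrom].size - 1)
            hit = self.codes[chrom][idx] == codes
            vals = np.where(hit, self.counts[chrom][idx], 0).astype(float)
            if normalize:
                vals /= self.lengths[chrom]
            rows[chrom] = vals
        return pd.DataFrame.from_dict(rows, orient="index", columns=codes)

    def restrict(self, codes: np.ndarray) -> "KmerMatrix":
        codes = np.sort(codes)
        new_codes, new_counts = {}, {}
        for chrom in self.chromosomes:
            keep = np.isin(self.codes[chrom], codes)
            new_codes[chrom] = self.codes[chrom][keep]
            new_counts[chrom] = self.counts[chrom][keep]
        return KmerMatrix(self.k, new_codes, new_counts, dict(self.lengths))


@dataclass
class SubgenomeAssignment:
    labels: dict[str, str]                       # chromosome -> 'A' | 'D'
    confidence: dict[str, float]                 # silhouette-like separation
    diagnostic_kmers: dict[str, list[str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chromosome": sorted(self.labels),
            "label": [self.labels[c] for c in sorted(self.labels)],
            "score": [self.confidence[c] for c in sorted(self.labels)]})


def count_kmers(genome: AnnotatedGenome, k: int = 13) -> KmerMatrix:
    """Count canonical k-mers per chromosome, normalisable by length."""
    if k % 2 == 0 or not 3 <= k <= 21:
        raise ValueError(f"k must be odd and in [3, 21], got {k}")
    codes, counts, lengths = {}, {}, {}
    for chrom in sorted(genome.chromosomes):
        seq = genome.chromosomes[chrom]
        if len(seq) < k:
            raise ValueError(f"chromosome {chrom} shorter than k={k}")
        uniq, cnt = np.unique(canonical_kmer_codes(seq, k), return_counts=True)
        codes[chrom], counts[chrom] = uniq, cnt.astype(np.int64)
        lengths[chrom] = len(seq)
    return KmerMatrix(k=k, codes=codes, counts=counts, lengths=lengths)


def select_differential_kmers(matrix: KmerMatrix,
                              homoeolog_pairs: list[tuple[str, str]],
                              min_total: int = 100,
                              min_fold: float = 2.0) -> KmerMatrix:
    """Retain k-mers with total count >= min_total whose between-homoeolog
    fold change (max over min, with the denominator floored at one count to
    avoid division by zero) is >= min_fold in a majority of pairs."""
    paired = {c for pair in homoeolog_pairs for c in pair}
    missing = set(matrix.chromosomes) - paired
    if missing:
        raise ValueError(f"homoeolog pairing does not cover {sorted(missing)}")

    codes, totals = matrix.total_counts()
    candidates = codes[totals >= min_total]
    if candidates.size:
        dense = matrix.count_matrix(candidates)
        votes = np.zeros(candidates.size, dtype=int)
        for a, d in homoeolog_pairs:
            hi = np.maximum(dense.loc[a].to_numpy(), dense.loc[d].to_numpy())
            lo = np.minimum(dense.loc[a].to_numpy(), dense.loc[d].to_numpy())
            fold = hi / np.maximum(lo, 1.0)
            votes += (fold >= min_fold).astype(int)
        selected = candidates[votes * 2 > len(homoeolog_pairs)]
    else:
        selected = candidates
    if selected.size == 0:
        raise PhasingSignalError(
            f"no phasing signal: no k-mer passed total>={min_total} and "
            f"fold>={min_fold} in a majority of {len(homoeolog_pairs)} pairs")
    return matrix.restrict(selected)


def assign_subgenomes(matrix: KmerMatrix,
                      homoeolog_pairs: list[tuple[str, str]],
                      ) -> SubgenomeAssignment:
    """Two-group hierarchical clustering (correlation distance, average
    linkage) of chromosomes on the length-normalised differential matrix,
    required to split every homoeologous pair; labels are arbitrary up to a
    global A/D swap and anchored to the lexicographically first chromosome."""
    codes, _ = matrix.total_counts()
    if codes.size == 0:
        raise PhasingSignalError("differential k-mer matrix is empty")
    dense = matrix.count_matrix(codes, normalize=True)
    dense = dense.sort_index()
    X = dense.to_numpy()
    centered = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    norms[norms == 0] = 1.0
    corr = (centered / norms[:, None]) @ (centered / norms[:, None]).T
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    clusters = fcluster(Z, t=2, criterion="maxclust")

    chroms = list(dense.index)
    cluster_of = dict(zip(chroms, clusters))
    for a, d in homoeolog_pairs:
        if cluster_of[a] == cluster_of[d]:
            raise RuntimeError(
                f"homoeologous pair ({a}, {d}) fell in the same cluster; "
                f"differential k-mers do not separate the subgenomes")

    anchor = cluster_of[chroms[0]]
    labels = {c: ("A" if cluster_of[c] == anchor else "D") for c in chroms}

    confidence = {}
    for i, c in enumerate(chroms):
        same = [j for j, o in enumerate(chroms) if j != i and clusters[j] == clusters[i]]
        other = [j for j, o in enumerate(chroms) if clusters[j] != clusters[i]]
        a = float(np.mean(dist[i, same])) if same else 0.0
        b = float(np.mean(dist[i, other]))
        confidence[c] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0

    diag: dict[str, list[str]] = {"A": [], "D": []}
    mean_a = X[[labels[c] == "A" for c in chroms]].mean(axis=0)
    mean_d = X[[labels[c] == "D" for c in chroms]].mean(axis=0)
    for code, ma, md in zip(codes, mean_a, mean_d):
        diag["A" if ma >= md else "D"].append(kmer_to_string(int(code), matrix.k))
    return SubgenomeAssignment(labels=labels, confidence=confidence,
                               diagnostic_kmers=diag)
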