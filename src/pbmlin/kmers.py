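"""K-mer features and sparse binary design matrices.

A probe's measured log intensity is modelled as a sum of affinity
contributions of the K-mers contained in its sequence.  This module
enumerates candidate K-mer features (contiguous 4-8-mers and optionally
8-mers with a single ignored base), ranks 7/8-mers by their median probe
intensity for regularization, and builds the sparse binary containment
matrix H (probes x features, plus a trailing intercept column of ones).

Containment is evaluated over the full probe sequence, flanks included;
the model's mean subtraction guards against flank K-mers absorbing the
background intensity.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse

from .exceptions import SequenceAlphabetError

ALPHABET = "ACGT"
_RC_TABLE = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of an A/C/G/T string."""
    if any(c not in "ACGT" for c in seq):
        bad = next(c for c in seq if c not in "ACGT")
        raise SequenceAlphabetError(f"invalid base {bad!r} in sequence")
    return seq.translate(_RC_TABLE)[::-1]


@dataclass(frozen=True)
class KmerFeature:
    """One design-matrix column: a K-mer pattern, optionally gapped.

    ``pattern`` holds the informative bases only.  If ``gap_offset`` is set,
    a single ignored base sits after position ``gap_offset`` (1-based count
    of informative bases preceding the gap), so the feature matches a window
    of ``k + 1`` bases.  ``canonical`` marks features that stand for a
    {pattern, reverse-complement} pair in the strand-tied model.
    """

    pattern: str
    gap_offset: int | None = None
    canonical: bool = False

    def __post_init__(self) -> None:
        if any(c not in "ACGT" for c in self.pattern):
            raise SequenceAlphabetError(
                f"invalid base in feature pattern {self.pattern!r}")
        if self.gap_offset is not None and not (
                1 <= self.gap_offset <= len(self.pattern) - 1):
            raise ValueError(
                f"gap_offset {self.gap_offset} not strictly inside "
                f"{len(self.pattern)}-mer")

    @property
    def k(self) -> int:
        """Number of informative bases."""
        return len(self.pattern)

    @property
    def span(self) -> int:
        """Window length the feature occupies in a sequence."""
        return self.k + (1 if self.gap_offset is not None else 0)

    @property
    def is_gapped(self) -> bool:
        return self.gap_offset is not None

    def key(self) -> tuple[str, int]:
        return (self.pattern, -1 if self.gap_offset is None else self.gap_offset)

    def reverse_complement(self) -> "KmerFeature":
        rc = reverse_complement(self.pattern)
        g = None if self.gap_offset is None else self.k - self.gap_offset
        return KmerFeature(rc, g, self.canonical)


def canonical_key(pattern: str, gap_offset: int | None) -> tuple[str, int]:
    """Canonical (pattern, gap) key for a {feature, revcomp} pair.

    The canonical representative is the lexicographically smaller of the
    pattern and its reverse complement (ties broken on the gap offset).
    """
    rc = pattern.translate(_RC_TABLE)[::-1]
    g = -1 if gap_offset is None else gap_offset
    grc = -1 if gap_offset is None else len(pattern) - gap_offset
    return min((pattern, g), (rc, grc))


def canonicalize(feature: KmerFeature) -> KmerFeature:
    pat, g = canonical_key(feature.pattern, feature.gap_offset)
    return KmerFeature(pat, None if g == -1 else g, canonical=True)


@dataclass
class KmerSet:
    """Ordered collection of K-mer features defining design-matrix columns.

    The intercept (all-ones) column is implicit and always last.
    """

    features: list[KmerFeature]
    strand_tied: bool = False
    _index: dict[tuple[str, int], int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        for j, f in enumerate(self.features):
            key = f.key()
            if key in self._index:
                raise ValueError(f"duplicate feature {f.pattern}")
            self._index[key] = j

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    @property
    def n_columns(self) -> int:
        """Feature columns plus the intercept column."""
        return len(self.features) + 1

    def column_of(self, feature: KmerFeature) -> int:
        return self._index[feature.key()]

    @property
    def max_span(self) -> int:
        return max((f.span for f in self.features), default=0)

    def partition_by_k(self) -> list[tuple[tuple[int, bool], list[int]]]:
        """Column indices grouped by (k, is_gapped), ascending in k."""
        groups: dict[tuple[int, bool], list[int]] = {}
        for j, f in enumerate(self.features):
            groups.setdefault((f.k, f.is_gapped), []).append(j)
        return sorted(groups.items())


@dataclass
class DesignMatrix:
    """Sparse binary probe x feature matrix with trailing intercept column."""

    matrix: sparse.csr_matrix
    row_ids: list[str]
    kmer_set: KmerSet

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


def enumerate_kmers(k: int) -> list[KmerFeature]:
    """All 4^k contiguous K-mers in lexicographic order."""
    if not 1 <= k <= 12:
        raise ValueError(f"k={k} out of supported range 1..12")
    return [KmerFeature("".join(p))
            for p in itertools.product(ALPHABET, repeat=k)]


def enumerate_gapped_kmers(k: int = 8, gap_offset: int = 4) -> list[KmerFeature]:
    """All 4^k K-mers with one ignored base after ``gap_offset`` informative
    bases; each matches a (k+1)-base window."""
    if not 1 <= gap_offset <= k - 1:
        raise ValueError(f"gap_offset {gap_offset} out of range for k={k}")
    return [KmerFeature("".join(p), gap_offset)
            for p in itertools.product(ALPHABET, repeat=k)]


def enumerate_gapped_8mers(gap_offset: int = 4) -> list[KmerFeature]:
    return enumerate_gapped_kmers(8, gap_offset)


def _window_patterns(seq: str, k: int, gap_offset: int | None) -> Iterable[str]:
    """Patterns of all (possibly gapped) k-windows of ``seq``, forward strand."""
    span = k + (1 if gap_offset is not None else 0)
    if gap_offset is None:
        for i in range(len(seq) - span + 1):
            yield seq[i:i + span]
    else:
        g = gap_offset
        for i in range(len(seq) - span + 1):
            yield seq[i:i + g] + seq[i + g + 1:i + span]


def kmer_median_intensities(
    sample,
    k: int,
    gapped: bool = False,
    gap_offset: int = 4,
) -> dict[str, tuple[float, int]]:
    """Median log intensity and support count per observed K-mer.

    Containment is strand-specific over the probe sequence as written
    (flanks included).  Probes with missing intensity are ignored; each
    probe contributes at most once per K-mer regardless of copy number.
    Features absent from every probe are omitted.
    """
    g = gap_offset if gapped else None
    values: dict[str, list[float]] = {}
    for seq, y in zip(sample.sequences(), sample.intensities()):
        if np.isnan(y):
            continue
        for pat in set(_window_patterns(seq, k, g)):
            values.setdefault(pat, []).append(float(y))
    return {pat: (float(np.median(v)), len(v)) for pat, v in values.items()}


def _rank_features(medians: Mapping[str, tuple[float, int]]) -> list[str]:
    # highest median first; ties broken by higher support, then pattern order
    return [p for p, _ in sorted(
        medians.items(), key=lambda kv: (-kv[1][0], -kv[1][1], kv[0]))]


def select_kmers(
    sample,
    full_ks: Sequence[int] = (4, 5, 6),
    top_counts: Mapping[int, int] | None = None,
    gapped_top: int = 0,
    gap_offset: int = 4,
    median_cache: dict | None = None,
) -> KmerSet:
    """Select the regularized feature set from a preprocessed sample.

    All K-mers of each length in ``full_ks`` are kept; for each length in
    ``top_counts`` only the requested number of highest-median-intensity
    K-mers is kept.  ``median_cache`` may be shared across calls to avoid
    recomputing median tables during parameter sweeps.
    """
    if top_counts is None:
        top_counts = {7: 2000, 8: 1000}
    features: list[KmerFeature] = []
    for k in sorted(full_ks):
        features.extend(enumerate_kmers(k))

    def medians_for(k: int, gapped: bool) -> dict[str, tuple[float, int]]:
        if median_cache is not None:
            key = (k, gapped, gap_offset if gapped else None)
            if key not in median_cache:
                median_cache[key] = kmer_median_intensities(
                    sample, k, gapped=gapped, gap_offset=gap_offset)
            return median_cache[key]
        return kmer_median_intensities(sample, k, gapped=gapped,
                                       gap_offset=gap_offset)

    for k, n in sorted(top_counts.items()):
        if n <= 0:
            continue
        med = medians_for(k, False)
        if n > len(med):
            warnings.warn(
                f"requested {n} top {k}-mers but only {len(med)} observed; "
                "clamping", stacklevel=2)
            n = len(med)
        features.extend(KmerFeature(p) for p in _rank_features(med)[:n])

    if gapped_top > 0:
        med = medians_for(8, True)
        n = min(gapped_top, len(med))
        if n < gapped_top:
            warnings.warn(
                f"requested {gapped_top} gapped 8-mers but only {len(med)} "
                "observed; clamping", stacklevel=2)
        features.extend(KmerFeature(p, gap_offset)
                        for p in _rank_features(med)[:n])
    return KmerSet(features)


def select_top_kmers(sample, n7: int = 2000, n8: int = 1000,
                     gapped_n: int = 0, gap_offset: int = 4) -> KmerSet:
    """Default regularized set: all 4-6-mers plus the top-median 7/8-mers
    (8376 K-mer features with the default counts)."""
    return select_kmers(sample, full_ks=(4, 5, 6),
                        top_counts={7: n7, 8: n8},
                        gapped_top=gapped_n, gap_offset=gap_offset)


def build_design_matrix(
    sequences: Sequence[str],
    kmer_set: KmerSet,
    strand_tied: bool | None = None,
    row_ids: Sequence[str] | None = None,
) -> DesignMatrix:
    """Binary containment matrix H for ``sequences`` against ``kmer_set``.

    Entry (i, j) is 1 iff feature j occurs in sequence i on the forward
    strand (strand-specific) or on either strand (strand-tied); multiple
    occurrences still give 1.  A final all-ones intercept column is
    appended.
    """
    tied = kmer_set.strand_tied if strand_tied is None else strand_tied
    seqs = [s.upper() for s in sequences]
    if not seqs:
        raise ValueError("no sequences given")
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
    seq_len = lengths.pop()
    if kmer_set.features and seq_len < kmer_set.max_span:
        raise ValueError(
            f"sequence length {seq_len} shorter than the longest feature "
            f"span {kmer_set.max_span}")

    col: dict[tuple[str, int], int] = dict(kmer_set._index)
    configs = set()
    for f in kmer_set.features:
        configs.add((f.k, f.gap_offset))
        if tied and f.gap_offset is not None:
            configs.add((f.k, f.k - f.gap_offset))
    configs = sorted(configs, key=lambda c: (c[0], -1 if c[1] is None else c[1]))

    n_feat = len(kmer_set.features)
    indptr = [0]
    indices: list[int] = []
    for seq in seqs:
        hit: set[int] = set()
        for k, g in configs:
            for pat in _window_patterns(seq, k, g):
                key = canonical_key(pat, g) if tied else (pat, -1 if g is None else g)
                j = col.get(key)
                if j is not None:
                    hit.add(j)
        row_cols = sorted(hit)
        row_cols.append(n_feat)  # intercept
        indices.extend(row_cols)
        indptr.append(len(indices))

    data = np.ones(len(indices), dtype=np.float64)
    H = sparse.csr_matrix((data, np.asarray(indices), np.asarray(indptr)),
                          shape=(len(seqs), n_feat + 1))
    if row_ids is None:
        row_ids = [f"probe_{i}" for i in range(len(seqs))]
    return DesignMatrix(H, list(row_ids), kmer_set)
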