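"""Harmonic and formal k-mer filters and the feature matrices they induce.

A *basic* harmonic filter of length K is a template over K-1 successive
root intervals (mod 12) plus a major/minor quality bit per position; its
response to a song is the number of K-chord windows matching the template
exactly.  A *tau-normalized* filter instead templates the K root offsets
relative to the song's tonic, carries one quality bit per position, and an
extra key bit that must equal the song's mode — making responses invariant
under transposition.  Formal filters are plain k-mers over section labels
(verse/chorus/...).

Songs-by-filters count matrices are binarized (count >= 1) for the
generative model; low-support filters (non-zero in fewer than
``min_support`` songs of the fitting corpus) are pruned and the retained
filter list frozen for reuse on held-out data.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus import Corpus, Song

BASIC, TAU = "basic", "tau"


@dataclass(frozen=True)
class HarmonicFilter:
    """One harmonic k-mer template.

    ``transitions`` has length K-1 for kind ``basic`` (successive root
    intervals) and K for kind ``tau`` (offsets from the tonic);
    ``chord_types`` has length K; ``key_bit`` is used only by tau filters.
    """

    kind: str
    K: int
    transitions: tuple[int, ...]
    chord_types: tuple[int, ...]
    key_bit: int = 0

    def __post_init__(self) -> None:
        want = self.K - 1 if self.kind == BASIC else self.K
        if self.kind not in (BASIC, TAU):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if len(self.transitions) != want:
            raise ValueError(
                f"{self.kind} K={self.K} filter needs {want} transitions, "
                f"got {len(self.transitions)}")
        if len(self.chord_types) != self.K:
            raise ValueError("chord_types length must equal K")
        if any(not 0 <= t <= 11 for t in self.transitions):
            raise ValueError("transitions must lie in 0..11")
        if any(u not in (0, 1) for u in self.chord_types):
            raise ValueError("chord_types must be binary")


@dataclass(frozen=True)
class FormalFilter:
    """A k-mer template over formal-section category indices."""

    K: int
    labels: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != self.K:
            raise ValueError("labels length must equal K")


def enumerate_basic_filters(K: int) -> list[HarmonicFilter]:
    """All 12^(K-1) * 2^K basic filters; transitions vary fastest, then
    chord-type vectors."""
    if K < 1:
        raise ValueError("K must be >= 1")
    return [
        HarmonicFilter(BASIC, K, trans, types)
        for types in itertools.product((0, 1), repeat=K)
        for trans in itertools.product(range(12), repeat=K - 1)
    ]


def enumerate_tau_filters(K: int) -> list[HarmonicFilter]:
    """All 12^K * 2^(K+1) tau-normalized filters; transitions fastest,
    then chord types, key bit slowest."""
    if K < 1:
        raise ValueError("K must be >= 1")
    return [
        HarmonicFilter(TAU, K, trans, types, key_bit)
        for key_bit in (0, 1)
        for types in itertools.product((0, 1), repeat=K)
        for trans in itertools.product(range(12), repeat=K)
    ]


def enumerate_formal_filters(K: int, n_categories: int) -> list[FormalFilter]:
    """All n_categories^K formal k-mer filters."""
    if K < 1:
        raise ValueError("K must be >= 1")
    return [FormalFilter(K, labs)
            for labs in itertools.product(range(n_categories), repeat=K)]


# ---------------------------------------------------------------------------
# Responses.  The per-filter functions slide a window literally; the matrix
# builder below instead keys each window once and counts, which is what
# makes K=4 enumeration spaces (27648 filters) tractable.
# ---------------------------------------------------------------------------

def _basic_key(song: Song, i: int, K: int):
    ch = song.chords
    trans = tuple((ch[i + j + 1].root - ch[i + j].root) % 12 for j in range(K - 1))
    types = tuple(ch[i + j].quality for j in range(K))
    return trans, types


def _tau_key(song: Song, i: int, K: int):
    ch = song.chords
    offs = tuple((ch[i + j].root - song.tonality.tonic) % 12 for j in range(K))
    types = tuple(ch[i + j].quality for j in range(K))
    return offs, types, song.tonality.mode


def basic_response(song: Song, f: HarmonicFilter) -> int:
    """Count of K-chord windows matching a basic filter's interval and
    quality template."""
    if f.kind != BASIC:
        raise ValueError("basic_response requires a basic filter")
    n = len(song.chords) - f.K + 1
    return sum(_basic_key(song, i, f.K) == (f.transitions, f.chord_types)
               for i in range(max(n, 0)))


def tau_response(song: Song, g: HarmonicFilter) -> int:
    """Count of windows matching a tau filter; zero unless the song's mode
    equals the filter's key bit."""
    if g.kind != TAU:
        raise ValueError("tau_response requires a tau filter")
    if song.tonality.mode != g.key_bit:
        return 0
    n = len(song.chords) - g.K + 1
    target = (g.transitions, g.chord_types, g.key_bit)
    return sum(_tau_key(song, i, g.K) == target for i in range(max(n, 0)))


def formal_response(song: Song, f: FormalFilter,
                    vocabulary: list[str]) -> int:
    """Count of windows of the formal-label sequence matching the filter,
    with labels resolved through ``vocabulary`` (index order)."""
    idx = {lab: k for k, lab in enumerate(vocabulary)}
    seq = [idx[lab] for lab in song.formal if lab in idx]
    n = len(seq) - f.K + 1
    return sum(tuple(seq[i:i + f.K]) == f.labels for i in range(max(n, 0)))


def filter_response(song: Song, f, vocabulary: list[str] | None = None) -> int:
    if isinstance(f, FormalFilter):
        return formal_response(song, f, vocabulary or [])
    return basic_response(song, f) if f.kind == BASIC else tau_response(song, f)


# ---------------------------------------------------------------------------
# Feature matrices
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Songs x filters counts plus the binarized view fitted by the model."""

    counts: np.ndarray
    filters: list
    song_ids: list[str]
    support: np.ndarray = field(default=None)  # songs with non-zero response
    formal_vocabulary: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.support is None:
            self.support = (self.counts > 0).sum(axis=0)

    @property
    def binary(self) -> np.ndarray:
        return (self.counts >= 1).astype(np.int8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_files(self, matrix_path, filter_path) -> None:
        pd.DataFrame(self.counts, index=pd.Index(self.song_ids, name="id")) \
            .to_csv(matrix_path)
        rows = []
        for f in self.filters:
            if isinstance(f, FormalFilter):
                rows.append({"kind": "formal", "K": f.K,
                             "transitions": "",
                             "chord_types": "",
                             "labels": " ".join(map(str, f.labels)),
                             "key_bit": ""})
            else:
                rows.append({"kind": f.kind, "K": f.K,
                             "transitions": " ".join(map(str, f.transitions)),
                             "chord_types": " ".join(map(str, f.chord_types)),
                             "labels": "",
                             "key_bit": f.key_bit if f.kind == TAU else ""})
        pd.DataFrame(rows).to_csv(filter_path, index=False)

    @classmethod
    def from_files(cls, matrix_path, filter_path) -> "FeatureMatrix":
        mat = pd.read_csv(matrix_path, index_col="id")
        fdf = pd.read_csv(filter_path, dtype=str, keep_default_na=False)
        filters = []
        for r in fdf.itertuples(index=False):
            if r.kind == "formal":
                filters.append(FormalFilter(int(r.K),
                                            tuple(map(int, r.labels.split()))))
            else:
                filters.append(HarmonicFilter(
                    r.kind, int(r.K),
                    tuple(map(int, r.transitions.split())),
                    tuple(map(int, r.chord_types.split())),
                    int(r.key_bit) if r.key_bit != "" else 0))
        return cls(mat.to_numpy(), filters, [str(i) for i in mat.index])


def response_matrix(corpus: Corpus, filters: list,
                    formal_vocabulary: list[str] | None = None) -> np.ndarray:
    """Raw counts for an arbitrary (possibly mixed-kind) filter list, keyed
    per window so the cost is O(total windows), not O(songs x filters)."""
    col_of: dict = {}
    for j, f in enumerate(filters):
        if isinstance(f, FormalFilter):
            key = ("formal", f.K, f.labels)
        elif f.kind == BASIC:
            key = (BASIC, f.K, f.transitions, f.chord_types)
        else:
            key = (TAU, f.K, f.transitions, f.chord_types, f.key_bit)
        col_of.setdefault(key, []).append(j)
    Ks_basic = {f.K for f in filters
                if isinstance(f, HarmonicFilter) and f.kind == BASIC}
    Ks_tau = {f.K for f in filters
              if isinstance(f, HarmonicFilter) and f.kind == TAU}
    Ks_formal = {f.K for f in filters if isinstance(f, FormalFilter)}
    vocab_idx = {lab: k for k, lab in enumerate(formal_vocabulary or [])}

    X = np.zeros((len(corpus), len(filters)), dtype=int)
    for n, song in enumerate(corpus):
        seen: Counter = Counter()
        for K in Ks_basic:
            for i in range(len(song.chords) - K + 1):
                t, u = _basic_key(song, i, K)
                seen[(BASIC, K, t, u)] += 1
        for K in Ks_tau:
            for i in range(len(song.chords) - K + 1):
                offs, u, mode = _tau_key(song, i, K)
                seen[(TAU, K, offs, u, mode)] += 1
        if Ks_formal:
            seq = tuple(vocab_idx[lab] for lab in song.formal if lab in vocab_idx)
            for K in Ks_formal:
                for i in range(len(seq) - K + 1):
                    seen[("formal", K, seq[i:i + K])] += 1
        for key, count in seen.items():
            for j in col_of.get(key, ()):
                X[n, j] = count
    return X


def build_feature_matrix(corpus: Corpus, filters: list, min_support: int = 1,
                         formal_vocabulary: list[str] | None = None,
                         concat: FeatureMatrix | None = None) -> FeatureMatrix:
    """Compute responses, prune filters supported by fewer than
    ``min_support`` songs, and (optionally) append the columns of a second,
    already-built matrix with rows aligned by song id."""
    X = response_matrix(corpus, filters, formal_vocabulary)
    support = (X > 0).sum(axis=0)
    keep = support >= min_support
    if not keep.any() and (concat is None or concat.counts.shape[1] == 0):
        raise ValueError(
            f"all {len(filters)} filters pruned at min_support={min_support}; "
            "lower min_support")
    kept = [f for f, k in zip(filters, keep) if k]
    fm = FeatureMatrix(X[:, keep], kept, [s.id for s in corpus],
                       support[keep], formal_vocabulary)
    if concat is not None:
        order = {sid: i for i, sid in enumerate(concat.song_ids)}
        if set(order) != set(fm.song_ids):
            raise ValueError("concat matrices cover different songs")
        rows = [order[sid] for sid in fm.song_ids]
        fm = FeatureMatrix(
            np.hstack([fm.counts, concat.counts[rows]]),
            fm.filters + list(concat.filters), fm.song_ids,
            np.concatenate([fm.support, concat.support]),
            formal_vocabulary)
    return fm


# ---------------------------------------------------------------------------
# Formal-category coarse-graining
# ---------------------------------------------------------------------------

def coarse_grain_formal(corpus: Corpus, strategy: str = "identity",
                        manual_map: dict[str, str] | None = None,
                        tail_share: float = 0.01,
                        other_label: str = "other"):
    """Build a label mapping over the observed formal vocabulary.

    ``identity`` keeps the observed categories; ``manual_map`` applies a
    user projection (e.g. outro/fadeout -> end); ``tail_to_other`` merges
    the M smallest categories onto ``other``, with M the largest count of
    smallest-frequency categories whose combined share of observed labels
    is at most ``tail_share`` (frequency ties broken alphabetically).

    Returns ``(mapping, vocabulary)``; total label mass is conserved.
    """
    counts: Counter = Counter(lab for s in corpus for lab in s.formal)
    observed = sorted(counts)
    if strategy == "identity":
        mapping = {lab: lab for lab in observed}
    elif strategy == "manual_map":
        unknown = set(manual_map or {}) - set(observed)
        if unknown:
            raise ValueError(f"manual_map references unknown labels: {sorted(unknown)}")
        mapping = {lab: (manual_map or {}).get(lab, lab) for lab in observed}
    elif strategy == "tail_to_other":
        total = sum(counts.values())
        by_rarity = sorted(observed, key=lambda lab: (counts[lab], lab))
        merged, acc = set(), 0
        for lab in by_rarity:
            if total and (acc + counts[lab]) / total <= tail_share:
                merged.add(lab)
                acc += counts[lab]
            else:
                break
        mapping = {lab: (other_label if lab in merged else lab) for lab in observed}
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    vocabulary = sorted(set(mapping.values()))
    return mapping, vocabulary


def apply_formal_mapping(corpus: Corpus, mapping: dict[str, str]) -> Corpus:
    from dataclasses import replace
    return Corpus([replace(s, formal=[mapping.get(lab, lab) for lab in s.formal])
                   for s in corpus])


# ---------------------------------------------------------------------------
# Motif spectra and indexed-residual SVD (exploratory views)
# ---------------------------------------------------------------------------

def chord_single_index(root: int, quality: int) -> int:
    """Mod-24 single-chord index: root + 12 * quality."""
    return root + 12 * quality


def chord_pair_index(first: tuple[int, int], second: tuple[int, int]) -> int:
    """Pair index 24 * single(first) + single(second), in 0..575."""
    return 24 * chord_single_index(*first) + chord_single_index(*second)


def motif_spectrum(song: Song, K: int = 2, normalize: bool = False) -> np.ndarray:
    """Occurrence counts of chord K-mers over the 24^K mod-24 index space
    (first chord is the most significant digit); optionally normalized to a
    frequency distribution (an all-zero vector stays all-zero)."""
    if K < 2:
        raise ValueError("K must be >= 2")
    spec = np.zeros(24 ** K)
    ch = song.chords
    for i in range(len(ch) - K + 1):
        idx = 0
        for j in range(K):
            idx = idx * 24 + chord_single_index(ch[i + j].root, ch[i + j].quality)
        spec[idx] += 1
    if normalize and spec.sum() > 0:
        spec /= spec.sum()
    return spec


def svd_residual_map(counts: np.ndarray, standardize: bool = True):
    """SVD of a songs x transition-index count matrix's residuals.

    Residuals are correspondence-analysis standardized residuals
    (observed - expected) / sqrt(expected) under row/column independence;
    cells with zero expected count get residual 0.  ``standardize=False``
    decomposes the raw counts instead.  Returns
    ``(singular_values, left_factors, right_factors)`` in descending
    singular-value order.
    """
    X = np.asarray(counts, dtype=float)
    total = X.sum()
    if total <= 0:
        raise ValueError("count matrix has zero grand total")
    if standardize:
        expected = np.outer(X.sum(axis=1), X.sum(axis=0)) / total
        R = np.zeros_like(X)
        nz = expected > 0
        R[nz] = (X[nz] - expected[nz]) / np.sqrt(expected[nz])
    else:
        R = X
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    return s, U, Vt
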