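"""Synthetic corpora with known ground truth.

The generator realizes the point-wise mutational process the energy prior
is motivated by: a chronological sequence of B-bit codes where each bit of
a song's code flips independently with probability ``flip_rate`` relative
to the previous song, a known one-layer decoder mapping codes to Bernoulli
feature probabilities, and (optionally) chord sequences realizing the
active signatures through per-bit motif pools.  Everything is seeded and
bit-reproducible.

An exact Gibbs sampler for the energy prior itself is included for
small-N prior-sampling tests (the global normalizer is intractable, so
the flip process — not prior sampling — is the default generator).
"""

from __future__ import annotations

from datetime import date, timedelta

import numpy as np
from scipy.optimize import linear_sum_assignment

from .corpus import ChordSymbol, Corpus, Song, Tonality, dedup_repeats
from .model import Decoder, EvoGraph, code_table


def simulate_codes(N: int, B: int, flip_rate: float, seed: int = 0) -> np.ndarray:
    """Markov flip process: row 0 is iid Bernoulli(0.5); each later row
    flips each bit of its predecessor independently with ``flip_rate``."""
    if not 0 <= flip_rate <= 0.5:
        raise ValueError("flip_rate must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    Z = np.empty((N, B), dtype=int)
    Z[0] = rng.random(B) < 0.5
    for t in range(1, N):
        flips = rng.random(B) < flip_rate
        Z[t] = np.where(flips, 1 - Z[t - 1], Z[t - 1])
    return Z


def simulate_decoder(B: int, F: int, strength: float = 2.0,
                     seed: int = 0) -> Decoder:
    """One-layer ground-truth decoder.

    Weights are iid from {-strength, 0, +strength} with probabilities
    (1/3, 1/3, 1/3); each bias is -(column weight sum)/2 so that under
    uniform codes the logit distribution is symmetric about 0 and every
    feature's marginal frequency is exactly 0.5.
    """
    if strength < 0:
        raise ValueError("strength must be >= 0")
    rng = np.random.default_rng(seed)
    dec = Decoder(B, F, depth=1, rng=0)
    W = rng.choice([-strength, 0.0, strength], size=(B, F))
    dec.weights[0] = W
    dec.biases[0] = -W.sum(axis=0) / 2.0
    return dec


def simulate_features(codes: np.ndarray, decoder: Decoder,
                      seed: int = 0) -> np.ndarray:
    """Sample the binary feature matrix: X[n, f] ~ Bernoulli(p[n, f]) with
    p the decoder output for song n's code."""
    codes = np.asarray(codes)
    if codes.shape[1] != decoder.B:
        raise ValueError("code width must match decoder input size")
    rng = np.random.default_rng(seed)
    p = decoder.forward(codes)
    return (rng.random(p.shape) < p).astype(int)


def default_motif_pools(B: int, k: int = 2, pool_size: int = 3,
                        seed: int = 0):
    """Disjoint per-bit pools of chord k-mers plus a background pool,
    drawn without replacement from the 24^k k-mer space."""
    rng = np.random.default_rng(seed)
    needed = (B + 1) * pool_size
    picks = rng.choice(24 ** k, size=needed, replace=False)

    def kmer(idx: int):
        chords = []
        for _ in range(k):
            idx, single = divmod(idx, 24)
            chords.append(ChordSymbol(single % 12, single // 12))
        return tuple(reversed(chords))

    pools = [[kmer(int(i)) for i in picks[b * pool_size:(b + 1) * pool_size]]
             for b in range(B)]
    background = [kmer(int(i)) for i in picks[B * pool_size:]]
    return pools, background


def simulate_chord_corpus(codes: np.ndarray, pools=None, background=None,
                          length: int = 40, seed: int = 0,
                          start: date = date(1958, 1, 1),
                          attach_genres: bool = True) -> Corpus:
    """Realize codes as chord sequences.

    Song n concatenates k-mers drawn uniformly from the pools of its
    active bits plus the background pool until at least ``length`` chords,
    then prunes consecutive repeats.  Tonality is fixed C major, dates
    follow code order, and (optionally) genre label ``"sig<b>"`` is
    attached for each active bit so genre prediction is exercisable.
    """
    codes = np.asarray(codes)
    N, B = codes.shape
    if pools is None or background is None:
        auto_pools, auto_bg = default_motif_pools(B, seed=seed)
        pools = auto_pools if pools is None else pools
        background = auto_bg if background is None else background
    if len(pools) != B or any(not p for p in pools) or not background:
        raise ValueError("need one non-empty pool per bit plus a background pool")
    rng = np.random.default_rng(seed)
    songs = []
    for n in range(N):
        active = [pools[b] for b in range(B) if codes[n, b]]
        sources = active + [background]
        chords: list[ChordSymbol] = []
        while len(chords) < length:
            pool = sources[rng.integers(len(sources))]
            chords.extend(pool[rng.integers(len(pool))])
        genres = frozenset(f"sig{b}" for b in range(B) if codes[n, b]) \
            if attach_genres else frozenset()
        songs.append(Song(
            id=f"syn{n:05d}",
            chords=dedup_repeats(chords),
            tonality=Tonality(4, 0),            # C major
            date=start + timedelta(days=n),
            genres=genres,
        ))
    return Corpus(songs)


def make_genre_labels(codes: np.ndarray):
    """Genre sets derived from code patterns: song n belongs to genre
    ``sig<b>`` iff its bit b is on."""
    codes = np.asarray(codes)
    return [frozenset(f"sig{b}" for b in range(codes.shape[1]) if row[b])
            for row in codes]


def recovery_score(fitted, truth: np.ndarray) -> float:
    """Best mean per-bit agreement between fitted and true codes over
    signature permutations and per-bit polarity flips.

    ``fitted`` may be an N x B_fit binary code matrix or an N x 2^B
    posterior (converted to thresholded bit marginals).  Polarity is free
    per matched pair and assignment is solved exactly (Hungarian on the
    flip-maximized agreement matrix, which equals the exhaustive search
    over permutations x flips since polarity decouples per pair).
    """
    fitted = np.asarray(fitted, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if fitted.ndim != 2 or fitted.shape[0] != truth.shape[0]:
        raise ValueError("fitted and truth must cover the same songs")
    if fitted.shape[1] != truth.shape[1] and (fitted.shape[1] & (fitted.shape[1] - 1)) == 0 \
            and fitted.shape[1] >= 2 ** truth.shape[1] and np.allclose(fitted.sum(1), 1):
        fitted = fitted @ code_table(int(np.log2(fitted.shape[1])))  # posterior
    bits = (fitted >= 0.5).astype(int)
    if bits.shape[1] < truth.shape[1]:
        raise ValueError("fitted code width must be >= true width")
    Bt, Bf = truth.shape[1], bits.shape[1]
    A = np.empty((Bt, Bf))
    for b in range(Bt):
        for c in range(Bf):
            agree = float(np.mean(truth[:, b] == bits[:, c]))
            A[b, c] = max(agree, 1 - agree)
    rows, cols = linear_sum_assignment(-A)
    return float(A[rows, cols].mean())


def gibbs_sample_prior(graph: EvoGraph, B: int, gamma: float,
                       n_sweeps: int = 200, seed: int = 0) -> np.ndarray:
    """Gibbs sampling from the energy prior P(Z) ~ exp(-E(Z)) on a small
    graph: per bit, P(Z_i(b)=1 | rest) = sigmoid(gamma * sum_j G_ij *
    (2 Z_j(b) - 1))."""
    rng = np.random.default_rng(seed)
    N = graph.n
    Z = (rng.random((N, B)) < 0.5).astype(int)
    for _ in range(n_sweeps):
        for i in range(N):
            js, ws = graph.neighbors[i]
            field = gamma * (ws[:, None] * (2 * Z[js] - 1)).sum(axis=0) \
                if len(js) else np.zeros(B)
            p1 = 1.0 / (1.0 + np.exp(-field))
            Z[i] = rng.random(B) < p1
    return Z
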