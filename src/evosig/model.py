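"""Latent evolutionary signatures: a binary-latent generative model whose
codes are coupled by an energy prior over a temporal graph.

Each song n carries a latent code Z_n in {0,1}^B (one bit per
*evolutionary signature*).  A decoder network NN(Z; theta) maps a code to
per-feature Bernoulli probabilities for the binarized feature matrix, and
the prior P(Z) ~ exp(-E(Z)) with

    E(Z) = sum_{i, j<i} G(i,j) * gamma * Hamming(Z_i, Z_j)

penalizes code disagreement between graph-adjacent songs.  G is a
symmetric non-negative closeness matrix; the default is a temporal-window
adjacency G(i,j) = [0 < |i-j| <= w] on chronological ranks.

Fitting is variational Bayes EM with a mean-field posterior that is
explicit over all 2^B codes per song (B is capped at 7), alternating
sequential per-song E-step updates with gradient M-steps on theta.  The
reported ELBO omits the prior's (constant) log-partition term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils import check_random_state

logger = logging.getLogger(__name__)

MAX_BITS = 7  # explicit 2^B posteriors only
PROB_CLIP = 1e-6


def code_table(B: int) -> np.ndarray:
    """The canonical code order: row c is the binary expansion of c with
    bit 0 varying fastest (codes[c, b] = (c >> b) & 1)."""
    c = np.arange(2 ** B)
    return ((c[:, None] >> np.arange(B)[None, :]) & 1).astype(float)


def hamming_table(B: int) -> np.ndarray:
    """2^B x 2^B matrix of Hamming distances between all code pairs."""
    C = code_table(B)
    return np.abs(C[:, None, :] - C[None, :, :]).sum(axis=2)


# ---------------------------------------------------------------------------
# Evolutionary graph and energy
# ---------------------------------------------------------------------------

@dataclass
class EvoGraph:
    """Symmetric non-negative closeness matrix over songs; the diagonal is
    ignored by every energy sum."""

    weights: np.ndarray
    window: int | None = None

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("graph weights must be square")
        if not np.allclose(W, W.T):
            raise ValueError("graph weights must be symmetric")
        if (W < 0).any():
            raise ValueError("graph weights must be non-negative")
        self.weights = W
        # neighbour lists (j, weight) excluding the diagonal
        self.neighbors = []
        for i in range(W.shape[0]):
            js = np.nonzero(W[i])[0]
            js = js[js != i]
            self.neighbors.append((js, W[i, js]))

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def edges(self):
        """(i, j, weight) with j < i over non-zero off-diagonal entries."""
        ii, jj = np.nonzero(np.tril(self.weights, k=-1))
        return zip(ii, jj, self.weights[ii, jj])


def build_window_graph(N: int, w: int) -> EvoGraph:
    """Temporal-window adjacency: G(i,j) = 1 iff 0 < |i - j| <= w, with
    indices read as chronological ranks."""
    if N < 1 or w < 0:
        raise ValueError("need N >= 1 and w >= 0")
    idx = np.arange(N)
    d = np.abs(idx[:, None] - idx[None, :])
    return EvoGraph(((d > 0) & (d <= w)).astype(float), window=w)


def pair_energy(beta: np.ndarray, beta_prime: np.ndarray, g: float,
                gamma: float) -> float:
    """E_{i,j}(beta, beta') = g * gamma * Hamming(beta, beta')."""
    beta = np.asarray(beta)
    beta_prime = np.asarray(beta_prime)
    if beta.shape != beta_prime.shape:
        raise ValueError("codes must have equal length")
    return float(g * gamma * np.sum(beta != beta_prime))


def total_energy(Z: np.ndarray, graph: EvoGraph, gamma: float) -> float:
    """E(Z): sum of pair energies over unordered graph edges (j < i)."""
    Z = np.asarray(Z)
    if Z.shape[0] != graph.n:
        raise ValueError("code list size must match graph size")
    return float(sum(pair_energy(Z[i], Z[j], g, gamma)
                     for i, j, g in graph.edges()))


# ---------------------------------------------------------------------------
# Decoder: feed-forward map from B-bit codes to F Bernoulli probabilities
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Decoder:
    """A small MLP with sigmoid output.  depth=1 is a single affine layer
    (logits = Z @ W + c), deeper decoders interpose ReLU hidden layers of
    width ``hidden``.  Forward/backward are hand-written numpy."""

    def __init__(self, B: int, F: int, depth: int = 1, hidden: int = 16,
                 rng=None, init_scale: float = 0.1):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        rng = check_random_state(rng)
        self.B, self.F, self.depth, self.hidden = B, F, depth, hidden
        dims = [B] + [hidden] * (depth - 1) + [F]
        self.weights = [rng.normal(0.0, init_scale, size=(dims[k], dims[k + 1]))
                        for k in range(depth)]
        self.biases = [np.zeros(dims[k + 1]) for k in range(depth)]

    @property
    def params(self) -> list[np.ndarray]:
        return self.weights + self.biases

    def copy(self) -> "Decoder":
        new = object.__new__(Decoder)
        new.B, new.F, new.depth, new.hidden = self.B, self.F, self.depth, self.hidden
        new.weights = [w.copy() for w in self.weights]
        new.biases = [b.copy() for b in self.biases]
        return new

    def logits(self, codes: np.ndarray, keep_cache: bool = False):
        a = np.atleast_2d(np.asarray(codes, dtype=float))
        cache = [a]
        for k in range(self.depth - 1):
            a = np.maximum(a @ self.weights[k] + self.biases[k], 0.0)
            cache.append(a)
        out = a @ self.weights[-1] + self.biases[-1]
        return (out, cache) if keep_cache else out

    def forward(self, codes: np.ndarray) -> np.ndarray:
        """Bernoulli probabilities, one row per code; values in (0, 1)."""
        return _sigmoid(self.logits(codes))

    def backward(self, codes: np.ndarray, dlogits: np.ndarray):
        """Gradients of a scalar objective w.r.t. every parameter, given
        its gradient w.r.t. the output logits."""
        _, cache = self.logits(codes, keep_cache=True)
        gW = [None] * self.depth
        gb = [None] * self.depth
        delta = dlogits
        for k in range(self.depth - 1, -1, -1):
            gW[k] = cache[k].T @ delta
            gb[k] = delta.sum(axis=0)
            if k > 0:
                delta = (delta @ self.weights[k].T) * (cache[k] > 0)
        return gW + gb


def decoder_forward(beta: np.ndarray, decoder: Decoder) -> np.ndarray:
    """Probability vector for a single code."""
    return decoder.forward(np.atleast_2d(beta))[0]


def log_pgen(x: np.ndarray, beta: np.ndarray, decoder: Decoder) -> float:
    """Bernoulli log-likelihood of one binary feature row under one code,
    with probabilities clipped to [1e-6, 1-1e-6]."""
    p = np.clip(decoder_forward(beta, decoder), PROB_CLIP, 1 - PROB_CLIP)
    x = np.asarray(x, dtype=float)
    return float(np.sum(x * np.log(p) + (1 - x) * np.log1p(-p)))


def loglik_matrix(X: np.ndarray, decoder: Decoder,
                  codes: np.ndarray) -> np.ndarray:
    """N x 2^B matrix L[i, c] = log P_gen(X_i | code c)."""
    p = np.clip(decoder.forward(codes), PROB_CLIP, 1 - PROB_CLIP)
    X = np.asarray(X, dtype=float)
    return X @ np.log(p).T + (1 - X) @ np.log1p(-p).T


# ---------------------------------------------------------------------------
# VBEM steps
# ---------------------------------------------------------------------------

def _softmax(s: np.ndarray) -> np.ndarray:
    s = s - s.max()
    e = np.exp(s)
    return e / e.sum()


def estep_update(i: int, Q: np.ndarray, L: np.ndarray, graph: EvoGraph,
                 gamma: float, form: str = "printed",
                 codes: np.ndarray | None = None,
                 H: np.ndarray | None = None) -> np.ndarray:
    """One local mean-field update for song i; returns the normalized row.

    ``printed`` places exp(-E) inside the neighbour expectation:
        log q_{i,b} = L[i,b] + sum_j sum_b' q_{j,b'} exp(-E_ij(b,b'))
    ``expected_energy`` is the textbook update using the expected energy:
        log q_{i,b} = L[i,b] - gamma * sum_j G_ij * E_{q_j}[Hamming(b, Z_j)]
    Both restrict the sum to graph neighbours of i.
    """
    B = int(np.log2(Q.shape[1]))
    codes = code_table(B) if codes is None else codes
    H = hamming_table(B) if H is None else H
    s = L[i].astype(float).copy()
    js, ws = graph.neighbors[i]
    if form == "printed":
        for j, g in zip(js, ws):
            s += np.exp(-g * gamma * H) @ Q[j]
    elif form == "expected_energy":
        if len(js):
            m = Q[js] @ codes                       # neighbour bit marginals
            on_cost = (ws[:, None] * (1 - m)).sum(axis=0)   # bit set in beta
            off_cost = (ws[:, None] * m).sum(axis=0)        # bit clear
            s -= gamma * (codes @ on_cost + (1 - codes) @ off_cost)
    else:
        raise ValueError(f"unknown estep_form {form!r}")
    if not np.all(np.isfinite(s)):
        raise FloatingPointError(f"non-finite E-step scores for song index {i}")
    return _softmax(s)


def _expected_objective(decoder: Decoder, codes: np.ndarray, S: np.ndarray,
                        Nbeta: np.ndarray) -> float:
    p = np.clip(decoder.forward(codes), PROB_CLIP, 1 - PROB_CLIP)
    return float(np.sum(S * np.log(p) + (Nbeta[:, None] - S) * np.log1p(-p)))


def mstep(Q: np.ndarray, X: np.ndarray, decoder: Decoder, steps: int = 20,
          form: str = "expected", rng=None, learning_rate: float = 0.05,
          codes: np.ndarray | None = None) -> Decoder:
    """Gradient M-step on the decoder.

    ``expected`` ascends the exact objective
    sum_i sum_beta q_{i,beta} log P_gen(X_i | beta) (tractable because the
    2^B posterior is explicit); ``sampled`` draws one code per song per
    step from Q and ascends the Monte-Carlo objective.  Adam-style update;
    under ``expected`` the parameters with the best objective seen across
    steps are returned, so the step never decreases the objective.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    rng = check_random_state(rng)
    B = decoder.B
    codes = code_table(B) if codes is None else codes
    X = np.asarray(X, dtype=float)
    dec = decoder.copy()
    mom = [np.zeros_like(p) for p in dec.params]
    vel = [np.zeros_like(p) for p in dec.params]
    b1, b2, eps = 0.9, 0.999, 1e-8

    if form == "expected":
        S = Q.T @ X
        Nbeta = Q.sum(axis=0)
    elif form != "sampled":
        raise ValueError(f"unknown mstep_form {form!r}")

    best_obj, best_params = -np.inf, None
    for t in range(1, steps + 1):
        if form == "sampled":
            draws = np.array([rng.choice(Q.shape[1], p=Q[i] / Q[i].sum())
                              for i in range(Q.shape[0])])
            Q_hat = np.zeros_like(Q)
            Q_hat[np.arange(Q.shape[0]), draws] = 1.0
            S = Q_hat.T @ X
            Nbeta = Q_hat.sum(axis=0)
        if form == "expected":
            obj = _expected_objective(dec, codes, S, Nbeta)
            if obj > best_obj:
                best_obj = obj
                best_params = [p.copy() for p in dec.params]
        p = dec.forward(codes)
        dlogits = S - Nbeta[:, None] * p          # gradient of the objective
        grads = dec.backward(codes, dlogits)
        for k, (par, g) in enumerate(zip(dec.params, grads)):
            mom[k] = b1 * mom[k] + (1 - b1) * g
            vel[k] = b2 * vel[k] + (1 - b2) * g * g
            mhat = mom[k] / (1 - b1 ** t)
            vhat = vel[k] / (1 - b2 ** t)
            par += learning_rate * mhat / (np.sqrt(vhat) + eps)   # ascent
    if form == "expected":
        if _expected_objective(dec, codes, S, Nbeta) < best_obj:
            for par, bp in zip(dec.params, best_params):
                par[...] = bp
    return dec


def expected_energy(Q: np.ndarray, graph: EvoGraph, gamma: float,
                    codes: np.ndarray | None = None) -> float:
    """Closed-form E_Q[E(Z)] from the per-bit marginals of Q."""
    B = int(np.log2(Q.shape[1]))
    codes = code_table(B) if codes is None else codes
    m = Q @ codes
    total = 0.0
    for i, j, g in graph.edges():
        total += g * gamma * np.sum(m[i] + m[j] - 2 * m[i] * m[j])
    return float(total)


def elbo(Q: np.ndarray, X: np.ndarray, decoder: Decoder, graph: EvoGraph,
         gamma: float, codes: np.ndarray | None = None) -> float:
    """ELBO up to the prior's constant log-partition:
    E_Q[log P_gen] - E_Q[E(Z)] + H(Q)."""
    B = decoder.B
    codes = code_table(B) if codes is None else codes
    L = loglik_matrix(X, decoder, codes)
    recon = float(np.sum(Q * L))
    q = np.clip(Q, 1e-300, None)
    entropy = float(-np.sum(Q * np.log(q)))
    return recon - expected_energy(Q, graph, gamma, codes) + entropy


# ---------------------------------------------------------------------------
# Signature report
# ---------------------------------------------------------------------------

@dataclass
class SignatureReport:
    """Per-song signature activations (unit mean per signature over the
    timeline) and the per-signature feature-weight view."""

    activations: np.ndarray   # T x B, mean over T is 1 per column
    weights: np.ndarray       # B x F (first-layer weights)
    normalizers: np.ndarray   # the per-signature means that were divided out


def signature_report(Q: np.ndarray, decoder: Decoder) -> SignatureReport:
    """Activations omega[t, b] = marginal P(bit b on in song t) divided by
    its mean over songs (a never-active bit keeps activation 0); the
    weight view is the one-layer weight matrix W (for deeper decoders the
    first-layer weights are reported with a caveat)."""
    B = decoder.B
    marg = Q @ code_table(B)
    z = marg.mean(axis=0)
    omega = np.divide(marg, z[None, :], out=np.zeros_like(marg),
                      where=z[None, :] > 0)
    if decoder.depth > 1:
        logger.warning("signature_report: decoder depth %d > 1; reporting "
                       "first-layer weights", decoder.depth)
    return SignatureReport(omega, decoder.weights[0].T.copy(), z)


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class EvolutionarySignatureModel(TransformerMixin, BaseEstimator):
    """Graph-coupled binary-latent model of a binarized feature matrix.

    Parameters
    ----------
    B : int
        Number of signature bits (latent code length), at most 7.
    gamma : float
        Energy weight of the evolutionary prior; 0 decouples the songs.
    window : int
        Temporal window w for the default graph (ignored when ``fit`` is
        given an explicit graph).
    epochs, mstep_steps, learning_rate
        VBEM schedule: one sequential E-step sweep plus one M-step of
        ``mstep_steps`` gradient steps per epoch.
    depth, hidden
        Decoder architecture (1 = single affine layer, the interpretable
        default).
    estep_form : {"printed", "expected_energy"}
        Which local update to use (see :func:`estep_update`).
    mstep_form : {"expected", "sampled"}
        Exact expected objective versus Monte-Carlo sampling from Q.
    n_init : int
        Number of VBEM restarts with fresh decoder initializations; the
        run with the best final ELBO is kept.  Mean-field VBEM on binary
        codes has signature-collapse local optima, and restarts are the
        standard remedy (compare ``KMeans(n_init=...)``).
    random_state : int or RandomState
        Seeds decoder initialization and any sampling; fits are
        deterministic given it (and the ``expected`` M-step).

    Attributes
    ----------
    posterior_ : (N, 2^B) mean-field posterior Q.
    decoder_ : fitted :class:`Decoder`.
    elbo_trace_ : per-epoch ELBO values (up to the prior log-partition).
    graph_ : the :class:`EvoGraph` used.
    codes_ : the canonical 2^B x B code table.
    """

    def __init__(self, B: int = 5, gamma: float = 1.0, window: int = 5,
                 epochs: int = 10, mstep_steps: int = 20,
                 learning_rate: float = 0.05, depth: int = 1,
                 hidden: int = 16, estep_form: str = "printed",
                 mstep_form: str = "expected", n_init: int = 4,
                 random_state: int = 0):
        self.B = B
        self.gamma = gamma
        self.window = window
        self.epochs = epochs
        self.mstep_steps = mstep_steps
        self.learning_rate = learning_rate
        self.depth = depth
        self.hidden = hidden
        self.estep_form = estep_form
        self.mstep_form = mstep_form
        self.n_init = n_init
        self.random_state = random_state

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y=None, graph: EvoGraph | None = None):
        """Fit to a binary N x F matrix whose rows are in chronological
        order (the default graph couples temporal neighbours)."""
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (songs x features)")
        if not np.isin(X, (0, 1)).all():
            raise ValueError("X must be binary (threshold counts at >= 1)")
        if not 1 <= self.B <= MAX_BITS:
            raise ValueError(f"B must be in 1..{MAX_BITS} for the explicit "
                             "2^B posterior")
        if self.epochs < 1 or self.gamma < 0 or self.n_init < 1:
            raise ValueError("need epochs >= 1, gamma >= 0 and n_init >= 1")
        N, F = X.shape
        rng = check_random_state(self.random_state)
        g = build_window_graph(N, self.window) if graph is None else graph
        if g.n != N:
            raise ValueError("graph size must match number of songs")
        codes = code_table(self.B)
        H = hamming_table(self.B)
        best = None
        for _ in range(self.n_init):
            Q = np.full((N, 2 ** self.B), 1.0 / 2 ** self.B)
            dec = Decoder(self.B, F, self.depth, self.hidden, rng=rng)
            trace = []
            for epoch in range(self.epochs):
                L = loglik_matrix(X, dec, codes)
                for i in range(N):                   # sequential sweep
                    Q[i] = estep_update(i, Q, L, g, self.gamma,
                                        self.estep_form, codes, H)
                dec = mstep(Q, X, dec, self.mstep_steps, self.mstep_form,
                            rng, self.learning_rate, codes)
                val = elbo(Q, X, dec, g, self.gamma, codes)
                if not np.isfinite(val):
                    raise FloatingPointError(
                        f"non-finite ELBO at epoch {epoch + 1}")
                trace.append(val)
            if best is None or trace[-1] > best[2][-1]:
                best = (Q, dec, trace)
        self.posterior_, self.decoder_, trace = best
        self.graph_ = g
        self.elbo_trace_ = np.array(trace)
        self.codes_ = codes
        self.n_features_in_ = F
        return self

    # -- inference ----------------------------------------------------------

    def map_train_codes(self) -> np.ndarray:
        """Per-song argmax of the posterior Q (ties -> lowest code index);
        returns an N x B binary matrix."""
        idx = np.argmax(self.posterior_, axis=1)
        return self.codes_[idx].astype(int)

    def code_prior_(self) -> np.ndarray:
        """Marginal distribution of codes across training songs,
        P(beta) = (1/N) sum_i Q_i(beta)."""
        return self.posterior_.mean(axis=0)

    def transform(self, X) -> np.ndarray:
        """MAP codes for held-out songs, scored independently as
        P_gen(x | beta) * P(beta) with the training marginal as prior."""
        X = np.asarray(X)
        L = loglik_matrix(X, self.decoder_, self.codes_)
        prior = self.code_prior_()
        with np.errstate(divide="ignore"):
            logprior = np.where(prior > 0, np.log(np.clip(prior, 1e-300, None)),
                                -np.inf)
        scores = L + logprior[None, :]
        out = np.empty((X.shape[0], self.B), dtype=int)
        for j in range(X.shape[0]):
            row = scores[j]
            if not np.isfinite(row).any():
                logger.warning("test song %d: prior has zero mass on every "
                               "code; falling back to likelihood argmax", j)
                row = L[j]
            out[j] = self.codes_[int(np.argmax(row))]
        return out

    def signature_report(self) -> SignatureReport:
        return signature_report(self.posterior_, self.decoder_)

    def score(self, X, y=None) -> float:
        """Mean per-song MAP log-likelihood of held-out binary rows."""
        Z = self.transform(X)
        return float(np.mean([log_pgen(x, z, self.decoder_)
                              for x, z in zip(np.asarray(X), Z)]))


# ---------------------------------------------------------------------------
# Checkpointing (JSON; schema is versioned)
# ---------------------------------------------------------------------------

CHECKPOINT_SCHEMA = 1


def save_checkpoint(model: EvolutionarySignatureModel, path,
                    extra: dict | None = None) -> None:
    """Write config, decoder layers, posterior and ELBO trace to one JSON
    file."""
    import json
    payload = {
        "schema": CHECKPOINT_SCHEMA,
        "config": model.get_params(),
        "decoder": {
            "B": model.decoder_.B, "F": model.decoder_.F,
            "depth": model.decoder_.depth, "hidden": model.decoder_.hidden,
            "weights": [w.tolist() for w in model.decoder_.weights],
            "biases": [b.tolist() for b in model.decoder_.biases],
        },
        "posterior": model.posterior_.tolist(),
        "graph_window": model.graph_.window,
        "elbo_trace": model.elbo_trace_.tolist(),
        "extra": extra or {},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_checkpoint(path) -> EvolutionarySignatureModel:
    import json
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("schema") != CHECKPOINT_SCHEMA:
        raise ValueError(f"unsupported checkpoint schema {payload.get('schema')}")
    model = EvolutionarySignatureModel(**payload["config"])
    d = payload["decoder"]
    dec = Decoder(d["B"], d["F"], d["depth"], d["hidden"], rng=0)
    dec.weights = [np.array(w) for w in d["weights"]]
    dec.biases = [np.array(b) for b in d["biases"]]
    model.decoder_ = dec
    model.posterior_ = np.array(payload["posterior"])
    model.elbo_trace_ = np.array(payload["elbo_trace"])
    model.codes_ = code_table(d["B"])
    model.n_features_in_ = d["F"]
    N = model.posterior_.shape[0]
    w = payload.get("graph_window")
    model.graph_ = build_window_graph(N, w if w is not None else model.window)
    return model
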