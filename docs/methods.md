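# Methods

## Model

Each song `n` in a date-ordered corpus carries a binary latent code
`Z_n ∈ {0,1}^B`; bit `b` is read as the on/off state of evolutionary
signature `b` in that song. A decoder network maps a code to per-feature
Bernoulli probabilities for the binarized feature matrix `X ∈ {0,1}^{N×F}`
(a feature is 1 when the corresponding chord/formal k-mer filter fires at
least once in the song). The joint density is

    P(X, Z) = ∏ᵢ P_gen(Xᵢ | NN(Zᵢ; θ)) · P(Z),
    P(Z) ∝ exp(−E(Z)),  E(Z) = Σ_{i,j<i} G(i,j) γ Σ_b [Zᵢ(b) ≠ Zⱼ(b)].

`G` is any symmetric non-negative closeness matrix; the package builds a
temporal-window graph `G(i,j) = [0 < |i−j| ≤ w]` on chronological ranks.
The energy is the graph-weighted Hamming disagreement between codes, i.e.
the log-probability cost of a point-wise mutation (bit flip) between
related songs. The prior's global normalizer is intractable and never
needed: it is constant in both `Q` and `θ`, so the reported ELBO is exact
*up to that additive constant*. This is stated here once and applies to
every ELBO value the package prints.

### Variational fitting

The posterior is mean-field by song, each factor an explicit distribution
over all `2^B` codes (`B ≤ 7`, the cap that keeps exact enumeration
cheap). One VBEM epoch is: a sequential E-step sweep over songs in
chronological order, then an M-step of `mstep_steps` gradient steps on
`θ`. Two E-step update rules are provided:

- `printed` (default): `q_{i,β} ∝ P_gen(Xᵢ|β) · exp(Σ_{j∈nbr(i)} Σ_β'
  q_{j,β'} exp(−E_{ij}(β,β')))` — the exponentiated-energy form, with the
  neighbour sum restricted to the graph neighbourhood of `i`.
- `expected_energy`: the textbook coordinate-ascent mean-field update
  `q_{i,β} ∝ P_gen(Xᵢ|β) · exp(−Σ_{j∈nbr(i)} G(i,j) γ E_{q_j}[H(β, Z_j)])`,
  computed from neighbour bit marginals.

Only `expected_energy` carries the coordinate-ascent guarantee, so the
monotone-ELBO tests use it; the two agree exactly at γ = 0. The M-step
default ascends the exact expected objective `Σᵢ Σ_β q_{i,β} log
P_gen(Xᵢ|β)` (tractable because the posterior is explicit); a `sampled`
Monte-Carlo variant (one code drawn per song per step from `Q`) is also
available. Decoder probabilities are clipped to `[1e−6, 1−1e−6]` inside
likelihoods so log terms stay finite.

### Numerical and optimizer choices

- **Optimizer**: Adam-style update, fixed learning rate 0.05, 20 steps
  per M-step. Under the expected objective the parameters with the best
  objective seen across the steps are kept, so an M-step never decreases
  the objective regardless of step-size luck.
- **Initialization**: `Q` uniform; decoder weights i.i.d. normal with
  scale 0.1, biases zero.
- **Restarts**: mean-field VBEM on binary codes has signature-collapse
  local optima (two bits locking onto one factor). `n_init` (default 4)
  independent restarts are run and the fit with the best final ELBO kept,
  the same remedy `KMeans` uses. Fits are deterministic given
  `random_state`.
- **Tie-breaks**: code enumeration order is binary counting with bit 0
  fastest; every argmax (MAP codes, kernel-CV selection) resolves ties to
  the lowest index, so results are order-deterministic.
- **Degenerate inputs**: a test-time code prior with zero mass everywhere
  triggers a fall-back to the likelihood argmax with a warning; a
  never-active signature keeps activation 0 rather than dividing by a
  zero normalizer.

### Signature views

Activations `ω_{t,b}` are the posterior bit marginals divided by their
per-signature mean over songs (so each signature's activation averages 1
across the timeline). The per-signature feature-weight view returns the
one-layer decoder weight matrix `W` (for deeper decoders, the first-layer
weights with a logged caveat); under the optional positive
parametrization `θ = exp(W)` this is literally the log-weight matrix.

## Features

Basic harmonic filters of length `K` template the `K−1` successive root
intervals (mod 12) and `K` major/minor quality bits; there are
`12^(K−1)·2^K` of them and every `K`-window matches exactly one, so
responses over the full enumeration sum to `l(n)−K+1`. Tau-normalized
filters template the `K` root offsets from the tonic plus a key bit that
must equal the song's mode (`12^K·2^(K+1)` filters), making responses
transposition-invariant. Formal filters are plain k-mers over section
labels. Filters supported by fewer than `min_support` songs of the
*fitting* corpus are pruned and the retained list frozen for held-out
data; the default 100 suits corpora of several hundred songs and must be
scaled down for toy data (the CLI therefore requires it explicitly).

Chords are reduced to root pitch-class (flat-name convention Ab = 0) and
major/minor quality; 7ths, 9ths, inversions and similar extensions are
collapsed by a configurable policy table, and chords outside it
(diminished, augmented, power chords, bare roots) are dropped with a
warning — this preserves the 24-chord state space while keeping the
parser total. The mod-24 indexing (`single = root + 12·quality`,
`pair = 24·first + second`) is a repository convention; any fixed
bijection would do. The "indexed residual" SVD uses
correspondence-analysis standardized residuals `(O−E)/√E` under row/column
independence (raw-count SVD behind a flag), because that view of a count
matrix is the standard correspondence-analysis decomposition.

Formal-category coarse-graining offers identity, a user-supplied manual
projection, and `tail_to_other`, which merges the M rarest categories
into an `other` label with M the largest count whose combined share of
observed labels stays ≤ 0.01 (frequency ties broken alphabetically).

## Prediction

Training song `i` (chronological order) gets label `y_i = i/N ∈ (0,1]`.
Held-out songs get MAP codes scored as likelihood × training-marginal
prior by explicit enumeration; predictions are Nadaraya–Watson kernel
regressions with kernel `exp(−α·H)`, hence always convex combinations of
training labels. Genre prediction runs the same kernel per genre on 0/1
labels; genres with fewer than `min_genre_count` (default 10) training
positives, or no test positive, are excluded since Pearson r is undefined
for zero-variance truths; threshold-0.5 accuracy is reported as a
secondary metric. Hyper-parameters are cross-validated on period r over
γ ∈ {0.1, 1, 10}, w ∈ {1, 2, 5} and α ∈ {0.25, 0.5, 1, 2, 4} (the α grid
and 5 chronological-stride folds are package choices), refitting per
combination on fold-train portions.

The permutation trend test compares a decrease-type statistic of the
activation trajectories — by default the late/early temporal-quartile
variance ratio, alternatively the OLS slope of windowed variance — with
the same statistic from models refitted on randomly permuted song
orderings; `p = (1 + #{null ≤ observed})/(1 + n_perm)`. The stability
analysis refits with fresh seeds/subsamples and matches signatures across
runs by Hungarian assignment on absolute trajectory correlations. Both
statistics are package stand-ins for an unpublished choice; they are
documented alternatives, not canonical.

## Synthetic generator

The generator realizes the mutational process the prior is motivated by:
row 0 of the code matrix is i.i.d. Bernoulli(0.5) and each subsequent row
flips each bit independently with probability `flip_rate` — exactly the
point-wise process, *not* a sample from the energy prior itself (whose
normalizer is intractable; an exact Gibbs sampler is included for
small-N prior checks). The ground-truth decoder is one layer with weights
i.i.d. from {−s, 0, +s} (probability 1/3 each) and biases set so every
feature's marginal frequency is exactly 0.5 under uniform codes. Chord
realizations concatenate k-mers from disjoint per-bit motif pools plus a
background pool, fixed C-major tonality, dates in code order, and genre
labels attached per active bit.

Default study conditions used by the tests and the acceptance script:

- recovery: N = 400, B = 3, F = 80, flip_rate = 0.05, strength = 2,
  fitted at γ = 1, w = 5, 10 epochs, 20 M-steps — mean recovery ≥ 0.85
  and at least matching the γ = 0 ablation in most seeds;
- period prediction: slow-drift families (flip_rate ≈ 1–3 expected flips
  per bit over the corpus) — at flip_rate = 0.05 and N = 400 the
  2^B-state chain mixes within ~10 songs, so absolute rank is
  information-theoretically unrecoverable from a code and no predictor
  could score well; rank recovery requires codes that segment the
  timeline, which is what slow drift produces;
- trend-test calibration: 60 replicates of non-evolving (flip_rate = 0.5,
  i.e. i.i.d.) corpora at N = 60, B = 2, F = 24 with 3-epoch fits and
  n_perm = 19, sized so the full null distribution of refits is
  recomputed hundreds of times within a normal test run.

What passing these experiments does **not** show: the generator's
features are conditionally independent given the code and its decoder
matches the fitted architecture, so recovery here is a best case; real
song corpora have correlated features, non-stationary genre composition,
dating error, and influence structure far richer than a temporal window.
Synthetic results validate the machinery, not the musicology.

## Known limitations

- `B ≤ 7` by construction (explicit `2^B` posterior); a posterior
  factorized over bits would lift this but is not implemented.
- The graph `G` is fixed, never learned; tree/DAG-structured priors and
  fitness terms are out of scope.
- The ELBO is comparable only across runs with the same `γ` and graph
  (the omitted prior log-partition depends on both).
- The `printed` E-step form has no ascent guarantee; use
  `expected_energy` when monotone ELBO diagnostics matter.
- Key estimation is not provided: tonality must accompany each song.
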