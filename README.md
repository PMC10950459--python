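# evosig — latent evolutionary signatures for symbolic song corpora

`evosig` models the evolution of musical style in a dated corpus of songs
the way mutational-signature methods model evolutionary processes in
genomes. Each song is reduced to a vector of **chord k-mer features**
(counts of harmonic "motifs", optionally normalized to the song's tonality
so they are key-invariant, plus k-mers over formal section labels such as
verse/chorus). A **binary latent code** `Z_n ∈ {0,1}^B` is then fitted to
each song — one bit per *evolutionary signature* — together with a decoder
network `NN(Z; θ)` that maps codes to Bernoulli probabilities for the
binarized features:

```
P(X, Z) = P(X | Z) P(Z),      P(X | Z) = ∏ᵢ P_gen(Xᵢ | NN(Zᵢ; θ))
P(Z) ∝ exp(−E(Z)),            E(Z) = Σ_{i, j<i} G(i,j) · γ · H(Zᵢ, Zⱼ)
```

where `H` is the Hamming distance and `G` is a symmetric "closeness"
graph over songs — by default a temporal window on chronological ranks,
`G(i,j) = [0 < |i−j| ≤ w]`. The energy prior plays the role of a
point-wise mutational process: codes of temporally adjacent songs are
penalized for disagreeing, so signatures must evolve smoothly.

Fitting is **variational Bayes EM** with a mean-field posterior that is
explicit over all `2^B` codes per song (`B ≤ 7`), alternating sequential
per-song E-step updates with gradient M-steps on `θ`, monitored by the
ELBO. Learned codes are evaluated by **MAP inference** for held-out songs
(training-marginal prior) and **Hamming-kernel regression**
`ŷ = Σᵢ exp(−α·H(z, Zᵢ*)) yᵢ / W` for period (chronological-rank) and
genre prediction, scored by Pearson correlation.

The package is aimed at computational musicology and cultural-evolution
research, but nothing in the model is music-specific: any corpus of dated
entities with sparse count features fits the same mold. A fully seeded
synthetic generator (drifting codes → decoder → features → chord
sequences) provides ground truth, so every stage is testable without any
data download.

## Worked example

```python
from evosig import (EvolutionarySignatureModel, HammingKernelRegressor,
                    chronological_split, build_feature_matrix,
                    enumerate_tau_filters, evaluate_period, period_labels,
                    simulate_codes, simulate_chord_corpus)
from evosig.features import response_matrix

codes = simulate_codes(N=300, B=3, flip_rate=0.01, seed=11)   # ground truth
corpus = simulate_chord_corpus(codes, length=40, seed=12)
train, test = chronological_split(corpus, stride=5)           # every 5th held out

fm = build_feature_matrix(train, enumerate_tau_filters(1), min_support=10)
model = EvolutionarySignatureModel(B=3, gamma=1.0, window=5,
                                   epochs=10, random_state=0).fit(fm.binary)

Z_tr = model.map_train_codes()
Z_te = model.transform((response_matrix(test, fm.filters) >= 1).astype(int))
pred = HammingKernelRegressor(alpha=1.0) \
    .fit(Z_tr, period_labels(len(train))).predict(Z_te)
print(evaluate_period(pred, period_labels(len(test))))
```

With progress printing added around each stage, an actual run reports:

```
corpus: 300 songs -> train 240, test 60
features: 15 of 48 tau K=1 filters retained
final ELBO: -689.1
signature recovery vs ground truth: 0.963
period prediction Pearson r: 0.708
```

Reading: of the 48 tonality-normalized single-chord filters, 15 occur in
at least 10 training songs; the fitted posterior recovers 96% of the true
signature bits (up to label permutation and polarity); and the MAP codes
of the held-out songs predict their chronological rank with r ≈ 0.71 —
far above chance because the codes drift slowly in time, which is exactly
the structure the energy prior encodes.

The same pipeline is available from the shell:

```bash
evosig simulate --n-songs 300 --bits 3 --flip-rate 0.01 --seed 11 --out sim/
evosig features --corpus sim/corpus.csv --kinds tau --k 1 \
    --min-support 10 --stride 5 --out feat/
evosig train --features feat/train_counts.csv --filters feat/train_filters.csv --out run/
evosig evaluate --checkpoint run/checkpoint.json \
    --test-features feat/test_counts.csv --test-filters feat/test_filters.csv \
    --tasks period --out eval/
```

Every command writes a JSON manifest (config, seeds, input digests) so
runs are exactly reproducible.

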