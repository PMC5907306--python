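# ddinmf

Prediction of drug-drug interactions (DDIs) for *new* drugs — drugs with no
known interactions — from their feature vectors, via matrix factorization of
the known-interaction network, together with structural analysis of the
signed DDI network.

Two prediction settings are supported:

- **binary** (conventional): does a pair interact at all?  The binarized
  adjacency is factorized with nonnegative matrix factorization (NMF).
- **comprehensive** (signed): is the interaction *enhancive* (+1) or
  *degressive* (-1)?  The signed adjacency is factorized with **semi-NMF**
  (mixed-sign basis `W`, nonnegative encoding `H`).

Training decomposes the adjacency `A ≈ W H` and fits a SIMPLS partial
least squares regression `Hᵀ = F B` from the drug feature matrix to the
encoding.  Prediction maps a new drug's features through `B` into the
latent space and scores its pairs with the known drugs as `A_x = (W H_x)ᵀ`.
Features can optionally be reduced with Gaussian-kernel kernel PCA (with
PCA-based dimension estimation and out-of-sample projection for new drugs).

The analysis half provides signed degree profiles, the four-pattern signed
triangle census with balanced / unbalanced / weakly-balanced classification,
and kernel-PCA embeddings of the factor matrices with degree rank
correlations.

A synthetic-data module generates signed networks with planted communities,
node-polarity-derived edge signs (exactly structurally balanced at zero
noise), and community-coupled binary features, so the full pipeline is
testable offline.

## CLI

```bash
# generate a synthetic benchmark
ddinmf simulate --preset default --seed 1 --out data/

# fit a model (mode: binary | comprehensive; --r auto = rank(A)/2)
ddinmf train --edges data/edges.tsv --features data/features.csv \
    --mode comprehensive --r auto --k 40 --out model/

# score new drugs against the known drugs
ddinmf predict --model model/ --features new_drugs.csv --out scores.csv

# cold-start K-fold cross-validation (new-drug protocol)
ddinmf cv --edges data/edges.tsv --features data/features.csv \
    --mode both --k-folds 10 --repeats 5 --seed 7 --out results.json

# signed-network structural analysis
ddinmf analyze --edges data/edges.tsv --out analysis/
```

Input formats: edge lists are TSV with header `drug_a  drug_b  sign`
(sign `+1`/`-1`, or `E`/`D`); feature tables are CSV/TSV with a `drug_id`
first column and numeric feature columns.

## Python API

```python
import ddinmf

A, F, truth = ddinmf.generate_benchmark("default", seed=1)
model = ddinmf.train(A, F, mode="comprehensive", r=8, k=10, seed=0)
scores = ddinmf.predict_new(model, new_features)   # new x known score matrix

res = ddinmf.run_cv(A, F, {"mode": "binary", "K": 10, "r": 8, "k": 10, "seed": 0})
census = ddinmf.triangle_census(A)
print(res.auroc, ddinmf.balance_fraction(census))
```

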