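# unidims

Quantifying the **universal dimensions** of visual representations: which
latent dimensions of a neural network's activations are (a) learned by *every*
network regardless of initialization, architecture, or task, and (b) shared
with brain responses to the same stimuli?

`unidims` implements the full analysis as a tested pipeline over dense
activation matrices, together with a latent-factor simulator that generates
worlds with known ground truth so every step can be validated end to end.  It
is aimed at researchers in computational neuroscience / NeuroAI who want to
run or probe this style of cross-system representational analysis without the
terabyte-scale inputs (pretrained model zoos, large fMRI datasets) the
original studies require.

## The two metrics

Every analyzed dimension *d* is one principal component of one network
layer's globally max-pooled activations: the PC basis is fit on a large
*fit* stimulus set and a smaller shared *evaluation* set is projected into
it.  For each dimension:

- **Universality** — predict the dimension's evaluation-set series from the
  concatenated pooled layers of each *other* network with nested
  cross-validated ridge regression (outer 5-fold; inner leave-one-out
  selection of the penalty λ ∈ {0} ∪ {10⁻³ … 10⁴}); score each predictor
  network by the mean held-out Pearson *r* across folds, and summarize as

  Universality(d) = median(r₍d,1₎, …, r₍d,m₎)

- **Brain similarity** — the same cross-validated prediction, with each
  subject's (stimuli × voxels) response matrix as the predictor:

  BrainSimilarity(d) = mean(r₍d,1₎, …, r₍d,n₎)

Downstream inference asks how the two metrics covary across all dimensions:
Spearman's ρ, a partial Spearman controlling for PC rank, a one-sided
stimulus-label permutation test (one shared permutation per target network,
so within-network dependence is preserved), quantile-of-100 summaries, a
between-subject reliability adjustment, and a representational similarity
analysis (RSA) that reconstructs each network from only its top-10/5 most
universal dimensions.

## Worked example

The numbered drivers under `analysis/` run the whole study on the default
simulated world (6 networks × 3 layers × 60 channels mixing 3 universal and 6
idiosyncratic latents; 600 fit / 200 evaluation stimuli; 4 subjects whose
voxels mix the universal latents):

```bash
python analysis/01_simulate_world.py      # world.h5: activations + brain data
python analysis/02_extract_dimensions.py  # pcs.h5: PC bases + projections
python analysis/03_score_dimensions.py    # scores.csv: both metrics per dim
python analysis/04_inference.py           # inference.json + summary.json
python analysis/05_rsa.py                 # rsa.json
python analysis/06_null_control.py        # null_control.json
```

Driver 04 prints, for this configuration:

```
Spearman(universality, brain similarity) = +0.578 over 1080 dimensions
partial Spearman given PC rank          = +0.568
permutation test: p = 0.0050 (199 label permutations)
```

Most of the 1,080 dimensions are idiosyncratic (median universality +0.01),
but the planted universal dimensions are recovered almost perfectly
(universality up to 0.999) and are exactly the ones the simulated brain
predicts — the positive ρ with the smallest attainable p at 199 permutations
(1/200 = 0.005).  Driver 05 shows the RSA counterpart: reducing each network
to its top-5 most universal dimensions leaves test-set representational
similarity unchanged or slightly improved:

```
network  layer    full    top-10  top-5
net0     layer0   +0.968  +0.982  +0.981
...
largest decrease from keeping only 5 universal dimensions: -0.010
```

Driver 06 is the negative control: with brain latents sampled independently
of every network latent, universality still spans its full range while the
coupling drops to the null scale.

The same machinery accepts real data: any HDF5 container with one group per
network, one (stimuli × channels[, spatial]) dataset per layer, and one
matrix per subject can be fed through the identical scoring path (see
`unidims.io`).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the complete pipeline from scratch — simulation, pooling, PCA,
both metrics for all dimensions, permutation inference, and reduced RSA —
with all randomness derived from `--seed`, prints the headline statistics,
and writes the target JSON to `--out`.  Intermediate artifacts go to
`scratch/acceptance_seed<seed>/`.

## Layout

- `src/unidims/` — the library: `world` (simulator), `activations`
  (pooling/PCA), `mapping` (nested-CV ridge, OLS, one-to-one),
  `metrics` (universality, brain similarity, reliability), `inference`
  (Spearman, partial, permutation), `rsa`, `pipeline` (orchestration,
  persistence, resumable stages), `io` (HDF5/YAML).
- `analysis/` — numbered narrative drivers (above).
- `docs/methods.md` — model, estimation choices, and known limitations.
- `tests/` — unit, property, and acceptance tests.
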