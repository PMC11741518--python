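# kinegraph

Temporal causal discovery from live-cell time-lapse imaging features.

Live-cell microscopy produces long multivariate time series of cellular
morphodynamics — shape, motility, division/apoptosis state, and cell–cell
interactions — under controlled experimental conditions. `kinegraph` turns
such recordings into *temporal causal networks*: which features drive
which, at which time delays, which associations stem from unobserved
common causes, and how experimental conditions (drug treatment,
co-cultured cell types) act on the system. It is aimed at quantitative
cell biologists and methodologists working with tumor-on-chip or similar
time-lapse assays, and at anyone with mixed-type multivariate time series
who wants lag-resolved causal structure rather than correlation networks.

The package has two independent halves:

* **Feature extraction** (`kinegraph.tracking`, `kinegraph.features`):
  circular-Hough detection of disk-like cells in two size classes,
  Hungarian-algorithm tracking with gated inverse-distance costs,
  active-contour segmentation of the main cancer cell, and 15 per-frame
  descriptors (shape, motility, state, interaction).
* **Causal discovery** (`kinegraph.discovery`, `kinegraph.information`):
  learns a *time-unfolded* graph G_t in which each variable appears at
  lags 0, δτ, …, τ. Under stationarity the structure is translation
  invariant, so only edges touching the contemporaneous layer are learned
  and then duplicated at earlier layers. Edge decisions use penalized
  mutual information for finite samples: an edge survives iff

      n · I(x; y | Z) − k(partition, Z) > 0,

  where I is estimated by adaptive rank discretization and k is a
  model-selection complexity. Lagged edges are pre-oriented toward the
  future; contemporaneous edges and latent-cause (bidirected) edges are
  oriented through signed three-point information I(x;y;z|U) — negative
  values mark colliders. Transfer entropy
  T[X→Y] = I(Y_t ; X_past | Y_past) is available as a statistic, and the
  engine reproduces the textbook relation between its vanishing and
  temporal v-structures (including the counterexample where a lagged
  feedback edge makes the converse fail).

Ground-truthed synthetic generators (15-node linear and nonlinear
autoregressive networks, didactic two-variable models, latent-confounder
models, microscopy-like videos) plus a precision/recall/F scorer close the
loop for validation.

## Worked example

```python
import numpy as np
from kinegraph import TemporalCausalModel
from kinegraph.benchmarks import generate_pair_model

# X drives Y contemporaneously; X is autonomous AR(1)
network, dataset = generate_pair_model("a", T=10_000, seed=3)

model = TemporalCausalModel(dataset, tau=2, delta_tau=1)
result = model.fit()
print(result.summary())
```

```
Temporal causal discovery results
=================================================
variables:    2    samples:    10000
tau: 2 ts    delta_tau: 1 ts    layers: 2
summary edges: 3
-------------------------------------------------
source        target         lag orient     sign  conf
X             X                1 directed   +     1.00
X             Y                0 directed   +     1.00
Y             Y                1 directed   +     1.00
```

The engine recovers exactly the generating structure: each variable's
autoregressive memory as a directed lag-1 self-loop, and the
contemporaneous X→Y effect oriented by the temporal v-structure
Y_{t−1}→Y_t←X_t (confidence 1.00; signs are the association signs of the
endpoint columns). The reverse transfer entropy is correctly judged
insignificant:

```python
from kinegraph import transfer_entropy
te = transfer_entropy(dataset, "Y", "X", max_lag=2)
print(te.significant_info)   # 0.0  (nats; shrunk to zero by the penalty)
```

For imaging data, the same model can be fitted straight from an extracted
feature table:

```python
from kinegraph.benchmarks import render_synthetic_video
from kinegraph.features import extract_feature_table

stack, truth = render_synthetic_video(n_immune=6, n_frames=30, seed=4)
features = extract_feature_table(stack, truth.events)  # 15 descriptors/frame
```

A command-line interface mirrors the library:
`kinegraph discover|extract|pipeline|bench|score --help`.

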