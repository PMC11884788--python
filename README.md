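# teflow

Transfer-entropy information-flow analysis for paired single-cell
signaling time courses — with a Langevin reaction-cascade simulator for
generating synthetic paired trajectories.

## The problem

Live-cell imaging can record the membrane-translocation responses of two
signaling proteins (for example SOS and RAF in the EGFR–RAS–MAPK
system) *simultaneously in the same cells*, minute by minute, across
hundreds of cells per stimulus condition.  Transfer entropy (TE)
quantifies the direction, timing and strength of the information flow
between the two reaction time courses without assuming any kinetic
model: it asks how much better the result channel's value at time *t*
can be predicted when, in addition to the result channel's own value at
a reference time *T*r, the cause channel's value at a causal time *T*c
is known.  Significant forward TE (cause → result) reflects the
upstream reaction's control capability over the downstream one;
significant backward TE indicates feedback loops or shared hidden
inputs.

## The estimator

For jointly Gaussian responses, TE has a closed form in covariances.
With X the result channel, Y the cause channel, and `Tc = Tr < t`:

    TE_{Y→X}(t) = I(X_t ; X_Tr, Y_Tc) − I(X_t ; X_Tr)
                = ½ ln [ Σ(X_t | X_Tr) / Σ(X_t | X_Tr ⊕ Y_Tc) ]   (nats)

where each conditional variance is a Schur complement of the sample
covariance matrix, e.g. `Σ(X_t|X_Tr) = Σ(X_t) − Σ(X_t,X_Tr) Σ(X_Tr)⁻¹
Σ(X_t,X_Tr)ᵀ`.  Statistical machinery around the estimator:

- **Significance**: the cause-channel cell assignment is permuted 1000
  times (destroying every element of the cause–result cross-covariance
  while preserving both marginals); the upper 1% point of the null TE
  distribution is the threshold.
- **TEsum**: the sum of significant TE over a named peak window of the
  TE time course, reported as the mean and 5–95% range of 100 bootstrap
  replicates (cells resampled with replacement, resample size = sample
  size, threshold recomputed per replicate).
- **Conditional TEsum** vs stimulus dose: per-dose TEsums averaged per
  bootstrap replicate.  Conditional > pooled TEsum indicates a bypass
  information route through the stimulus receptor that skips the cause
  channel; pooled ≥ conditional is expected for a tandem cascade.
- **Condition comparisons**: per-replicate TEsum differences between two
  datasets/modes, significant when the 5–95% interval excludes zero.

The simulator integrates saturating Langevin rate equations (input →
cause species S → result species R, with optional feedback, bypass and
common-input couplings) with classical RK4 drift plus Gaussian noise
increments, lognormal cell-to-cell parameter variability, and 1-minute
sampling with 3 pre-stimulation frames — matching the structure of the
experimental trajectory tables.

## Worked example

```python
from teflow import (TransferEntropyModel, PeakWindow, build_network,
                    SimProtocol, simulate, concat_datasets)

# paired trajectories from a cascade with a negative feedback loop,
# four EGF doses x 300 cells, 1-min grid
net = build_network("feedback")
proto = SimProtocol(doses=(0.1, 1.0, 10.0, 100.0), n_cells=300, duration=40)
pooled = concat_datasets(simulate(net, proto, seed=10))

model = TransferEntropyModel(pooled, tc_values=[2, 5, 10], t_max=30)
res = model.fit(seed=0)
print(res.summary())

early_bw = PeakWindow("early_bw", "bw", 5, 6, 15)
est = res.bootstrap_tesum(early_bw, seed=1)
print(f"early bw TEsum: {est.mean:.3f} nats (5-95% {est.lo:.3f}-{est.hi:.3f}, n={est.n})")
```

prints

```
Transfer entropy results
================================================================
cells: 1200    null resamples: 1000    threshold percentile: 99
directions: fw, bw    Tc values: 3    t range: <= 30 min
----------------------------------------------------------------
direction  n queries  n signif  max TE (nats)    argmax (Tc,t)
       fw         73        73         0.2011           (5,29)
       bw         73        49         0.0266          (10,17)
================================================================
early bw TEsum: 0.120 nats (5-95% 0.068-0.185, n=1200)
```

All 73 forward queries are significant (the cascade transmits
information downstream at every causal time), and 49 backward queries
are significant too — the signature of the feedback loop: knowing the
result channel at Tc improves prediction of the cause channel beyond
its own history.  The early backward TEsum of 0.120 nats, with a 5–95%
bootstrap range well above zero, quantifies that reverse control
capability.  On the `tandem` preset (no feedback) the backward course
shows no block of significant values.

`res.table` holds the tidy `(direction, tc, t, te, threshold,
significant, n)` DataFrame; `res.plot_timecourse("bw")` plots the
significant-only TE time courses.

## Command line

The same pipeline is scriptable from a single YAML config:

```sh
teflow simulate -c config.yaml     # write per-dose trajectory CSVs + manifest
teflow te -c config.yaml           # TE time courses with significance
teflow tesum -c config.yaml        # bootstrap TEsum per peak window
teflow conditional -c config.yaml  # dose-conditional TEsum
teflow compare -c config.yaml      # TEsum difference between two modes/datasets
```

Trajectory CSVs have a `cell_id` column followed by one column per
minute relative to stimulation (`-3,-2,-1,0,1,...`); a YAML manifest
maps file pairs to condition metadata (EGF dose, genotype, inhibitor).
Every run writes a JSON manifest with the config hash and seed;
identical config + seed reruns are byte-identical.

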