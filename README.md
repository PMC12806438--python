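# delayformer

Multi-step forecasting of **all** variables of a high-dimensional dynamical
system from limited, noisy observations — by treating each channel's
delay-embedded window as an image.

Delay-embedding theory (Takens; Sauer's fractal generalization) says that
the vector of `L` consecutive lagged values of a *single* generic observable,
`Y_k^t = (x_k^t, …, x_k^{t+L-1})`, reconstructs the full system state
whenever `L > 2d` (`d` = attractor box-counting dimension). Each channel of
a multivariate series therefore individually encodes the whole system, and
forecasting becomes learning the map `Ψ_k` from one channel's known delay
vectors to the future values of every channel.

The model solves all `Ψ_k = f_k ∘ E` at once:

* each channel's length-`W` input window is delay-embedded into an
  `L × (W−L+1)` **Hankel matrix** (`Y[i,j] = w[i+j]`, constant
  anti-diagonals) and sliced into `p2 × p1` patches, flattened into tokens;
* one **shared transformer encoder** `E` (patch projection + sinusoidal
  positions + post-norm blocks `U = LN(H + MSA(H))`, `H' = LN(U + FF(U))`)
  processes every channel's token sequence with identical weights,
  cross-learning the common dynamics (channel independence);
* a per-channel affine head `f_k` maps the flattened representation `Z_k`
  to channel `k`'s `H`-step forecast; a shared-head variant makes the model
  dataset- and channel-count-agnostic for pretraining, zero-shot transfer,
  and few-shot fine-tuning.

Training minimizes the channel-independent MSE (errors pooled over batch,
horizon, channels) with Adam. The package also ships the benchmark it is
validated on — a chain of ten coupled 3-D Lorenz subsystems (σ=10, ρ=28,
β=8/3, coupling γ·z_{i−1}, γ=0.1; RK4, dt=0.01) with additive-noise and
time-varying-σ regimes — plus the evaluation protocols: chronological
splits, z-score normalization from training statistics, multi-seed
aggregation, noise sweeps, training-size/observed-dimension ablations, and
a persistence baseline. Everything runs on NumPy; the network's forward and
backward passes are implemented in-package and verified against finite
differences.

For whom: researchers in nonlinear dynamics / systems biology who want an
STI-style state forecaster with a modern encoder, and forecasting
practitioners who want a delay-embedding front end for standard
benchmark-format CSVs.

## Worked example

`python examples/train_forecaster.py` — simulate a 6-variable coupled-Lorenz
series, z-score, train a small model, compare against persistence:

```
windows: 477 train / 77 val / 253 test
epoch 0: train loss 0.6862  val MSE 0.2124
epoch 1: train loss 0.2656  val MSE 0.0701
epoch 2: train loss 0.1740  val MSE 0.0883
epoch 3: train loss 0.1284  val MSE 0.0979
epoch 4: train loss 0.0940  val MSE 0.0346
test  MSE 0.1732  MAE 0.3206   (normalized scale)
naive MSE 0.4618  MAE 0.5262  (persistence baseline)
```

The model's 16-step-ahead error is ~2.7× below the repeat-last-value
baseline on the held-out segment: it has learned the oscillatory dynamics,
not just the signal level. The other examples each demonstrate one
capability: `simulate_lorenz.py` (the benchmark generator and its regimes),
`hankel_patching.py` (the embedding algebra and its exact inverses),
`foundation_model.py` (pretrain on three coupling strengths, zero-shot on a
fourth, fine-tune on 5% of its windows).

A thin CLI wraps the same functions:

```bash
delayformer simulate --subsystems 10 --samples 5000 --time-varying --out runs/sim --csv
delayformer train --data runs/sim/series.csv --out runs/model --epochs 3 --stride 3
delayformer predict --checkpoint runs/model/checkpoint \
    --norm runs/model/normalization.json --data runs/sim/series.csv --out forecast.csv
```

Custom datasets drop in as benchmark-dialect CSV (leading `date` column,
one numeric column per channel). Missing values are an error, not an
imputation.

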