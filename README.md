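# tkebgc

Multimodal imitation-learned grip control for myoelectric prosthetic hands,
with a synthetic grasp-dynamics environment, baseline controllers, a gesture
classifier, and the evaluation metrics to compare them.

## The problem

Operating a hand tool — hammering, sawing, peeling — with a myoelectric
prosthesis is much harder than discrete grasping: rigid impacts and variable
loads repeatedly knock the tool loose, and a controller must re-stabilize
the grip within tens of milliseconds. Two conventional strategies both
struggle: a **fixed-force (FiF)** controller closes to a calibrated preload
and never adapts, so a hard impact can shake the tool out of the hand; a
**force-follows (FoF)** controller tracks a reference contact force from
delayed sensor readings and therefore lags every disturbance.

This package implements a third strategy: a grip controller cloned from
human demonstrations. The network consumes a history of length *P* = 20
control ticks of three time-aligned modalities — surface EMG envelopes
(*E*, 3 channels, mV), tactile pad forces (*F*, 9 pads, N) and joint angles
(*J*, 5 joints, degrees) — and predicts the joint-angle increment for the
next tick:

```
ΔĴ_{t+1} = MLP( concat( z_t , J_t W_J0 , F_t W_F0 ) )
```

where `z_t` is the last row of a Transformer-style fusion encoding
`Z = Fusion(Q, K, V)`: the physical state (joint + tactile embeddings)
forms the attention **query**, and convolutional + linear features of the
EMG history form the **key** and **value**. The physical state thus
retrieves the user's motor intent from the EMG stream, instead of the EMG
dominating the prediction. Training minimizes the mean squared increment
error `L = (1/N) Σ ‖ΔĴ_n − ΔJ_n‖²` with Adam, and the controller executes
`J_{t+1} = J_t + ΔĴ_{t+1}` under a per-tick step clamp.

Because no public recording of such demonstrations exists, the package
ships a first-class synthetic environment (`tkebgc.synth`): a compliant
9-pad contact model over a joint synergy, Poisson rigid-impact disturbances
with task-specific magnitudes, friction-cone slip and drop dynamics, a
delayed corrective demonstrator, and amplitude-modulated band-limited EMG
synthesis. The same plant serves as the closed-loop testbed for all three
controllers.

## Worked example

```python
from tkebgc.experiment import ExperimentConfig, run_closed_loop, train_from_demos
from tkebgc.model import ModelConfig

cfg = ExperimentConfig(seed=1, episodes=20, model_config=ModelConfig(seed=1, epochs=40))
model, history, held_out = train_from_demos(cfg)   # demos from hammer + saw only
table = run_closed_loop(cfg, model)                # peel/desk are unseen tasks
print(table.groupby(["task", "controller"])[["n_drops", "force_tracking_error"]]
      .mean().round(3))
```

prints (seed 1):

```
                   n_drops  force_tracking_error
task   controller
desk   FiF            0.00                 1.048
       FoF            0.00                 0.019
       TKE-BGC        0.00                 0.070
hammer FiF            2.30                 2.697
       FoF            0.00                 0.404
       TKE-BGC        0.05                 0.290
peel   FiF            0.00                 1.043
       FoF            0.00                 0.024
       TKE-BGC        0.00                 0.074
saw    FiF            0.00                 0.983
       FoF            0.00                 0.095
       TKE-BGC        0.00                 0.130
```

Reading: under hammer-level impacts the learned controller drops the tool
more than an order of magnitude less often than the marginal-preload FiF
baseline (0.05 vs 2.30 drops per episode) and holds the target grip force
with less error than the delay-2 FoF tracker (0.29 N vs 0.40 N); on the gentle tasks
all adaptive controllers keep the tool safe. `force_tracking_error` is the
mean absolute deviation from the 8 N grip target during the hold phase.

The command-line interface exposes the same pipeline:
`tkebgc simulate`, `tkebgc train`, `tkebgc eval-offline`,
`tkebgc eval-closed-loop`, `tkebgc classify-gestures`, `tkebgc dtw`.

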