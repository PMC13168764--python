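# Methods

This note documents the models, the synthetic study design, the numerical
choices, and what the tests do and do not establish.

## Signals and conventions

All controllers operate on a 60 Hz control-tick grid (the data glove's
tactile and bend sensors stream at ≥60 Hz; EMG is native ~2 kHz). A trial
holds three time-aligned matrices: EMG envelopes `[T × 3]` (mV), tactile
pad forces `[T × 9]` (N, saturating at 20 N), joint angles `[T × 5]`
(degrees, flexion convention, limits [0, 90]°). The per-tick EMG feature is
the mean rectified amplitude of the native samples falling in that tick
interval; tactile and joint streams are linearly interpolated onto the tick
grid. Tick indices are 0-based; a training window covers ticks
`[k, k+P)` and its supervised target is `J[k+P] − J[k+P−1]`, the increment
into the tick after the window. Per-tick increments are clamped to ±5°.

Splitting is always at trial level (ratio 6:2:2, largest-remainder
apportionment, seeded permutation), so overlapping windows never leak
between subsets; the gesture-classifier trainer additionally *verifies*
leak-freedom and aborts on violation.

## EMG conditioning

Band-pass: 2nd-order Butterworth, 20–500 Hz. Notch: 50 Hz, Q = 30 (the
quality factor is our choice; only the centre frequency is fixed by the
protocol). Full-wave rectification, then 256 ms windows with a 128 ms step
(512/256 samples at 2 kHz; ms→samples by nearest integer). Filters run
causally with zero initial state by default — the mode an online controller
requires — with an optional zero-phase forward–backward mode for offline
analysis; whether the original protocol was causal is unstated, so both are
provided.

## The controller network

Widths (the original hyperparameter table is not public; these are our
defaults, all configurable): d_E = 32, d_k = 64, d_q = 32, d_a = 64, h = 4
heads, MLP hidden (128, 64), ReLU, dropout 0.1, Adam lr 1e-3 with a ×0.3
step decay at 60% and 85% of the epochs, batch 64. The EMG ConvNet is two
kernel-3 same-padded 1-D convolutions with a stride-1 average pooling, so
the temporal length stays P as the dimension algebra requires. The fusion
step is one block — multihead scaled dot-product attention (physical-state
query, EMG key/value), residual + layer normalization, position-wise
feed-forward, residual + normalization — with the block count a config
knob. Inputs are z-scored per channel with statistics frozen from the
training split (online inference re-uses the frozen statistics; whether to
re-normalize per window was an open choice and frozen statistics are the
conservative one). Model archives store the named weight arrays, the
config, and the normalization statistics; loading re-validates every shape.

Training selects the best-on-validation parameters; gradients are clipped
to a global norm of 10 (rare clamp-boundary windows otherwise destabilize
late epochs). The training-window budget (~2,000) is filled by *balanced*
subsampling: every window whose target has any component above 0.5° (grasp
onsets, approach steps, impact corrections) is kept, and the abundant
quiet-hold windows are stride-subsampled to fill the rest. Uniform striding
was observed to leave so few onset windows that the cloned policy missed
grasp initiation entirely.

## Synthetic grasp dynamics

The plant reduces tool grasping to one mechanical degree of freedom plus a
posture null space. Grip closure is the synergy-weighted joint angle
`c = s·J` with `s = [0.1, 0.3, 0.3, 0.2, 0.1]` (middle joints dominate
corrections). Each pad is a linear spring engaging at a staggered closure
threshold (20–44° across the 9 pads); stiffness is uniform and set so full
closure yields ≈18 N total. A held tool can slip outward by a displacement
that subtracts from effective closure (1 mm ≡ 1°). Impacts arrive as a
Poisson process and kick the displacement; whenever total force falls below
the friction-cone requirement `m g / μ` (0.5 kg, μ = 0.8 → ≈6.1 N) the
displacement ratchets up in proportion to the deficit, otherwise it decays
by ×0.8 per tick. A drop is all pads ≤0.1 N for 3 consecutive ticks
(debounce; the 0.1 N level is the protocol's, the hold time ours), after
which the tool is re-seated following a 1 s recovery penalty. Disturbance
presets: hammer 8 mm kicks at 1.2 /s, saw 4 mm at 1.0 /s, peel 1 mm at
0.6 /s, desk 1 mm at 0.4 /s — calibrated so that a frozen (non-corrective)
policy drops the tool in every hammer episode, occasionally under sawing,
and never on the gentle tasks, reproducing the qualitative task ordering.

**Demonstrator.** The corrective policy combines (i) a proportional force
correction `g (F* − F_total) s` with gain g = 4 °/N toward the 8 N target,
acting on the latest force reading (reaction delay 0 ticks — one tick of
latency remains inherent in the plant update; the FoF baseline's additional
2-tick sensor delay is precisely what distinguishes it), and (ii) a weak
posture regulation (gain 0.3/tick) pulling the joints toward the
synergy-proportional posture at the current closure. The posture term lies
in the null space of the closure map, so it never perturbs the force
dynamics, but it is essential for behaviour cloning: without it the learned
controller drifts off the demonstrated posture manifold in closed loop into
states it has never seen. Demonstration trials begin with a 60-tick rest at
a randomized open posture; the EMG envelope carries a tonic "intent"
component that rises one tick before motion onset (an electromechanical
delay), which is what lets the cloned policy time the grasp initiation.
Occasional small null-space "grip shifts" (1°, 0.3 /s) exercise the
posture-restoring response away from the nominal posture. Only *valid*
(drop-free) demonstrations are kept; a failed demonstration is re-recorded
under a fresh seed. Per-tick effort — which amplitude-modulates a
band-limited (20–500 Hz) noise carrier into the three EMG channels, clipped
to ±2 mV — is `0.25·intent + 0.6·F/F* + 0.4·|ΔJ|₁/5`.

Two independent RNG streams drive the plant and the EMG synthesis, so EMG
noise never perturbs the dynamics, and whole trials are bit-reproducible
under (seed, repetition).

**What the generator does not emulate:** real EMG nonstationarity (fatigue,
electrode shift, crosstalk), tactile hysteresis and shear, tool-specific
contact geometry, and genuinely human corrective variability. Passing the
closed-loop comparisons therefore shows that the architecture can clone and
deploy a corrective policy under impact disturbances with the assumed
statistical couplings — not that it would reach the same margins on human
data.

## Baselines and evaluation

FiF closes along the synergy until a preload is reached, then holds the
posture bitwise-constant. FoF applies `g (F_ref − F_delayed) s` with a
2-tick sensor delay. For closed-loop comparisons the FiF preload is
deliberately *marginal* (7 N, just above the ≈6.1 N slip bound), the regime
in which its non-adaptivity is visible; a grid-search calibration routine
(`experiment.calibrate_baseline`, ranking candidate preloads/references by
mean drops then mean contact force over seeded episodes) reproduces how
such values would be set in preliminary experiments. For offline comparison both
baselines are rolled forward open-loop against the demonstration's recorded
forces — how the original offline baseline curves were produced is
unstated, and this replay is our documented stand-in — while the learned
controller makes teacher-forced one-step predictions.

Metrics: per-joint and overall RMSE; drop counting with the same 3-tick
debounce as the plant; grasp-state labels (unsuccessful: all pads ≤0.1 N;
suboptimal: any pad >15 N; ideal otherwise — boundaries closed/open exactly
as printed); completion time censored at the episode cap; average contact
force over active-contact ticks only (post-drop tails would otherwise
dominate); iEMG (rectangular-rule time integral of rectified amplitude,
summed over channels) and AvEMG (mean rectified amplitude). DTW uses the
classic dynamic program with local cost |a_i − b_j| and steps
(1,0),(0,1),(1,1); the protocol's "average similarity" is not given a
formula anywhere we could find, so we adopt
`s = 1/(1 + d / max(len_a, len_b))`, which satisfies both printed limiting
statements (d→0 ⇒ s→1); the choice is isolated in one function and
swappable.

The closed-loop experiment trains only on the two *seen* tasks (hammer,
saw) and evaluates all four, so peel and desk probe task generalization
exactly as in the original protocol. The simulated user's EMG during
closed-loop runs follows the same effort coupling as the demonstrations, so
effort metrics reflect how hard the grip has to be defended under each
controller. Episode sizes (420-tick demonstrations, 8 per task; 900-tick
episodes, 20 per cell) keep a full comparison within a few CPU-minutes
while holding the Monte-Carlo error of per-cell means well below the
between-controller differences.

## Gesture recognition

Six gestures (RE, WE, WF, HG, HO, WS) map to fixed grasp commands
(HG→grasp, HO→release, RE→hold, wrist gestures→tool-specific wrist
commands). The classifier is two 1-D conv layers (16, 32 channels, kernel
5) with temporal subsampling, a single GRU (hidden 64) and a softmax head —
a standard conv+recurrent stand-in, since the original "dynamic
convolution" mechanism and exact layer sizes are described only in
unavailable supplementary material. Synthetic gesture trials give each
gesture a fixed 3-channel amplitude signature over carrier noise with slow
contraction wobble and per-trial amplitude jitter; signatures are separated
by far more than the noise floor, so high accuracy on this fixture
validates the pipeline (windowing, leak-free splitting, training), not EMG
science. The negative control is a whole-dataset permutation test: all
labels are shuffled, the pipeline is re-run, and accuracy is measured on
the permuted test labels, which concentrates tightly at chance (1/6).
Measuring a shuffled-trained model against the *true* labels instead has
irreducible plurality-vote variance over only six signature clusters and is
not a usable control at this scale.

## Known limitations

* One mechanical degree of freedom: the plant cannot represent multi-finger
  force allocation conflicts; the 9-pad pattern is informative but derived
  from a single closure variable.
* The demonstrator is itself a proportional law, so "policy recovery" is a
  well-posed regression; human demonstrations are richer and noisier.
* The imitation fit (and hence the closed-loop force-tracking margin over
  FoF) varies across experiment seeds more than across network
  initializations — harder demonstration draws yield measurably looser
  clones.
* Finger abduction and wrist degrees of freedom are not modeled; the
  gesture commands act only as discrete mode switches.
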