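"""The multimodal cross-attention grip controller network.

Architecture (per forward pass over a length-P history):

* EMG branch: a 1-D ConvNet (conv → ReLU → conv → average pooling, temporal
  length preserved) extracts high-level features H_E; the raw EMG window is
  linearly projected to E_r; their concatenation is mapped to width d_k and
  then projected to the attention key K and value V.
* Physical-state branch: joint and tactile histories are linearly embedded
  into a shared query space of width d_q each, concatenated, and projected
  to the query Q of width d_a.
* Fusion: multihead scaled dot-product attention with the physical state as
  query and EMG features as key/value, followed by a residual connection,
  layer normalization, a position-wise feed-forward layer, and a second
  residual + normalization (one fusion block; stackable).
* Head: the last fused row z_t is concatenated with linear projections of
  the *current* joint and tactile readings and fed to an MLP that outputs
  the joint-angle increment for the next control tick.

Training minimizes the mean (over samples) squared Euclidean norm of the
increment error with Adam.  Inputs are z-scored per channel with statistics
frozen from the training split.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .data import MultimodalTrial, WindowedSample, make_windows

__all__ = [
    "ModelConfig",
    "TkeBgc",
    "Normalizer",
    "loss_mse",
    "integrate",
    "train",
    "predict_sequence",
    "save_model",
    "load_model",
    "DimensionError",
    "TrainingError",
]

MAX_STEP_DEG = 5.0
JOINT_LIMITS = (0.0, 90.0)


class DimensionError(ValueError):
    pass


class TrainingError(RuntimeError):
    pass


@dataclass
class ModelConfig:
    P: int = 20
    n_emg: int = 3
    n_tactile: int = 9
    n_joint: int = 5
    d_E: int = 32          # EMG feature width
    d_k: int = 64          # key/value input width
    d_q: int = 32          # per-modality query embed width
    d_a: int = 64          # attention width
    h: int = 4             # attention heads
    n_blocks: int = 1      # fusion blocks
    ff_mult: int = 2       # feed-forward expansion inside a block
    mlp_hidden: tuple[int, ...] = (128, 64)
    dropout: float = 0.1
    lr: float = 1e-3
    batch: int = 64
    epochs: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.d_a % self.h != 0:
            raise DimensionError(f"d_a={self.d_a} must be divisible by h={self.h}")
        if self.P < 1 or min(self.d_E, self.d_k, self.d_q, self.d_a, self.h) < 1:
            raise DimensionError("history length and all widths must be >= 1")
        self.mlp_hidden = tuple(self.mlp_hidden)

    @property
    def d_head(self) -> int:
        return self.d_a // self.h


@dataclass
class Normalizer:
    """Per-channel z-scoring with statistics frozen from the training split."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, rows: np.ndarray) -> "Normalizer":
        mean = rows.mean(axis=0)
        std = rows.std(axis=0)
        std[std < 1e-8] = 1.0
        return cls(mean=mean, std=std)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.std


class _FusionBlock(nn.Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.ln1 = nn.LayerNorm(cfg.d_a)
        self.ff1 = nn.Linear(cfg.d_a, cfg.ff_mult * cfg.d_a, rng)
        self.ff2 = nn.Linear(cfg.ff_mult * cfg.d_a, cfg.d_a, rng)
        self.ln2 = nn.LayerNorm(cfg.d_a)

    def __call__(self, q: nn.Tensor, k: nn.Tensor, v: nn.Tensor,
                 drop_rng: np.random.Generator | None = None) -> nn.Tensor:
        cfg = self.cfg
        B, P, _ = q.shape

        def split_heads(x: nn.Tensor) -> nn.Tensor:
            return x.reshape(B, P, cfg.h, cfg.d_head).transpose(0, 2, 1, 3)

        qh, kh, vh = split_heads(q), split_heads(k), split_heads(v)
        scores = (qh @ kh.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(cfg.d_head))
        attn = nn.softmax(scores, axis=-1)
        heads = (attn @ vh).transpose(0, 2, 1, 3).reshape(B, P, cfg.d_a)
        heads = nn.dropout(heads, cfg.dropout, drop_rng)
        x = self.ln1(q + heads)
        ff = self.ff2(nn.dropout(self.ff1(x).relu(), cfg.dropout, drop_rng))
        return self.ln2(x + ff)


class TkeBgc(nn.Module):
    """Cross-attention controller network predicting joint-angle increments."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator | None = None):
        cfg = config
        self.config = cfg
        rng = rng or np.random.default_rng(cfg.seed)
        # EMG branch
        self.conv1 = nn.Conv1d(cfg.n_emg, cfg.d_E, kernel=3, rng=rng)
        self.conv2 = nn.Conv1d(cfg.d_E, cfg.d_E, kernel=3, rng=rng)
        self.W_r = nn.Linear(cfg.n_emg, cfg.d_E, rng, bias=False)
        self.W_r2 = nn.Linear(2 * cfg.d_E, cfg.d_k, rng, bias=False)
        self.W_k = nn.Linear(cfg.d_k, cfg.d_a, rng, bias=False)
        self.W_v = nn.Linear(cfg.d_k, cfg.d_a, rng, bias=False)
        # physical-state query branch
        self.W_J = nn.Linear(cfg.n_joint, cfg.d_q, rng)
        self.W_F = nn.Linear(cfg.n_tactile, cfg.d_q, rng)
        self.W_Q = nn.Linear(2 * cfg.d_q, cfg.d_a, rng, bias=False)
        self.blocks = [_FusionBlock(cfg, rng) for _ in range(cfg.n_blocks)]
        # current-state projections for the prediction head
        self.W_J0 = nn.Linear(cfg.n_joint, cfg.d_q, rng, bias=False)
        self.W_F0 = nn.Linear(cfg.n_tactile, cfg.d_q, rng, bias=False)
        dims = [cfg.d_a + 2 * cfg.d_q, *cfg.mlp_hidden, cfg.n_joint]
        self.mlp = [nn.Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.norm_emg = Normalizer(np.zeros(cfg.n_emg), np.ones(cfg.n_emg))
        self.norm_tac = Normalizer(np.zeros(cfg.n_tactile), np.ones(cfg.n_tactile))
        self.norm_joint = Normalizer(np.zeros(cfg.n_joint), np.ones(cfg.n_joint))

    # -- sub-computations (each checked against a loop oracle in tests) ----
    def _check(self, x: np.ndarray, width: int, what: str) -> None:
        if x.ndim != 3 or x.shape[1] != self.config.P or x.shape[2] != width:
            raise DimensionError(
                f"{what} must have shape [batch, P={self.config.P}, {width}], got {x.shape}"
            )

    def encode_emg(self, emg_hist: np.ndarray,
                   drop_rng: np.random.Generator | None = None) -> nn.Tensor:
        """EMG history [B, P, N_E] -> E' [B, P, d_k] (ConvNet + raw projection)."""
        self._check(np.asarray(emg_hist), self.config.n_emg, "EMG history")
        e = nn.Tensor(self.norm_emg(np.asarray(emg_hist, dtype=float)))
        h = nn.avg_pool1d(self.conv2(self.conv1(e).relu()), kernel=3)
        e_r = self.W_r(e)
        return self.W_r2(nn.concat([h, e_r], axis=-1))

    def project_query(self, joint_hist: np.ndarray, tactile_hist: np.ndarray) -> nn.Tensor:
        """Joint [B, P, N_J] and tactile [B, P, N_F] histories -> Q [B, P, d_a]."""
        self._check(np.asarray(joint_hist), self.config.n_joint, "joint history")
        self._check(np.asarray(tactile_hist), self.config.n_tactile, "tactile history")
        jp = self.W_J(nn.Tensor(self.norm_joint(np.asarray(joint_hist, dtype=float))))
        fp = self.W_F(nn.Tensor(self.norm_tac(np.asarray(tactile_hist, dtype=float))))
        return self.W_Q(nn.concat([jp, fp], axis=-1))

    def fuse(self, q: nn.Tensor, k: nn.Tensor, v: nn.Tensor,
             drop_rng: np.random.Generator | None = None) -> nn.Tensor:
        """Multihead cross-attention fusion block(s): [B, P, d_a] -> [B, P, d_a]."""
        z = q
        for block in self.blocks:
            z = block(z, k, v, drop_rng)
        return z

    def predict_increment(self, z: nn.Tensor, joints_now: np.ndarray,
                          tactile_now: np.ndarray,
                          drop_rng: np.random.Generator | None = None) -> nn.Tensor:
        """Fused sequence + current state -> increment estimate [B, N_J] (deg)."""
        z_t = z[(slice(None), -1)]
        j0 = self.W_J0(nn.Tensor(self.norm_joint(np.asarray(joints_now, dtype=float))))
        f0 = self.W_F0(nn.Tensor(self.norm_tac(np.asarray(tactile_now, dtype=float))))
        u = nn.concat([z_t, j0, f0], axis=-1)
        for layer in self.mlp[:-1]:
            u = nn.dropout(layer(u).relu(), self.config.dropout, drop_rng)
        return self.mlp[-1](u)

    def forward(self, emg_hist: np.ndarray, tactile_hist: np.ndarray,
                joint_hist: np.ndarray,
                drop_rng: np.random.Generator | None = None) -> nn.Tensor:
        e_prime = self.encode_emg(emg_hist, drop_rng)
        k, v = self.W_k(e_prime), self.W_v(e_prime)
        q = self.project_query(joint_hist, tactile_hist)
        z = self.fuse(q, k, v, drop_rng)
        return self.predict_increment(
            z, np.asarray(joint_hist)[:, -1], np.asarray(tactile_hist)[:, -1], drop_rng
        )

    def predict(self, emg_hist: np.ndarray, tactile_hist: np.ndarray,
                joint_hist: np.ndarray) -> np.ndarray:
        """Inference-mode increments (no dropout), as a plain array [B, N_J]."""
        return self.forward(emg_hist, tactile_hist, joint_hist).data

    # -- (de)serialization -------------------------------------------------
    def named_params(self) -> dict[str, nn.Tensor]:
        out: dict[str, nn.Tensor] = {}

        def visit(obj, prefix):
            for name, v in vars(obj).items():
                if isinstance(v, nn.Tensor) and v.requires_grad:
                    out[f"{prefix}{name}"] = v
                elif isinstance(v, nn.Module):
                    visit(v, f"{prefix}{name}.")
                elif isinstance(v, list) and v and isinstance(v[0], nn.Module):
                    for i, item in enumerate(v):
                        visit(item, f"{prefix}{name}.{i}.")

        visit(self, "")
        return out


def loss_mse(pred: nn.Tensor | np.ndarray, target: np.ndarray) -> nn.Tensor:
    """Mean over samples of the squared Euclidean norm of the increment error."""
    pred = pred if isinstance(pred, nn.Tensor) else nn.Tensor(pred)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise DimensionError(f"prediction {pred.shape} vs target {target.shape}")
    diff = pred - nn.Tensor(target)
    return (diff * diff).sum(axis=-1).mean()


def integrate(joints: np.ndarray, delta: np.ndarray,
              max_step: float = MAX_STEP_DEG,
              limits: tuple[float, float] = JOINT_LIMITS) -> np.ndarray:
    """Apply an increment under the per-tick step clamp and joint limits."""
    step = np.clip(np.asarray(delta, dtype=float), -max_step, max_step)
    return np.clip(np.asarray(joints, dtype=float) + step, *limits)


def _stack(samples: list[WindowedSample]):
    E = np.stack([s.emg_hist for s in samples])
    F = np.stack([s.tactile_hist for s in samples])
    J = np.stack([s.joint_hist for s in samples])
    y = np.stack([s.target_delta for s in samples])
    return E, F, J, y


def train(
    train_samples: list[WindowedSample],
    val_samples: list[WindowedSample],
    config: ModelConfig,
    verbose: bool = False,
) -> tuple[TkeBgc, dict]:
    """Adam training on the increment MSE; returns best-on-validation model.

    Fully seeded (weight init, shuffling, dropout) via ``config.seed``.
    """
    if not train_samples:
        raise TrainingError("empty training set")
    rng = np.random.default_rng(config.seed)
    model = TkeBgc(config, rng)
    E, F, J, y = _stack(train_samples)
    model.norm_emg = Normalizer.fit(E.reshape(-1, E.shape[-1]))
    model.norm_tac = Normalizer.fit(F.reshape(-1, F.shape[-1]))
    model.norm_joint = Normalizer.fit(J.reshape(-1, J.shape[-1]))
    has_val = len(val_samples) > 0
    if has_val:
        Ev, Fv, Jv, yv = _stack(val_samples)

    params = list(model.named_params().values())
    opt = nn.Adam(params, lr=config.lr)
    history = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_state = None
    n = len(train_samples)
    # step decay stabilizes the late epochs so best-on-val is not a lottery
    decay_points = {int(config.epochs * 0.6), int(config.epochs * 0.85)}
    for epoch in range(config.epochs):
        if epoch in decay_points:
            opt.lr *= 0.3
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch):
            idx = order[start : start + config.batch]
            opt.zero_grad()
            pred = model.forward(E[idx], F[idx], J[idx], drop_rng=rng)
            loss = loss_mse(pred, y[idx])
            if not np.isfinite(loss.data):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            loss.backward()
            opt.clip_grad_norm(10.0)
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        history["train_loss"].append(epoch_loss / n)
        if has_val:
            vl = float(loss_mse(model.predict(Ev, Fv, Jv), yv).data)
            history["val_loss"].append(vl)
            if vl < best_val:
                best_val = vl
                best_state = {k: t.data.copy() for k, t in model.named_params().items()}
        if verbose:
            msg = f"epoch {epoch + 1}/{config.epochs} train {history['train_loss'][-1]:.5f}"
            if has_val:
                msg += f" val {history['val_loss'][-1]:.5f}"
            print(msg)
    if best_state is not None:
        for k, t in model.named_params().items():
            t.data = best_state[k]
    return model, history


def predict_sequence(trial: MultimodalTrial, model: TkeBgc,
                     batch: int = 512) -> np.ndarray:
    """Teacher-forced one-step joint predictions J_hat_{t+1} for every t >= P-1.

    Returns [T - P, N_J]; row k predicts the joints at tick k + P from the
    recorded history ending at tick k + P - 1.
    """
    windows = make_windows(trial, model.config.P)
    if not windows:
        raise ValueError(f"trial too short for P={model.config.P}")
    E, F, J, _ = _stack(windows)
    preds = []
    for start in range(0, len(windows), batch):
        sl = slice(start, start + batch)
        delta = model.predict(E[sl], F[sl], J[sl])
        preds.append(integrate(J[sl][:, -1], delta))
    return np.vstack(preds)


def save_model(model: TkeBgc, path: str | Path) -> Path:
    """Archive = zip of named weight arrays (.npy) + config + norm stats JSON."""
    path = Path(path)
    cfg = asdict(model.config)
    cfg["mlp_hidden"] = list(cfg["mlp_hidden"])
    meta = {
        "config": cfg,
        "norm": {
            "emg": [model.norm_emg.mean.tolist(), model.norm_emg.std.tolist()],
            "tac": [model.norm_tac.mean.tolist(), model.norm_tac.std.tolist()],
            "joint": [model.norm_joint.mean.tolist(), model.norm_joint.std.tolist()],
        },
    }
    import io

    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta, indent=1))
        for name, tensor in model.named_params().items():
            buf = io.BytesIO()
            np.save(buf, tensor.data)
            zf.writestr(f"weights/{name}.npy", buf.getvalue())
    return path


def load_model(path: str | Path) -> TkeBgc:
    import io

    with zipfile.ZipFile(Path(path)) as zf:
        meta = json.loads(zf.read("meta.json"))
        cfg_kw = meta["config"]
        cfg_kw["mlp_hidden"] = tuple(cfg_kw["mlp_hidden"])
        model = TkeBgc(ModelConfig(**cfg_kw))
        for name, tensor in model.named_params().items():
            arr = np.load(io.BytesIO(zf.read(f"weights/{name}.npy")))
            if arr.shape != tensor.data.shape:
                raise DimensionError(
                    f"archived weight {name} has shape {arr.shape}, expected {tensor.data.shape}"
                )
            tensor.data = arr
        for attr, key in (("norm_emg", "emg"), ("norm_tac", "tac"), ("norm_joint", "joint")):
            mean, std = meta["norm"][key]
            setattr(model, attr, Normalizer(np.asarray(mean), np.asarray(std)))
    return model
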