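"""Joint adversarial training.

The total objective is ``L = L_cls + L_adv``: cross-entropy of the workload
classifier on the concatenated fused features plus an adversarial term that
drives the shared trunk toward modality-invariant features. Gradients are
clipped elementwise to an absolute value of 10 and the learning rate defaults
to 1e-3 (Adam).

Two adversarial modes are provided:

``non_saturating`` (default)
    Each epoch the modality classifier ``M`` is first refit to
    near-optimality on the cached fused features (it is a small MLP, so this
    costs little), then the feature path minimizes ``L_cls`` plus a
    flipped-label confusion term ``lambda * CE(M~(f), 1 - y_modal)`` against
    the frozen critic ``M~``. This is the standard non-saturating
    reformulation of the adversarial game: when ``M`` is confident, the plain
    reversed cross-entropy gradient vanishes (``dCE/dlogits = p - y -> 0``)
    and alignment stalls, whereas the confusion term keeps a strong gradient.
    Both formulations share the same fixed points (modality
    indistinguishability).

``grl``
    The literal single-loss formulation: ``L_adv = CE(M(GRL(f)), y_modal)``
    with the gradient-reversal layer carrying ``-lambda`` to the feature
    path, minimized jointly in one backward pass.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .autodiff import Tensor, concat, no_grad
from .model import TRMMAAN
from .preprocessing import PairedSample

__all__ = ["TrainConfig", "TrainState", "TrainedModel", "cross_entropy",
           "cross_entropy_logits", "total_loss", "train_epoch", "fit",
           "samples_to_arrays"]

logger = logging.getLogger(__name__)

PROB_FLOOR = 1e-12


@dataclass
class TrainConfig:
    lr: float = 1e-3
    clip_abs: float = 10.0
    epochs: int = 100
    batch_size: int = 32
    optimizer: str = "adam"
    adversarial_mode: str = "non_saturating"   # "non_saturating" | "grl"
    critic_steps: int = 30      # M refit steps per epoch (non_saturating)
    patience: int = 15          # early stop on training-loss plateau
    seed: int = 0

    def __post_init__(self):
        if self.lr < 0:
            raise ValueError("lr must be >= 0")
        if self.clip_abs <= 0:
            raise ValueError("clip_abs must be > 0")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")
        if self.adversarial_mode not in ("non_saturating", "grl"):
            raise ValueError("adversarial_mode must be 'non_saturating' or 'grl'")


@dataclass
class TrainState:
    epoch: int = 0
    loss_total: float = math.nan
    loss_cls: float = math.nan
    loss_adv: float = math.nan
    modal_acc: float = math.nan
    workload_acc_train: float = math.nan
    history: list[dict] = field(default_factory=list)


@dataclass
class TrainedModel:
    model: TRMMAAN
    history: list[dict]
    best_epoch: int


def cross_entropy(probs: np.ndarray, true_label: int) -> float:
    """``-log`` of the probability assigned to the true class.

    Probabilities are floored at 1e-12 for numerical safety.
    """
    probs = np.asarray(probs, dtype=np.float64)
    if not (0 <= true_label < probs.shape[-1]):
        raise ValueError(
            f"label {true_label} out of range for {probs.shape[-1]} classes")
    return float(-np.log(max(probs[true_label], PROB_FLOOR)))


def cross_entropy_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy from logits (stable log-softmax path), batched."""
    logp = nn.log_softmax(logits, axis=-1)
    n = logits.shape[0]
    picked = logp[np.arange(n), np.asarray(labels, dtype=np.intp)]
    return -picked.mean()


def total_loss(l_cls: float, l_adv: float) -> float:
    """``L = L_cls + L_adv`` (exact sum)."""
    if not (np.isfinite(l_cls) and np.isfinite(l_adv)):
        raise ValueError("loss terms must be finite")
    return l_cls + l_adv


def samples_to_arrays(samples: list[PairedSample]
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack a sample list into (eeg [N,C,T], emg [N,C,T], labels [N])."""
    eeg = np.stack([s.eeg for s in samples])
    emg = np.stack([s.emg for s in samples])
    y = np.array([s.label for s in samples], dtype=np.intp)
    return eeg, emg, y


def _modal_label_batch(n: int) -> np.ndarray:
    """Modality targets for a concatenated [eeg; emg] feature batch."""
    return np.concatenate([np.zeros(n, dtype=np.intp),
                           np.ones(n, dtype=np.intp)])


def _frozen_modal_logits(model: TRMMAAN, f: Tensor) -> Tensor:
    """M's logits with its parameters treated as constants (frozen critic)."""
    head = model.modal_head
    h = (f @ Tensor(head.fc1.weight.data) + Tensor(head.fc1.bias.data)).relu()
    return h @ Tensor(head.fc2.weight.data) + Tensor(head.fc2.bias.data)


def _refit_critic(model: TRMMAAN, eeg: np.ndarray, emg: np.ndarray,
                  optimizer: "nn.Adam", steps: int, clip_abs: float) -> float:
    """Train M on the current (cached, inference-mode) fused features.

    Returns M's post-refit accuracy on those features.
    """
    model.eval()
    with no_grad():
        fused = model.fused_features(Tensor(eeg), Tensor(emg))
    model.train()
    F = np.concatenate([fused["eeg"].data, fused["emg"].data])
    labels = _modal_label_batch(len(eeg))
    for _ in range(steps):
        logits = model.modal_head.logits(Tensor(F))
        loss = cross_entropy_logits(logits, labels)
        optimizer.zero_grad()
        loss.backward()
        nn.clip_gradients_(model.modal_head.parameters(), clip_abs)
        optimizer.step()
    with no_grad():
        pred = model.modal_head.logits(Tensor(F)).data.argmax(axis=-1)
    return float((pred == labels).mean())


def _batch_losses_grl(model: TRMMAAN, eeg: np.ndarray, emg: np.ndarray,
                      y: np.ndarray) -> tuple[Tensor, Tensor, Tensor, dict]:
    """Single-loss GRL formulation: returns (loss, l_cls, l_adv, diag)."""
    out = model.forward(Tensor(eeg) if model.uses_eeg else None,
                        Tensor(emg) if model.uses_emg else None)
    l_cls = cross_entropy_logits(out["workload_logits"], y)
    diag = {"workload_pred": out["workload_logits"].data.argmax(axis=-1)}
    if model.uses_adversary:
        logits = concat([out["modal_logits_eeg"], out["modal_logits_emg"]],
                        axis=0)
        labels = _modal_label_batch(len(y))
        l_adv = cross_entropy_logits(logits, labels)
        diag["modal_acc"] = float((logits.data.argmax(axis=-1) == labels).mean())
    else:
        l_adv = Tensor(0.0)
        diag["modal_acc"] = math.nan
    return l_cls + l_adv, l_cls, l_adv, diag


def _batch_losses_nonsat(model: TRMMAAN, eeg: np.ndarray, emg: np.ndarray,
                         y: np.ndarray) -> tuple[Tensor, Tensor, Tensor, dict]:
    """Non-saturating feature objective against the frozen critic."""
    fused = model.fused_features(Tensor(eeg), Tensor(emg))
    feats = [fused[m] for m in ("eeg", "emg") if m in fused]
    cat = feats[0] if len(feats) == 1 else concat(feats, axis=1)
    wl = model.workload_head.logits(cat)
    l_cls = cross_entropy_logits(wl, y)
    diag = {"workload_pred": wl.data.argmax(axis=-1)}
    if model.uses_adversary:
        logits = concat([_frozen_modal_logits(model, fused["eeg"]),
                         _frozen_modal_logits(model, fused["emg"])], axis=0)
        labels = _modal_label_batch(len(y))
        # confusion term: drive the frozen critic's prediction toward the
        # uniform distribution (cross-entropy against the uniform target),
        # which merges the modality clusters instead of swapping them
        logp = nn.log_softmax(logits, axis=-1)
        l_adv = -logp.mean() * model.cfg.grl_lambda
        diag["modal_acc"] = float((logits.data.argmax(axis=-1) == labels).mean())
    else:
        l_adv = Tensor(0.0)
        diag["modal_acc"] = math.nan
    return l_cls + l_adv, l_cls, l_adv, diag


def _batch_losses(model: TRMMAAN, eeg: np.ndarray, emg: np.ndarray,
                  y: np.ndarray, mode: str = "grl"):
    if mode == "grl" or not model.uses_adversary:
        return _batch_losses_grl(model, eeg, emg, y)
    return _batch_losses_nonsat(model, eeg, emg, y)


class _Optimizers:
    """Feature-path optimizer plus (when the model has an adversary trained
    in non-saturating mode) a separate critic optimizer for M."""

    def __init__(self, model: TRMMAAN, cfg: TrainConfig):
        self.split = (model.uses_adversary
                      and cfg.adversarial_mode == "non_saturating")
        if self.split:
            feat = [p for name, p in model.named_parameters()
                    if not name.startswith("modal_head")]
            self.features = _make_optimizer(feat, cfg)
            self.critic = _make_optimizer(model.modal_head.parameters(), cfg)
            self.feat_params = feat
        else:
            self.features = _make_optimizer(model.parameters(), cfg)
            self.critic = None
            self.feat_params = model.parameters()


def _make_optimizer(params: list[Tensor], cfg: TrainConfig):
    if cfg.optimizer == "adam":
        return nn.Adam(params, lr=cfg.lr)

    class SGD:
        def __init__(self, params, lr):
            self.params, self.lr = params, lr

        def step(self):
            for p in self.params:
                if p.grad is not None:
                    p.data -= self.lr * p.grad

        def zero_grad(self):
            for p in self.params:
                p.zero_grad()

    return SGD(params, cfg.lr)


def train_epoch(model: TRMMAAN, data: list[PairedSample], cfg: TrainConfig,
                state: TrainState, optimizer: _Optimizers | None = None,
                rng: np.random.Generator | None = None) -> TrainState:
    """One shuffled pass over the training data.

    Per batch: forward both branches, compute the classification and
    adversarial losses, backpropagate, clip every gradient element to
    ``[-clip_abs, +clip_abs]``, and step the optimizer. In non-saturating
    mode the critic M is refit on cached features before the pass.
    """
    if optimizer is None:
        optimizer = _Optimizers(model, cfg)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    eeg, emg, y = samples_to_arrays(data)
    model.train()

    critic_acc = math.nan
    if optimizer.split:
        critic_acc = _refit_critic(model, eeg, emg, optimizer.critic,
                                   cfg.critic_steps, cfg.clip_abs)

    order = rng.permutation(len(y))
    tot = cls = adv = 0.0
    modal_accs: list[float] = []
    correct = 0
    n_batches = 0
    for start in range(0, len(order), cfg.batch_size):
        idx = order[start:start + cfg.batch_size]
        loss, l_cls, l_adv, diag = _batch_losses(
            model, eeg[idx], emg[idx], y[idx], cfg.adversarial_mode)
        if not np.isfinite(loss.data):
            stats = {
                "batch_indices": idx.tolist(),
                "eeg_absmax": float(np.abs(eeg[idx]).max()),
                "emg_absmax": float(np.abs(emg[idx]).max()),
                "l_cls": float(l_cls.data), "l_adv": float(l_adv.data),
            }
            raise RuntimeError(
                f"NaN/Inf loss during training; batch stats: {stats}")
        optimizer.features.zero_grad()
        loss.backward()
        nn.clip_gradients_(optimizer.feat_params, cfg.clip_abs)
        optimizer.features.step()
        tot += float(loss.data)
        cls += float(l_cls.data)
        adv += float(l_adv.data)
        if np.isfinite(diag["modal_acc"]):
            modal_accs.append(diag["modal_acc"])
        correct += int((diag["workload_pred"] == y[idx]).sum())
        n_batches += 1

    state.epoch += 1
    state.loss_total = tot / n_batches
    state.loss_cls = cls / n_batches
    state.loss_adv = adv / n_batches
    if optimizer.split:
        state.modal_acc = critic_acc
    else:
        state.modal_acc = float(np.mean(modal_accs)) if modal_accs else math.nan
    state.workload_acc_train = correct / len(order)
    state.history.append({
        "epoch": state.epoch, "loss_total": state.loss_total,
        "loss_cls": state.loss_cls, "loss_adv": state.loss_adv,
        "modal_acc": state.modal_acc,
        "workload_acc_train": state.workload_acc_train,
    })
    return state


def fit(model: TRMMAAN, train_data: list[PairedSample],
        cfg: TrainConfig) -> TrainedModel:
    """Epoch loop with early stopping on a plateau of the classification
    loss.

    For non-adversarial variants the best-epoch (lowest training-loss)
    parameters are restored at the end.

    For adversarially trained models the total loss is smallest early in
    training simply because the modality classifier is still weak, so
    best-total-loss restoring would return a nearly unaligned model.
    Instead the checkpoint criterion is the *minimum critic-refit accuracy*:
    each epoch starts by refitting M on the previous epoch's features, and
    the recorded accuracy measures how separable those features still are —
    the state where even a freshly refit critic fails most is the
    best-aligned state. The first third of the run is treated as burn-in
    (both players are still warming up); if no epoch qualifies, the final
    parameters are kept.
    """
    state = TrainState()
    optimizer = _Optimizers(model, cfg)
    rng = np.random.default_rng(cfg.seed)
    adversarial = optimizer.split         # non-saturating adversarial mode
    burn_in = max(cfg.epochs // 3, 5)
    best_loss = math.inf
    best_critic = math.inf
    best_acc_tr = 0.0
    best_state: dict | None = None
    best_epoch = 0
    since_best = 0
    for _ in range(cfg.epochs):
        snapshot = model.state_dict() if adversarial else None
        train_epoch(model, train_data, cfg, state, optimizer, rng)
        if adversarial:
            # state.modal_acc is the refit-critic accuracy on the features
            # of the snapshot taken just above; a snapshot only qualifies
            # when its own training accuracy was near the best seen, so the
            # alignment criterion cannot revert to a half-trained classifier
            snap_acc = (state.history[-2]["workload_acc_train"]
                        if len(state.history) >= 2 else 0.0)
            best_acc_tr = max(best_acc_tr, state.workload_acc_train)
            if (state.epoch > burn_in and np.isfinite(state.modal_acc)
                    and state.modal_acc < best_critic - 1e-12
                    and snap_acc >= best_acc_tr - 0.05):
                best_critic = state.modal_acc
                best_state = snapshot
                best_epoch = state.epoch - 1
        if state.loss_cls < best_loss - 1e-9:
            best_loss = state.loss_cls
            since_best = 0
            if not adversarial:
                best_state = model.state_dict()
                best_epoch = state.epoch
        else:
            since_best += 1
            if since_best >= cfg.patience:
                logger.info("early stop at epoch %d", state.epoch)
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    else:
        best_epoch = state.epoch
    return TrainedModel(model, state.history, best_epoch)
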