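"""Mean Teacher semi-supervised training engine.

Two networks with identical architecture are maintained: a *student*
trained by backpropagation and a *teacher* whose parameters are an
exponential moving average (EMA) of the student's,

    theta' <- alpha * theta' + (1 - alpha) * theta,

updated after every optimization step and never receiving gradients.
Each step the student sees a strongly-augmented view of every clip and is
trained on

    total = L_sup + lambda(epoch) * (J + L_pseudo)

where ``L_sup`` is cross-entropy on labeled clips, ``J`` is the squared
2-norm distance between student and teacher class-probability vectors on
unlabeled clips (the teacher sees a weakly-augmented view), ``L_pseudo``
is cross-entropy against confidence-gated hard teacher labels, and
``lambda`` ramps linearly from 0 to its ceiling over the first 30 epochs.
Teacher predictions with maximum probability strictly above the
confidence threshold ``tau`` (0.8) are additionally *promoted*: the
sample leaves the unlabeled pool and joins the supervising set with its
hard pseudo-label, flagged as pseudo so it can never overwrite a ground
truth label.

Note on the combined objective: one printed form of the objective weights
the supervised term by ``lambda`` and the consistency term by
``1 - lambda``, which would anneal supervision off as the ramp completes;
the operational protocol ("the consistency weight lambda increases from 0
to 1.0") and the standard Mean Teacher formulation both imply
``L_sup + lambda * J``, which is what this module implements.

The public surface follows the model/results convention:
``MeanTeacherModel(labeled, unlabeled, val, config).fit(seed)`` returns a
:class:`TrainingResults` carrying the fitted networks, the per-epoch
history and a ``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .backbone3d import BackboneConfig, GaitBackbone
from .nn.optim import Adam
from .synthetic_gait import GaitSample, label2_from_label3
from .video_data import AugmentConfig, strong_augment, weak_augment

__all__ = [
    "TrainConfig",
    "TrainState",
    "LossBreakdown",
    "PseudoLabelRecord",
    "MeanTeacherModel",
    "TrainingResults",
    "softmax",
    "cross_entropy",
    "consistency_loss",
    "combined_loss",
    "ramp_lambda",
    "ema_update",
    "confidence_gate",
    "promote_pseudo_labels",
]

_EPS = 1e-12

LABELS3 = (11, 21, 22)


# ---------------------------------------------------------------------------
# losses and schedules
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Shift-invariant softmax; safe for arbitrarily large finite logits."""
    z = logits - np.max(logits, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _check_onehot(Y: np.ndarray) -> None:
    if Y.ndim == 1:
        Y = Y[None]
    ok = np.all(np.isin(Y, (0, 1))) and np.all(Y.sum(axis=-1) == 1)
    if not ok:
        raise ValueError("Y must be one-hot")


def cross_entropy(p: np.ndarray, Y: np.ndarray) -> float:
    """Mean cross-entropy -sum_i Y_i log p_i over the batch.

    ``p`` rows must sum to 1; probabilities are clamped below at 1e-12.
    """
    p = np.atleast_2d(np.asarray(p, dtype=np.float64))
    Y = np.atleast_2d(np.asarray(Y))
    _check_onehot(Y)
    if p.shape != Y.shape:
        raise ValueError("p and Y shape mismatch")
    return float(-(Y * np.log(np.clip(p, _EPS, None))).sum(axis=1).mean())


def consistency_loss(p_student: np.ndarray, p_teacher: np.ndarray) -> float:
    """Squared 2-norm between probability vectors, averaged over the batch."""
    ps = np.atleast_2d(np.asarray(p_student, dtype=np.float64))
    pt = np.atleast_2d(np.asarray(p_teacher, dtype=np.float64))
    if ps.shape != pt.shape:
        raise ValueError("probability vector length mismatch")
    return float(((ps - pt) ** 2).sum(axis=1).mean())


@dataclass
class LossBreakdown:
    supervised: float
    consistency: float
    lambda_used: float
    pseudo: float = 0.0
    total: float = field(init=False)

    def __post_init__(self):
        self.total = self.supervised + self.lambda_used * (
            self.consistency + self.pseudo)


def combined_loss(supervised: float, consistency: float,
                  lam: float, pseudo: float = 0.0) -> LossBreakdown:
    """total = L_sup + lambda * (J + L_pseudo); an empty unlabeled batch
    contributes 0 consistency for any lambda."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    return LossBreakdown(supervised=supervised, consistency=consistency,
                         lambda_used=lam, pseudo=pseudo)


def ramp_lambda(epoch: int, ramp_epochs: int = 30, ceiling: float = 1.0) -> float:
    """Linear consistency-weight ramp: 0 at epoch 0, ceiling from
    ``ramp_epochs`` on; non-decreasing."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    if ramp_epochs <= 0:
        return ceiling
    return ceiling * min(1.0, epoch / ramp_epochs)


def ema_update(theta_prime: dict[str, np.ndarray],
               theta: dict[str, np.ndarray], alpha: float) -> dict[str, np.ndarray]:
    """In-place EMA: every teacher entry <- alpha*old + (1-alpha)*student.

    Applied uniformly to weights and normalization buffers.
    """
    if set(theta_prime) != set(theta):
        raise ValueError("teacher/student parameter structure mismatch")
    for k, tp in theta_prime.items():
        if tp.shape != theta[k].shape:
            raise ValueError(f"shape mismatch for {k}")
        tp[...] = alpha * tp + (1.0 - alpha) * theta[k]
    return theta_prime


# ---------------------------------------------------------------------------
# pseudo-labeling
# ---------------------------------------------------------------------------

@dataclass
class PseudoLabelRecord:
    sample: object
    soft_label: np.ndarray
    confidence: float
    accepted: bool
    hard_label: int


def confidence_gate(p_teacher: np.ndarray, tau: float = 0.8,
                    samples: list | None = None) -> list[PseudoLabelRecord]:
    """Gate teacher probability vectors at confidence strictly above tau."""
    p = np.atleast_2d(np.asarray(p_teacher, dtype=np.float64))
    records = []
    for i, row in enumerate(p):
        conf = float(row.max())
        records.append(PseudoLabelRecord(
            sample=None if samples is None else samples[i],
            soft_label=row, confidence=conf,
            accepted=conf > tau, hard_label=int(row.argmax())))
    return records


def promote_pseudo_labels(records: list[PseudoLabelRecord],
                          labeled_pool: list, unlabeled_pool: list,
                          class_labels: tuple[int, ...] = LABELS3
                          ) -> tuple[list, list, int]:
    """Move gate-accepted samples into the supervising pool.

    Accepted samples receive their hard pseudo-label (flagged ``pseudo``)
    and leave the unlabeled pool; ground-truth labels are never
    overwritten.  Returns (labeled_pool, unlabeled_pool, n_promoted).
    """
    promoted_ids = set()
    for rec in records:
        if not rec.accepted or rec.sample is None:
            continue
        s = rec.sample
        if s.labeled and not s.pseudo:
            raise ValueError(
                f"sample {s.subject_id} already carries a ground-truth label")
        s.label3 = class_labels[rec.hard_label]
        s.label2 = label2_from_label3(s.label3)
        s.pseudo = True
        labeled_pool.append(s)
        promoted_ids.add(id(s))
    remaining = [s for s in unlabeled_pool if id(s) not in promoted_ids]
    return labeled_pool, remaining, len(promoted_ids)


# ---------------------------------------------------------------------------
# configuration and state
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Hyperparameters; defaults follow the full-scale training protocol
    (Adam 1e-4 with betas (0.9, 0.999), batch 16, 100 epochs, early stop
    after 10 stagnant validation epochs, learning rate halved after 5,
    EMA rate 0.99, confidence threshold 0.8, 30-epoch lambda ramp)."""

    epochs: int = 100
    batch_size: int = 16
    lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    alpha: float = 0.99
    tau: float = 0.8
    ramp_epochs: int = 30
    lambda_ceiling: float = 1.0
    phase1_epochs: int = 0          # supervised warm-up before the ramp
    early_stop_patience: int = 10
    plateau_patience: int = 5
    plateau_factor: float = 0.5
    pseudo_ce: bool = True          # hard pseudo-label CE term in phase 2
    promote: bool = True            # pool promotion at epoch ends
    augment: AugmentConfig = field(default_factory=AugmentConfig)

    def __post_init__(self):
        if not (0.0 <= self.alpha < 1.0):
            raise ValueError("alpha must lie in [0, 1)")
        if self.lambda_ceiling < 0:
            raise ValueError("lambda ceiling must be >= 0")


@dataclass
class TrainState:
    """Mutable training state: the two networks and schedule position."""

    student: GaitBackbone
    teacher: GaitBackbone
    optimizer: Adam
    epoch: int = 0
    lr: float = 1e-4
    alpha: float = 0.99
    tau: float = 0.8

    def teacher_state(self) -> dict[str, np.ndarray]:
        state = dict(self.teacher.named_params())
        state.update(self.teacher.named_buffers())
        return state

    def student_state(self) -> dict[str, np.ndarray]:
        state = dict(self.student.named_params())
        state.update(self.student.named_buffers())
        return state


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

def _stack_clips(samples: list[GaitSample]) -> np.ndarray:
    return np.concatenate([s.clip for s in samples], axis=0).astype(np.float32)


def _onehot(labels3: list[int], C: int = 3) -> np.ndarray:
    idx = np.array([LABELS3.index(l) for l in labels3])
    Y = np.zeros((len(idx), C), dtype=np.float32)
    Y[np.arange(len(idx)), idx] = 1.0
    return Y


class MeanTeacherModel:
    """Semi-supervised gait classifier in model/results style.

    Parameters
    ----------
    labeled, unlabeled
        Training pools of :class:`GaitSample`; the unlabeled pool may be
        empty, in which case training degrades to plain supervised
        training.
    val
        Validation samples (labeled) driving early stopping and the
        learning-rate plateau schedule.
    backbone_config, config
        Architecture and optimization hyperparameters.
    """

    def __init__(self, labeled: list[GaitSample],
                 unlabeled: list[GaitSample] | None = None,
                 val: list[GaitSample] | None = None,
                 backbone_config: BackboneConfig | None = None,
                 config: TrainConfig | None = None):
        if not labeled:
            raise ValueError("labeled training set must be non-empty")
        for s in labeled:
            if not s.labeled:
                raise ValueError(f"unlabeled sample {s.subject_id} in labeled pool")
        self.labeled = list(labeled)
        self.unlabeled = list(unlabeled or [])
        self.val = list(val or [])
        T, H, W = labeled[0].clip.shape[2:]
        self.backbone_config = backbone_config or BackboneConfig.make_tiny(
            in_channels=labeled[0].clip.shape[1], input_shape=(T, H, W))
        self.config = config or TrainConfig()

    @classmethod
    def from_samples(cls, samples: list[GaitSample], split, **kwargs
                     ) -> "MeanTeacherModel":
        """Build pools from a sample list and a :class:`SplitAssignment`."""
        by_split = {"train": [], "validation": [], "test": []}
        for s in samples:
            sp = split.mapping.get(s.subject_id)
            if sp in by_split:
                by_split[sp].append(s)
        labeled = [s for s in by_split["train"] if s.labeled]
        unlabeled = [s for s in by_split["train"] if not s.labeled]
        val = [s for s in by_split["validation"] if s.labeled]
        return cls(labeled, unlabeled, val, **kwargs)

    # -- internals ---------------------------------------------------------
    def _predict_proba(self, net: GaitBackbone, samples: list[GaitSample],
                       batch: int = 16) -> np.ndarray:
        net.eval()
        out = []
        for i in range(0, len(samples), batch):
            X = _stack_clips(samples[i:i + batch])
            out.append(softmax(net.forward(X)))
        net.train()
        return np.concatenate(out, axis=0)

    def _validate(self, net: GaitBackbone) -> tuple[float, float]:
        if not self.val:
            return float("nan"), float("nan")
        p = self._predict_proba(net, self.val)
        Y = _onehot([s.label3 for s in self.val])
        loss = cross_entropy(p, Y)
        acc = float((p.argmax(1) == Y.argmax(1)).mean())
        return loss, acc

    def fit(self, seed: int = 0, log_path: str | Path | None = None,
            verbose: bool = False) -> "TrainingResults":
        """Train student and teacher; reproducible given ``seed``.

        One integer seed fans out to independent streams for parameter
        initialization, batch order and the two augmentation branches.
        """
        cfg = self.config
        ss = np.random.SeedSequence(seed)
        init_s, order_s, aug_s, aug_t = ss.spawn(4)
        init_seed = int(init_s.generate_state(1)[0] % (2 ** 31 - 1))
        order_rng = np.random.default_rng(order_s)
        aug_rng_s = np.random.default_rng(aug_s)
        aug_rng_t = np.random.default_rng(aug_t)

        student = GaitBackbone(self.backbone_config, seed=init_seed)
        teacher = GaitBackbone(self.backbone_config, seed=init_seed)
        teacher.load_state_dict(student.state_dict())  # theta' <- theta
        opt = Adam(student.named_params(), lr=cfg.lr,
                   beta1=cfg.beta1, beta2=cfg.beta2)
        state = TrainState(student=student, teacher=teacher, optimizer=opt,
                           lr=cfg.lr, alpha=cfg.alpha, tau=cfg.tau)

        sup_pool = list(self.labeled)
        unl_pool = list(self.unlabeled)
        history: list[dict] = []
        best_val = np.inf
        best_state = student.state_dict()
        best_epoch = -1
        stagnant_stop = stagnant_lr = 0
        log_fh = open(log_path, "w") if log_path else None

        for epoch in range(cfg.epochs):
            state.epoch = epoch
            lam = ramp_lambda(max(0, epoch - cfg.phase1_epochs),
                              cfg.ramp_epochs, cfg.lambda_ceiling)
            in_phase2 = epoch >= cfg.phase1_epochs
            order = order_rng.permutation(len(sup_pool))
            unl_order = (order_rng.permutation(len(unl_pool))
                         if unl_pool else np.array([], dtype=int))
            sup_losses, cons_losses, pseudo_losses = [], [], []
            u_cursor = 0
            s_cursor = 0
            # cover the larger pool once per epoch, cycling the smaller one
            n_drive = len(sup_pool)
            if in_phase2 and lam > 0 and unl_pool:
                n_drive = max(n_drive, len(unl_pool))
            n_steps = int(np.ceil(n_drive / cfg.batch_size))
            for _step in range(n_steps):
                k_sup = min(cfg.batch_size, len(sup_pool))
                if s_cursor + k_sup > len(order):
                    order = order_rng.permutation(len(sup_pool))
                    s_cursor = 0
                sel = order[s_cursor:s_cursor + k_sup]
                s_cursor += k_sup
                batch = [sup_pool[i] for i in sel]
                Xs = np.concatenate([
                    strong_augment(s.clip, aug_rng_s, cfg.augment)
                    for s in batch], axis=0)
                Y = _onehot([s.label3 for s in batch])
                nl = len(batch)

                use_unl = in_phase2 and lam > 0 and len(unl_pool) > 0
                if use_unl:
                    k = min(cfg.batch_size, len(unl_pool))
                    if u_cursor + k > len(unl_order):
                        unl_order = order_rng.permutation(len(unl_pool))
                        u_cursor = 0
                    usel = unl_order[u_cursor:u_cursor + k]
                    u_cursor += k
                    ubatch = [unl_pool[i] for i in usel]
                    Xu_s = np.concatenate([
                        strong_augment(s.clip, aug_rng_s, cfg.augment)
                        for s in ubatch], axis=0)
                    Xu_t = np.concatenate([
                        weak_augment(s.clip, aug_rng_t, cfg.augment)
                        for s in ubatch], axis=0)
                    X = np.concatenate([Xs, Xu_s], axis=0)
                else:
                    X = Xs

                student.zero_grad()
                logits = student.forward(X)
                p = softmax(logits)
                p_sup = p[:nl]
                sup_loss = cross_entropy(p_sup, Y)
                dlogits = np.zeros_like(logits)
                dlogits[:nl] = (p_sup - Y) / nl

                cons = pseudo = 0.0
                if use_unl:
                    p_u = p[nl:]
                    teacher.eval()
                    p_t = softmax(teacher.forward(Xu_t))
                    cons = consistency_loss(p_u, p_t)
                    # d/dlogit of mean ||p_u - p_t||^2 through softmax
                    g = 2.0 * (p_u - p_t) / len(p_u)
                    dl_cons = p_u * (g - (g * p_u).sum(1, keepdims=True))
                    dlogits[nl:] += lam * dl_cons
                    if cfg.pseudo_ce:
                        recs = confidence_gate(p_t, cfg.tau)
                        acc_idx = [i for i, r in enumerate(recs) if r.accepted]
                        if acc_idx:
                            Yp = np.zeros_like(p_u)
                            for i in acc_idx:
                                Yp[i, recs[i].hard_label] = 1.0
                            pseudo = cross_entropy(
                                p_u[acc_idx], Yp[acc_idx])
                            dl_pce = np.zeros_like(p_u)
                            dl_pce[acc_idx] = (
                                p_u[acc_idx] - Yp[acc_idx]) / len(acc_idx)
                            dlogits[nl:] += lam * dl_pce

                student.backward(dlogits.astype(np.float32))
                opt.lr = state.lr
                opt.step(student.named_grads())
                ema_update(state.teacher_state(), state.student_state(),
                           cfg.alpha)
                sup_losses.append(sup_loss)
                cons_losses.append(cons)
                pseudo_losses.append(pseudo)

            n_promoted = 0
            if cfg.promote and in_phase2 and lam > 0 and unl_pool:
                p_t = self._predict_proba(teacher, unl_pool)
                recs = confidence_gate(p_t, cfg.tau, samples=unl_pool)
                sup_pool, unl_pool, n_promoted = promote_pseudo_labels(
                    recs, sup_pool, unl_pool)

            val_loss, val_acc = self._validate(student)
            entry = {
                "epoch": epoch,
                "lambda": lam,
                "lr": state.lr,
                "sup_loss": float(np.mean(sup_losses)),
                "cons_loss": float(np.mean(cons_losses)),
                "pseudo_loss": float(np.mean(pseudo_losses)),
                "val_loss": val_loss,
                "val_acc": val_acc,
                "n_promoted": n_promoted,
                "n_unlabeled": len(unl_pool),
            }
            history.append(entry)
            if log_fh:
                log_fh.write(json.dumps(entry) + "\n")
            if verbose:
                print(f"epoch {epoch:3d}  sup {entry['sup_loss']:.4f}  "
                      f"cons {entry['cons_loss']:.4f}  lam {lam:.2f}  "
                      f"val_acc {val_acc:.3f}")

            if self.val:
                if val_loss < best_val - 1e-6:
                    best_val = val_loss
                    best_state = student.state_dict()
                    best_epoch = epoch
                    stagnant_stop = stagnant_lr = 0
                else:
                    stagnant_stop += 1
                    stagnant_lr += 1
                    if stagnant_lr >= cfg.plateau_patience:
                        state.lr *= cfg.plateau_factor
                        stagnant_lr = 0
                    if stagnant_stop >= cfg.early_stop_patience:
                        break
            else:
                best_state = student.state_dict()
                best_epoch = epoch

        if log_fh:
            log_fh.close()
        return TrainingResults(
            model=self, state=state, history=history,
            best_state=best_state, best_epoch=best_epoch, seed=seed)


class TrainingResults:
    """Fitted-model container: networks, history, and summary statistics."""

    def __init__(self, model: MeanTeacherModel, state: TrainState,
                 history: list[dict], best_state: dict,
                 best_epoch: int, seed: int):
        self.model = model
        self.state = state
        self.history = history
        self.best_state = best_state
        self.best_epoch = best_epoch
        self.seed = seed
        # restore best-validation weights into a dedicated network
        self.student = GaitBackbone(model.backbone_config)
        self.student.load_state_dict(best_state)
        self.teacher = state.teacher

    def predict_proba(self, samples: list[GaitSample],
                      network: str = "student") -> np.ndarray:
        net = self.student if network == "student" else self.teacher
        return self.model._predict_proba(net, samples)

    def predict_label3(self, samples: list[GaitSample],
                       network: str = "student") -> list[int]:
        p = self.predict_proba(samples, network)
        return [LABELS3[i] for i in p.argmax(1)]

    def summary(self) -> str:
        cfg = self.model.config
        h = self.history
        lines = [
            "Mean Teacher training results",
            "=" * 46,
            f"{'epochs run':<28}{len(h):>18}",
            f"{'best validation epoch':<28}{self.best_epoch:>18}",
            f"{'seed':<28}{self.seed:>18}",
            f"{'labeled clips':<28}{len(self.model.labeled):>18}",
            f"{'unlabeled clips':<28}{len(self.model.unlabeled):>18}",
            f"{'EMA rate alpha':<28}{cfg.alpha:>18}",
            f"{'confidence threshold tau':<28}{cfg.tau:>18}",
            f"{'lambda ramp (epochs)':<28}{cfg.ramp_epochs:>18}",
        ]
        if h:
            lines += [
                f"{'final supervised loss':<28}{h[-1]['sup_loss']:>18.4f}",
                f"{'final consistency loss':<28}{h[-1]['cons_loss']:>18.4f}",
            ]
            if self.model.val:
                best = min(e["val_loss"] for e in h)
                acc = max(e["val_acc"] for e in h)
                lines += [
                    f"{'best validation loss':<28}{best:>18.4f}",
                    f"{'best validation accuracy':<28}{acc:>18.4f}",
                ]
            total_prom = sum(e["n_promoted"] for e in h)
            lines.append(f"{'pseudo-labels promoted':<28}{total_prom:>18}")
        lines.append("=" * 46)
        return "\n".join(lines)
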