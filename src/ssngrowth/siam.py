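"""Siamese growth-prediction model for paired nodule VOIs.

Two VOIs of the same nodule at consecutive time points pass through a
shared-weight 3D vision-transformer encoder.  Three embeddings are
produced: a global summary of the current VOI (FG_t), a local
nodule-centred summary of the current VOI (FL_t) and a local summary
of the prior VOI (FL_{t-1}); no global summary is ever computed for
the prior, since the surrounding anatomy is essentially unchanged
while the lesion itself is what evolves.  When no prior scan exists, a
learnable substitute vector stands in for FL_{t-1}.  A
spatial-temporal mixer (one token-mixing layer across the three
embeddings plus a channel MLP, with residuals and layer norm) fuses
them, and a linear head regresses the annualized relative mass growth
rate ``p``.

Training minimises the class-weighted smooth-L1 loss

    L = alpha * SmoothL1(p, y) * [y >= r] + SmoothL1(p, y) * [y < r]

which up-weights the scarce growing nodules (alpha = 3, r = 0.1) while
keeping the task a regression.  Decisions come from a sharpened
logistic map of p around an operating threshold ``th``:

    prob = 1 / (1 + exp(-(p - th) / tau)),   tau = 0.1

with prob >= 0.5 (equivalently p >= th) declaring growth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .nn.autodiff import Tensor, concat, gather_rows
from .nn.layers import LayerNorm, Linear, Module, PatchEncoder3D, patchify
from .nn.optim import AdamW, warmup_cosine_lr

__all__ = [
    "ModelConfig",
    "FeatureBundle",
    "ModelOutput",
    "SiamGrowthModel",
    "weighted_smooth_l1",
    "sharpen",
    "select_threshold",
    "train_model",
    "predict",
    "normalize_hu",
]

HU_WINDOW = (-1000.0, 400.0)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyper-parameters.

    Defaults follow the training recipe: alpha = 3 (best of the 1-5
    sweep), r = 0.1, AdamW with weight decay 0.05 and first-moment
    decay 0.9, batch 16, base lr 5e-4 warmed up over 5 epochs to
    lr * batch / 64 and cosine-annealed afterwards.  The "tiny"
    encoder (4 layers, 128 dims, 8^3-voxel patches on 32^3 VOIs) is a
    desk-scale stand-in for the full "vit-b" flag.
    """

    voi_size: int = 32
    patch_size: int = 8
    embed_dim: int = 128
    depth: int = 4
    heads: int = 4
    encoder: str = "tiny"
    alpha: float = 3.0
    r: float = 0.1
    beta: float = 1.0
    lr: float = 5e-4
    weight_decay: float = 0.05
    momentum_beta1: float = 0.9
    batch_size: int = 16
    epochs: int = 100
    warmup_epochs: int = 5
    tau: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.alpha < 1:
            raise ValueError("alpha must be >= 1")
        if self.r <= 0 or self.beta <= 0 or self.tau <= 0:
            raise ValueError("r, beta and tau must be positive")
        if self.voi_size % self.patch_size:
            raise ValueError("voi_size must divide by patch_size")

    @classmethod
    def vit_b(cls, **kw) -> "ModelConfig":
        """Full-scale configuration (ViT-B sized encoder)."""
        return cls(voi_size=64, patch_size=8, embed_dim=768, depth=12,
                   heads=12, encoder="vit-b", **kw)


@dataclass
class FeatureBundle:
    """The three fused embeddings (each (B, D))."""

    fg_t: Tensor
    fl_t: Tensor
    fl_prev: Tensor


@dataclass
class ModelOutput:
    """Prediction for one nodule."""

    p: float
    prob: float
    decision: bool


def normalize_hu(vol: np.ndarray) -> np.ndarray:
    """Clip HU to [-1000, 400] and scale linearly to [0, 1]."""
    lo, hi = HU_WINDOW
    return (np.clip(vol, lo, hi) - lo) / (hi - lo)


def weighted_smooth_l1(p, y, alpha: float = 3.0, r: float = 0.1,
                       beta: float = 1.0):
    """Class-weighted smooth-L1 between predicted and true growth rate.

    Accepts numpy arrays (returns an array) or autodiff Tensors
    (returns a Tensor for backprop).  The smooth-L1 base is quadratic
    within ``beta`` of zero residual and linear outside; samples whose
    true rate meets the indicator cutoff ``y >= r`` are weighted by
    ``alpha``.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    if isinstance(p, Tensor):
        dt = p.data.dtype
        yv = y.data if isinstance(y, Tensor) else np.asarray(y, float)
        d = p - Tensor(yv.astype(dt))
        absd = np.abs(d.data)
        quad = absd < beta
        # piecewise base via masks; masks are constants w.r.t. p
        base = (d * d) * (0.5 / beta) * Tensor(quad.astype(dt)) \
            + (Tensor(np.sign(d.data)) * d - beta / 2.0) * Tensor((~quad).astype(dt))
        w = np.where(yv >= r, alpha, 1.0).astype(dt)
        return base * Tensor(w)
    p = np.asarray(p, float)
    y = np.asarray(y, float)
    d = np.abs(p - y)
    base = np.where(d < beta, 0.5 * d * d / beta, d - beta / 2.0)
    return np.where(y >= r, alpha, 1.0) * base


def sharpen(p, th: float, tau: float = 0.1):
    """Map raw output p to a growth probability via a sharpened logistic."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    from scipy.special import expit

    p = np.asarray(p, float)
    out = expit((p - th) / tau)
    return float(out) if out.ndim == 0 else out


def select_threshold(val_outputs, val_labels) -> float:
    """Operating threshold maximising Youden's J on validation outputs.

    Candidates are midpoints between consecutive sorted unique scores
    plus one candidate below the minimum and one above the maximum;
    ties in J resolve toward the smaller threshold.
    """
    scores = np.asarray(val_outputs, float)
    y = np.asarray(val_labels).astype(int)
    if y.min() == y.max():
        raise ValueError("validation labels contain a single class")
    u = np.unique(scores)
    cands = np.concatenate([[u[0] - 1.0], (u[:-1] + u[1:]) / 2.0, [u[-1] + 1.0]])
    npos, nneg = y.sum(), (1 - y).sum()
    best_th, best_j = cands[0], -np.inf
    for th in cands:
        pred = scores >= th
        j = (pred & (y == 1)).sum() / npos + (~pred & (y == 0)).sum() / nneg - 1.0
        if j > best_j + 1e-12:
            best_j, best_th = j, th
    return float(best_th)


class SiamGrowthModel(Module):
    """Shared-weight Siamese encoder + spatial-temporal mixer + head."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.encoder = PatchEncoder3D(cfg.voi_size, cfg.patch_size,
                                      cfg.embed_dim, cfg.depth, cfg.heads, rng)
        d = cfg.embed_dim
        # learnable substitute for the missing prior local embedding
        self.fl_substitute = Tensor(
            rng.normal(0, 0.02, size=(1, d)).astype(np.float32),
            requires_grad=True)
        # spatial-temporal mixer: token mixing across the 3 embeddings,
        # then channel mixing, both residual with layer norm
        self.ln_tok = LayerNorm(d)
        self.tok_mix = Linear(3, 3, rng)
        self.ln_ch = LayerNorm(d)
        self.ch_fc1 = Linear(d, 2 * d, rng)
        self.ch_fc2 = Linear(2 * d, d, rng)
        self.ln_out = LayerNorm(d)
        self.head = Linear(3 * d, 1, rng)

    # -- encoding ------------------------------------------------------
    def _patch(self, vols: np.ndarray) -> Tensor:
        return Tensor(patchify(normalize_hu(vols), self.cfg.patch_size)
                      .astype(np.float32))

    def encode_pair(self, current: np.ndarray,
                    prior: np.ndarray | None = None,
                    prior_present: np.ndarray | None = None,
                    pre_patched: bool = False) -> FeatureBundle:
        """Embed a batch of (prior, current) VOIs.

        ``current``: (B, S, S, S) HU volumes (or pre-patchified
        (B, T, P) with ``pre_patched=True``).  ``prior`` may be None
        (all missing), or a batch aligned with ``prior_present`` (a
        boolean vector marking which rows have a real prior).  Rows
        without a prior receive the learnable substitute embedding.
        """
        cur_tok = Tensor(current) if pre_patched else self._patch(current)
        tokens = self.encoder(cur_tok)
        fg_t = self.encoder.global_embedding(tokens)
        fl_t = self.encoder.local_embedding(tokens)
        B = cur_tok.shape[0]

        if prior is None:
            ones = Tensor(np.ones((B, 1), dtype=np.float32))
            fl_prev = ones @ self.fl_substitute
        else:
            prior_tok = Tensor(prior) if pre_patched else self._patch(prior)
            present = np.ones(B, bool) if prior_present is None \
                else np.asarray(prior_present, bool)
            if prior_tok.shape[0] != int(present.sum()):
                raise ValueError("prior batch must contain exactly the rows "
                                 "flagged present")
            if present.all():
                fl_prev = self.encoder.local_embedding(self.encoder(prior_tok))
            else:
                fl_real = self.encoder.local_embedding(self.encoder(prior_tok))
                n_miss = int((~present).sum())
                ones = Tensor(np.ones((n_miss, 1), dtype=np.float32))
                fl_miss = ones @ self.fl_substitute
                stacked = concat([fl_real, fl_miss], axis=0)
                order = np.concatenate([np.nonzero(present)[0],
                                        np.nonzero(~present)[0]])
                fl_prev = gather_rows(stacked, np.argsort(order))
        return FeatureBundle(fg_t=fg_t, fl_t=fl_t, fl_prev=fl_prev)

    # -- fusion + head -------------------------------------------------
    def fuse_and_predict(self, bundle: FeatureBundle) -> Tensor:
        """STM fusion of the three embeddings, then the scalar head."""
        B, D = bundle.fg_t.shape
        toks = concat([b.reshape(B, 1, D) for b in
                       (bundle.fg_t, bundle.fl_t, bundle.fl_prev)], axis=1)
        # token mixing: linear map across the 3-token axis
        tm = self.ln_tok(toks).transpose(0, 2, 1)  # (B, D, 3)
        tm = self.tok_mix(tm).transpose(0, 2, 1)
        x = toks + tm
        x = x + self.ch_fc2(self.ch_fc1(self.ln_ch(x)).gelu())
        x = self.ln_out(x).reshape(B, 3 * D)
        return self.head(x).reshape(B)

    def forward(self, current, prior=None, prior_present=None,
                pre_patched=False) -> Tensor:
        return self.fuse_and_predict(self.encode_pair(
            current, prior, prior_present, pre_patched))

    # -- inference -----------------------------------------------------
    def predict_rates(self, current, prior=None, prior_present=None,
                      pre_patched=False, batch_size: int = 32) -> np.ndarray:
        """Predicted growth rates p for a dataset, batched, no grad."""
        cur = np.asarray(current)
        n = cur.shape[0]
        present = np.zeros(n, bool) if prior is None else (
            np.ones(n, bool) if prior_present is None
            else np.asarray(prior_present, bool))
        prior_rows = None if prior is None else np.asarray(prior)
        out = np.empty(n)
        pos_of_present = {i: k for k, i in enumerate(np.nonzero(present)[0])}
        for s in range(0, n, batch_size):
            sl = np.arange(s, min(s + batch_size, n))
            pres = present[sl]
            pr = None
            if prior_rows is not None and pres.any():
                rows = [pos_of_present[i] for i in sl[pres]]
                pr = prior_rows[rows]
            elif prior_rows is not None:
                pres = np.zeros(sl.size, bool)
            out[sl] = self.forward(cur[sl], pr,
                                   pres if pr is not None else None,
                                   pre_patched).data
        return out

    def predict_pair(self, pair, th: float) -> ModelOutput:
        """Predict growth for one :class:`~ssngrowth.pairing.ExamPair`.

        Uses the nodule-centred VOIs directly (they must match the
        configured VOI size); a missing prior routes through the
        learnable substitute embedding.
        """
        cur = pair.current[0].values[None]
        pri = pair.prior[0].values[None] if pair.prior is not None else None
        return self.predict_outputs(cur, th, pri)[0]

    def predict_outputs(self, current, th: float, prior=None,
                        prior_present=None, pre_patched=False) -> list[ModelOutput]:
        p = self.predict_rates(current, prior, prior_present, pre_patched)
        prob = sharpen(p, th, self.cfg.tau)
        return [ModelOutput(float(pi), float(pr), bool(pr >= 0.5))
                for pi, pr in zip(p, np.atleast_1d(prob))]

    # -- persistence ---------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.state_dict())
        path.with_suffix(".json").write_text(
            json.dumps({"config": asdict(self.cfg)}, indent=2))

    @classmethod
    def load(cls, path) -> "SiamGrowthModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(ModelConfig(**meta["config"]))
        with np.load(path.with_suffix(".npz")) as z:
            model.load_state_dict({k: z[k] for k in z.files})
        return model


def train_model(model: SiamGrowthModel, current: np.ndarray,
                y: np.ndarray, prior: np.ndarray | None = None,
                prior_present: np.ndarray | None = None,
                epochs: int | None = None, pre_patched: bool = False,
                verbose: bool = False) -> dict:
    """Train with AdamW under the warmup + cosine schedule.

    ``current`` (and ``prior`` where present) are HU volumes (B,S,S,S)
    or pre-patchified token arrays; ``y`` is the annualized relative
    mass growth rate.  Returns a history dict with per-epoch mean loss
    and the learning-rate trace.  Deterministic for a fixed config
    seed.
    """
    cfg = model.cfg
    n = np.asarray(current).shape[0]
    if n == 0:
        raise ValueError("empty training set")
    y = np.asarray(y, float)
    epochs = cfg.epochs if epochs is None else epochs
    cur = np.asarray(current)
    if not pre_patched:
        cur = patchify(normalize_hu(cur), cfg.patch_size).astype(np.float32)
    present = np.zeros(n, bool) if prior is None else (
        np.ones(n, bool) if prior_present is None
        else np.asarray(prior_present, bool))
    pri = None
    if prior is not None:
        pri = np.asarray(prior)
        if not pre_patched:
            pri = patchify(normalize_hu(pri), cfg.patch_size).astype(np.float32)
    pos_of_present = {i: k for k, i in enumerate(np.nonzero(present)[0])}

    opt = AdamW(model.parameters(), lr=cfg.lr,
                betas=(cfg.momentum_beta1, 0.999),
                weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed + 1)
    steps_per_epoch = max(1, int(np.ceil(n / cfg.batch_size)))
    history = {"loss": [], "lr": []}
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for si in range(steps_per_epoch):
            frac_epoch = epoch + si / steps_per_epoch
            opt.lr = warmup_cosine_lr(
                frac_epoch, base_lr=cfg.lr, batch_size=cfg.batch_size,
                epochs=epochs, warmup_epochs=cfg.warmup_epochs)
            sl = order[si * cfg.batch_size:(si + 1) * cfg.batch_size]
            pres = present[sl]
            pr = None
            if pri is not None and pres.any():
                pr = pri[[pos_of_present[i] for i in sl[pres]]]
            p = model.forward(cur[sl], pr,
                              pres if pr is not None else None,
                              pre_patched=True)
            loss = weighted_smooth_l1(p, y[sl], cfg.alpha, cfg.r,
                                      cfg.beta).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history["loss"].append(float(np.mean(losses)))
        history["lr"].append(opt.lr)
        if verbose:
            print(f"epoch {epoch + 1}/{epochs} loss {history['loss'][-1]:.4f} "
                  f"lr {opt.lr:.2e}")
    return history


def predict(model: SiamGrowthModel, current, th: float, prior=None,
            prior_present=None) -> list[ModelOutput]:
    """Convenience wrapper: rates -> sharpened probabilities -> decisions."""
    return model.predict_outputs(current, th, prior, prior_present)
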