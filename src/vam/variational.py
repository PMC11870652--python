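"""Stochastic variational inference for the image-computable accumulator.

The generative model couples a convolutional encoder (drift means
``v = CNN(s)``) with the LBA likelihood and a standard-normal prior over the
LBA parameters ``theta = (b, A, t0)``.  The approximate posterior over the
transformed parameters ``theta* = T(theta)`` is a full-covariance Gaussian
``q(theta*) = N(mu, L L')`` parameterized by its Cholesky factor.  Fitting
maximizes a Monte-Carlo estimate of the evidence lower bound with the
reparameterization trick, ``theta* = L eps + mu``; each datapoint uses its
own independent draws of ``eps``.  The per-datapoint objective is

``(1/L) sum_l [ log p(rt, c | v, T^-1(theta*)) + log N(T^-1(theta*); 0, I)
               + log|det J_{T^-1}| - log q(theta*) ]``

with the batch estimate the mean over datapoints.  The joint density
contains a single prior for the whole dataset, so by default the prior,
Jacobian and entropy terms are split evenly across datapoints
(``prior_weight = 1/N_train``); attaching the full terms to every datapoint
(``prior_mode="per_datapoint"``) is exposed for comparison but tempers the
prior by the dataset size and visibly biases parameter recovery.

Gradients are analytic throughout.  Because ``theta*`` is an affine function
of ``eps``, the per-sample entropy term reduces to
``(3/2) log 2 pi + log|det L| + ||eps||^2 / 2``: its total derivative with
respect to ``mu`` vanishes and with respect to ``L`` is ``diag(1/L_ii)``, so
the ELBO gradient is the expectation of the model-term gradient pushed
through the reparameterization, plus that diagonal correction.  The encoder
receives ``d ELBO / d v`` and backpropagates it itself.  Both the gradient
path and the estimator are validated against finite differences and an
adaptive-quadrature evidence bound in the test suite.

The Adam optimizer and the training loops for the generative (ELBO) and
task-optimized (cross-entropy) objectives live here too.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from . import encoder as enc
from .lba import (
    LBAParams,
    TransformedParams,
    inverse_transform,
    loglik_grads_batch,
    sample_trials,
    transform_params,
)

__all__ = [
    "PosteriorGaussian",
    "FitConfig",
    "reparameterize",
    "gaussian_logq",
    "elbo_estimate",
    "elbo_with_grads",
    "Adam",
    "fit_vam",
    "fit_task_optimized",
    "cross_entropy",
    "map_estimate",
    "sample_model_behavior",
    "steps_per_epoch",
    "total_steps",
    "TrainingLog",
]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class PosteriorGaussian:
    """Gaussian variational posterior over transformed LBA parameters.

    ``mu`` is the mean of ``q`` over ``theta* = (b*, A*, t0*)``; ``L_chol``
    is the lower-triangular Cholesky factor of the covariance with strictly
    positive diagonal, so ``Sigma = L L'`` is symmetric positive definite by
    construction.
    """

    mu: np.ndarray
    L_chol: np.ndarray

    def __post_init__(self):
        mu = np.asarray(self.mu, dtype=float)
        L = np.asarray(self.L_chol, dtype=float)
        if mu.shape != (3,) or L.shape != (3, 3):
            raise ValueError("mu must be (3,), L_chol (3, 3)")
        if not (np.allclose(L, np.tril(L)) and np.all(np.diag(L) > 0)):
            raise ValueError("L_chol must be lower-triangular with positive diagonal")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "L_chol", L)

    @property
    def cov(self) -> np.ndarray:
        return self.L_chol @ self.L_chol.T

    def to_dict(self) -> dict:
        return {"mu": self.mu.tolist(), "L_chol": self.L_chol.tolist()}

    @classmethod
    def from_dict(cls, d) -> "PosteriorGaussian":
        return cls(np.asarray(d["mu"]), np.asarray(d["L_chol"]))


def reparameterize(mu, L_chol, eps) -> np.ndarray:
    """``theta* = L eps + mu`` for standard-normal draws ``eps`` (..., 3)."""
    return np.asarray(eps) @ np.asarray(L_chol).T + np.asarray(mu)


def gaussian_logq(theta_star, mu, L_chol):
    """Log density of N(mu, L L') at ``theta_star`` (..., 3), via the factor."""
    L = np.asarray(L_chol, dtype=float)
    diag = np.diag(L)
    if np.any(diag <= 0):
        raise ValueError("Cholesky factor must have positive diagonal")
    dev = np.asarray(theta_star, dtype=float) - np.asarray(mu, dtype=float)
    z = solve_triangular(L, dev.reshape(-1, 3).T, lower=True).T
    quad = (z * z).sum(axis=1)
    out = -1.5 * _LOG2PI - np.log(diag).sum() - 0.5 * quad
    return out.reshape(np.asarray(theta_star).shape[:-1]) if np.asarray(
        theta_star).ndim > 1 else float(out[0])


def _default_loglik(rts, choices, v, b, A, t0):
    return loglik_grads_batch(rts, choices, v, b, A, t0)


def _elbo_core(rts, choices, v, mu, L_chol, eps, loglik_fn=None,
               prior_weight=1.0):
    """Per-datapoint ELBO estimates and analytic gradients.

    ``eps``: (n, L, 3) frozen standard-normal draws.  Returns
    ``(elbo_i (n,), d_mu (3,), d_L (3,3), d_v (n, 4))`` where the gradients
    are of the batch-mean ELBO.
    """
    if loglik_fn is None:
        loglik_fn = _default_loglik
    rts = np.asarray(rts, dtype=float)
    choices = np.asarray(choices, dtype=int)
    v = np.atleast_2d(np.asarray(v, dtype=float))
    n, n_mc = eps.shape[0], eps.shape[1]
    if n == 0:
        raise ValueError("empty batch")
    theta_star = reparameterize(mu, L_chol, eps)           # (n, L, 3)
    eb = np.exp(theta_star[..., 0])                        # b - A
    A = np.exp(theta_star[..., 1])
    t0 = np.exp(theta_star[..., 2])
    b = eb + A
    ll, d_v_s, d_b, d_A, d_t0 = loglik_fn(rts, choices, v, b, A, t0)
    # prior N(theta; 0, I) on the natural scale
    logprior = -1.5 * _LOG2PI - 0.5 * (b * b + A * A + t0 * t0)
    logjac = theta_star.sum(axis=-1)
    logq = gaussian_logq(theta_star, mu, L_chol)
    w = prior_weight
    elbo_i = (ll + w * (logprior + logjac - logq)).mean(axis=1)
    # gradient of (loglik + w*(prior + jac)) wrt theta*, chained through T^-1
    g = np.empty_like(theta_star)
    g[..., 0] = eb * (d_b - w * b) + w
    g[..., 1] = A * (d_A + d_b - w * (b + A)) + w
    g[..., 2] = t0 * (d_t0 - w * t0) + w
    scale = 1.0 / (n * n_mc)
    d_mu = g.sum(axis=(0, 1)) * scale
    d_L = np.einsum("nli,nlj->ij", g, eps) * scale
    d_L += w * np.diag(1.0 / np.diag(L_chol))              # entropy term
    d_L = np.tril(d_L)
    d_v = d_v_s.mean(axis=1)
    return elbo_i, d_mu, d_L, d_v


def elbo_estimate(rts, choices, v, mu, L_chol, n_samples=10, seed=None,
                  rng=None, eps=None, loglik_fn=None, prior_weight=1.0):
    """Monte-Carlo ELBO estimate for a batch (mean over datapoints).

    Each datapoint gets its own ``n_samples`` independent draws of ``eps``
    (pass ``eps`` with shape (n, n_samples, 3) to freeze them).
    Deterministic given the seed.
    """
    rts = np.atleast_1d(np.asarray(rts, dtype=float))
    if eps is None:
        if rng is None:
            rng = np.random.default_rng(seed)
        eps = rng.standard_normal((rts.shape[0], n_samples, 3))
    elbo_i, *_ = _elbo_core(rts, choices, v, mu, L_chol, eps,
                            loglik_fn=loglik_fn, prior_weight=prior_weight)
    return float(elbo_i.mean())


def elbo_with_grads(rts, choices, v, mu, L_chol, eps, loglik_fn=None,
                    prior_weight=1.0):
    """ELBO estimate plus analytic gradients wrt (mu, L) and the drift means.

    Returns ``(elbo, d_mu, d_L, d_v)``; gradients are of the batch-mean
    estimator with the given frozen ``eps`` draws, so they match finite
    differences of :func:`elbo_estimate` exactly.
    """
    rts = np.atleast_1d(np.asarray(rts, dtype=float))
    elbo_i, d_mu, d_L, d_v = _elbo_core(rts, choices, v, mu, L_chol, eps,
                                        loglik_fn=loglik_fn,
                                        prior_weight=prior_weight)
    return float(elbo_i.mean()), d_mu, d_L, d_v


class Adam:
    """Adam over a flat dict of arrays (minimizes: pass negative gradients
    to ascend)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(p) for k, p in params.items()}
        self.v = {k: np.zeros_like(p) for k, p in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] = params[k] - self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps)
        return params


@dataclass(frozen=True)
class FitConfig:
    """Training configuration shared by the ELBO and cross-entropy fits.

    Defaults follow the reference recipe: minibatch 256, 10 MC samples per
    datapoint, Adam(1e-3, 0.9, 0.999).  The posterior is initialized at
    ``T(b=1.5, A=0.75, t0=0.3)`` with ``L = 0.1 I`` (the non-decision mean
    is clamped below the fastest observed RT if necessary).  ``epochs`` is a
    fixed budget; optional early stopping on validation ELBO is off by
    default.
    """

    epochs: int = 200
    batch_size: int = 256
    mc_samples: int = 10
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    seed: int = 0
    init_params: LBAParams = field(
        default_factory=lambda: LBAParams(b=1.5, A=0.75, t0=0.3))
    init_scale: float = 0.1
    augment: bool = True
    augment_cfg: enc.AugmentConfig = field(default_factory=enc.AugmentConfig)
    prior_mode: str = "scaled"
    early_stop: bool = False
    early_stop_patience: int = 10

    def __post_init__(self):
        if self.batch_size < 1 or self.mc_samples < 1:
            raise ValueError("batch_size and mc_samples must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.prior_mode not in ("scaled", "per_datapoint"):
            raise ValueError("prior_mode must be 'scaled' or 'per_datapoint'")


def steps_per_epoch(n_train: int, batch_size: int) -> int:
    """Optimizer steps per epoch: ceil(n_train / batch_size)."""
    return -(-int(n_train) // int(batch_size))


def total_steps(epochs: int, n_train: int, batch_size: int) -> int:
    """Total optimizer steps over a fixed epoch budget."""
    return int(epochs) * steps_per_epoch(n_train, batch_size)


@dataclass
class TrainingLog:
    """Per-epoch training history."""

    frame: pd.DataFrame

    def to_csv(self, path):
        self.frame.to_csv(path, index=False)


class _BiasEncoder:
    """Degenerate encoder: a single trainable drift 4-vector, images ignored.

    Used for pure LBA posterior fits (parameter-recovery studies) where the
    stimulus carries no information.
    """

    def __init__(self, init=np.zeros(4)):
        self.cfg = None

    @staticmethod
    def init_params(seed=0):
        return {"bias": np.zeros(4)}

    @staticmethod
    def forward(n, params):
        return np.broadcast_to(params["bias"], (n, 4)).copy()

    @staticmethod
    def backward(d_v):
        return {"bias": d_v.sum(axis=0)}


def _posterior_phi(cfg: FitConfig, rts):
    p0 = cfg.init_params
    min_rt = float(np.min(rts))
    if p0.t0 >= min_rt:
        p0 = LBAParams(p0.b, p0.A, 0.8 * min_rt, p0.s)
        warnings.warn(
            f"initial t0 >= fastest RT; clamped to {p0.t0:.4f}")
    mu0 = transform_params(p0).as_array()
    return {
        "mu": mu0,
        "log_diag": np.full(3, np.log(cfg.init_scale)),
        "offdiag": np.zeros(3),
    }


def _build_L(phi):
    L = np.zeros((3, 3))
    L[np.diag_indices(3)] = np.exp(phi["log_diag"])
    L[1, 0], L[2, 0], L[2, 1] = phi["offdiag"]
    return L


def _chol_grads(d_L, phi):
    """Map a gradient on L to the (log_diag, offdiag) parameterization."""
    return {
        "log_diag": np.diag(d_L) * np.exp(phi["log_diag"]),
        "offdiag": np.array([d_L[1, 0], d_L[2, 0], d_L[2, 1]]),
    }


def _epoch_batches(idx, batch_size, rng):
    perm = rng.permutation(idx)
    for lo in range(0, perm.shape[0], batch_size):
        yield perm[lo:lo + batch_size]


def fit_vam(images, rts, choices, train_idx, val_idx=None,
            encoder_cfg: enc.EncoderConfig | None = None,
            cfg: FitConfig = FitConfig(), encoder_kind="cnn",
            callback=None):
    """Jointly fit the variational posterior and the encoder by ELBO ascent.

    Per step: minibatch -> (augmented) images -> drift means -> fresh
    ``eps`` draws -> reparameterized MC ELBO -> analytic gradients wrt
    ``(mu, L)`` and backpropagated encoder gradients -> one Adam update of
    everything.  Fully deterministic given ``cfg.seed``.

    Parameters
    ----------
    images : (N, H, W, 3) array or None
        May be None with ``encoder_kind="bias"``.
    rts, choices : (N,) arrays
    train_idx, val_idx : index arrays
    encoder_cfg : EncoderConfig (required for the CNN encoder)
    encoder_kind : "cnn" or "bias"
        "bias" replaces the network with a single trainable drift 4-vector.

    Returns
    -------
    (PosteriorGaussian, params dict, TrainingLog, diagnostics dict)
    """
    rts = np.asarray(rts, dtype=float)
    choices = np.asarray(choices, dtype=int)
    train_idx = np.asarray(train_idx)
    ss = np.random.SeedSequence(cfg.seed)
    r_shuffle, r_eps, r_drop, r_aug = (np.random.default_rng(s)
                                       for s in ss.spawn(4))
    phi = _posterior_phi(cfg, rts[train_idx])
    if encoder_kind == "bias":
        zeta = _BiasEncoder.init_params()
    elif encoder_kind == "cnn":
        if encoder_cfg is None:
            raise ValueError("encoder_cfg required for the CNN encoder")
        zeta = enc.init_params(encoder_cfg, seed=cfg.seed)
    else:
        raise ValueError("encoder_kind must be 'cnn' or 'bias'")
    opt = Adam({**phi, **zeta}, lr=cfg.lr, beta1=cfg.beta1, beta2=cfg.beta2)
    # "scaled": one prior/Jacobian/entropy term for the whole training set
    # (the full-dataset bound, split evenly across datapoints);
    # "per_datapoint": those terms attached to every datapoint.
    w_prior = 1.0 / len(train_idx) if cfg.prior_mode == "scaled" else 1.0
    rows = []
    best_val, patience = -np.inf, 0
    for epoch in range(cfg.epochs):
        epoch_elbos = []
        for batch in _epoch_batches(train_idx, cfg.batch_size, r_shuffle):
            mu, L = phi["mu"], _build_L(phi)
            if encoder_kind == "bias":
                v = _BiasEncoder.forward(batch.shape[0], zeta)
                cache = None
            else:
                imgs = images[batch]
                if cfg.augment:
                    imgs = enc.augment_batch(imgs, rng=r_aug,
                                             cfg=cfg.augment_cfg)
                v, cache = enc.forward(imgs, zeta, encoder_cfg, mode="train",
                                       rng=r_drop, return_cache=True)
            eps = r_eps.standard_normal((batch.shape[0], cfg.mc_samples, 3))
            elbo, d_mu, d_L, d_v = elbo_with_grads(
                rts[batch], choices[batch], v, mu, L, eps,
                prior_weight=w_prior)
            if not np.isfinite(elbo):
                bad = int(batch[np.argmin(np.isfinite(
                    rts[batch]).astype(int))]) if batch.size else -1
                raise RuntimeError(
                    f"non-finite ELBO in epoch {epoch}; first trial index in "
                    f"the offending batch: {int(batch[0])} (suspect {bad})")
            grads = {"mu": -d_mu, **{k: -g for k, g in
                                     _chol_grads(d_L, phi).items()}}
            if encoder_kind == "bias":
                grads.update({k: -g for k, g in
                              _BiasEncoder.backward(d_v).items()})
            else:
                grads.update({k: -g for k, g in
                              enc.backward(d_v, zeta, encoder_cfg,
                                           cache).items()})
            merged = {**phi, **zeta}
            merged = opt.step(merged, grads)
            phi = {k: merged[k] for k in ("mu", "log_diag", "offdiag")}
            zeta = {k: merged[k] for k in zeta}
            epoch_elbos.append(elbo)
        row = {"epoch": epoch, "train_elbo": float(np.mean(epoch_elbos)),
               "val_elbo": np.nan, "val_accuracy": np.nan}
        if val_idx is not None and len(val_idx) > 0:
            mu, L = phi["mu"], _build_L(phi)
            if encoder_kind == "bias":
                v_val = _BiasEncoder.forward(len(val_idx), zeta)
            else:
                v_val = enc.forward(images[np.asarray(val_idx)], zeta,
                                    encoder_cfg, mode="eval")
            row["val_elbo"] = elbo_estimate(
                rts[np.asarray(val_idx)], choices[np.asarray(val_idx)],
                v_val, mu, L, n_samples=cfg.mc_samples, rng=r_eps,
                prior_weight=w_prior)
            row["val_accuracy"] = float(
                np.mean(np.argmax(v_val, axis=1) + 1
                        == choices[np.asarray(val_idx)]))
        rows.append(row)
        if callback is not None:
            callback(epoch, row)
        if cfg.early_stop and np.isfinite(row["val_elbo"]):
            if row["val_elbo"] > best_val:
                best_val, patience = row["val_elbo"], 0
            else:
                patience += 1
                if patience >= cfg.early_stop_patience:
                    break
    post = PosteriorGaussian(phi["mu"].copy(), _build_L(phi))
    log = TrainingLog(pd.DataFrame(rows))
    diagnostics = _fit_diagnostics(post, zeta, encoder_cfg, encoder_kind,
                                   images, rts, choices, val_idx, cfg)
    return post, zeta, log, diagnostics


def _fit_diagnostics(post, zeta, encoder_cfg, encoder_kind, images, rts,
                     choices, val_idx, cfg):
    """Failed-run detectors: chance accuracy, runaway negative drifts."""
    idx = np.asarray(val_idx) if val_idx is not None and len(val_idx) else \
        np.arange(min(512, len(rts)))
    if encoder_kind == "bias":
        v = _BiasEncoder.forward(len(idx), zeta)
    else:
        v = enc.forward(images[idx], zeta, encoder_cfg, mode="eval")
    p = map_estimate(post)
    rts_s, ch_s, valid = sample_trials(v, p, seed=cfg.seed + 1)
    match = float(np.mean(ch_s[valid] == choices[idx][valid])) if \
        valid.any() else 0.0
    neg_frac = float(np.mean(~valid))
    return {
        "sim_choice_agreement": match,
        "negative_drift_fraction": neg_frac,
        "chance_accuracy_flag": bool(match <= 0.30),
        "negative_drift_flag": bool(neg_frac > 0.50),
    }


def softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits, labels):
    """Mean softmax cross-entropy and its logits gradient.

    Uniform logits give the 4-class chance loss log 4; the gradient is
    ``(softmax - onehot) / n``.
    """
    logits = np.atleast_2d(np.asarray(logits, dtype=float))
    labels = np.asarray(labels, dtype=int)
    n, k = logits.shape
    p = softmax(logits)
    loss = -np.mean(np.log(np.clip(p[np.arange(n), labels], 1e-300, None)))
    grad = (p - np.eye(k)[labels]) / n
    return float(loss), grad


def fit_task_optimized(images, labels, train_idx, val_idx=None,
                       encoder_cfg: enc.EncoderConfig | None = None,
                       cfg: FitConfig = FitConfig(), callback=None):
    """Train the logits-head encoder with softmax cross-entropy.

    ``labels`` are true target directions (0..3).  Architecture, optimizer,
    initialization and augmentation are identical to the generative fit;
    only the loss differs.  Returns ``(params, TrainingLog)``.
    """
    labels = np.asarray(labels, dtype=int)
    train_idx = np.asarray(train_idx)
    if encoder_cfg is None:
        raise ValueError("encoder_cfg is required")
    ss = np.random.SeedSequence(cfg.seed)
    r_shuffle, _, r_drop, r_aug = (np.random.default_rng(s)
                                   for s in ss.spawn(4))
    zeta = enc.init_params(encoder_cfg, seed=cfg.seed)
    opt = Adam(zeta, lr=cfg.lr, beta1=cfg.beta1, beta2=cfg.beta2)
    rows = []
    for epoch in range(cfg.epochs):
        losses, accs = [], []
        for batch in _epoch_batches(train_idx, cfg.batch_size, r_shuffle):
            imgs = images[batch]
            if cfg.augment:
                imgs = enc.augment_batch(imgs, rng=r_aug, cfg=cfg.augment_cfg)
            logits, cache = enc.forward(imgs, zeta, encoder_cfg, mode="train",
                                        rng=r_drop, return_cache=True)
            loss, d_logits = cross_entropy(logits, labels[batch])
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite loss in epoch {epoch}")
            grads = enc.backward(d_logits, zeta, encoder_cfg, cache)
            zeta = opt.step(zeta, grads)
            losses.append(loss)
            accs.append(np.mean(np.argmax(logits, axis=1) == labels[batch]))
        row = {"epoch": epoch, "train_loss": float(np.mean(losses)),
               "train_accuracy": float(np.mean(accs)),
               "val_accuracy": np.nan}
        if val_idx is not None and len(val_idx) > 0:
            lv = enc.forward(images[np.asarray(val_idx)], zeta, encoder_cfg,
                             mode="eval")
            row["val_accuracy"] = float(np.mean(
                np.argmax(lv, axis=1) == labels[np.asarray(val_idx)]))
        rows.append(row)
        if callback is not None:
            callback(epoch, row)
    return zeta, TrainingLog(pd.DataFrame(rows))


def map_estimate(post: PosteriorGaussian) -> LBAParams:
    """MAP-style point estimate: ``T^-1`` of the posterior mean."""
    return inverse_transform(TransformedParams.from_array(post.mu))


def sample_model_behavior(post: PosteriorGaussian, zeta, encoder_cfg,
                          images, seed=None, rng=None):
    """Simulate RTs/choices from a fitted model on probe images.

    Drift means come from the eval-mode encoder; trials are sampled from the
    LBA at the MAP parameters.  Trials on which all four sampled drifts were
    non-positive are excluded; their fraction is reported.

    Returns ``(rts, choices, valid_mask, excluded_fraction, drift_means)``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if isinstance(zeta, dict) and "bias" in zeta:
        v = _BiasEncoder.forward(np.asarray(images).shape[0], zeta)
    else:
        v = enc.forward(images, zeta, encoder_cfg, mode="eval")
    p = map_estimate(post)
    rts, choices, valid = sample_trials(v, p, rng=rng)
    return rts, choices, valid, float(np.mean(~valid)), v
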