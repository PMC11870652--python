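"""Linear ballistic accumulator (LBA): transforms, likelihood, gradients, sampler.

The LBA is a race model for N-alternative speeded choice.  On each trial,
evidence for response ``k`` grows linearly at rate ``d_k ~ N(v_k, s^2)`` from a
start point drawn uniformly on ``[0, A]``; the first accumulator to reach the
threshold ``b`` determines the choice, and the response time is the winning
accumulator's crossing time plus a constant non-decision time ``t0``.  The
drift SD ``s`` is fixed to 1 so the remaining parameters are identifiable.

The defective density of (rt, choice) has the classic closed form built from
the marginal first-passage CDF/PDF of a single accumulator
(:func:`accumulator_cdf`, :func:`accumulator_pdf`).  Because drift draws can
all be negative, the density integrates to less than one; trials on which no
accumulator ever finishes are treated as undefined and excluded, with no
renormalization of the likelihood.

Parameters are optimized on the unconstrained scale
``theta* = (log(b - A), log A, log t0)``; :func:`transform_params` /
:func:`inverse_transform` map between the scales and :func:`log_jacobian`
gives the log |det J| of the inverse map needed for change-of-variables.

All likelihood routines are vectorized over trials, and
:func:`trial_loglik_grads` returns analytic gradients with respect to the
per-trial drift means and the transformed parameters (the formulas simplify
considerably after cancellation; they are validated against finite
differences in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.special import ndtr

__all__ = [
    "LBAParams",
    "TransformedParams",
    "transform_params",
    "inverse_transform",
    "log_jacobian",
    "accumulator_cdf",
    "accumulator_pdf",
    "trial_loglik",
    "trial_loglik_grads",
    "sample_trials",
]

# numerical guards (see docs/methods.md)
_DENSITY_FLOOR = 1e-300
_CDF_CEIL = 1.0 - 1e-12
_A_LIMIT = 1e-6  # below this, use the point-start (A -> 0) limiting forms

_SQRT2PI = np.sqrt(2.0 * np.pi)


def _phi(z):
    """Standard normal density."""
    return np.exp(-0.5 * z * z) / _SQRT2PI


@dataclass(frozen=True)
class LBAParams:
    """LBA parameters on the natural (constrained) scale.

    Attributes
    ----------
    b : float
        Decision threshold (evidence units); must exceed ``A``.
    A : float
        Upper bound of the uniform start-point distribution; ``A >= 0``.
    t0 : float
        Non-decision time in seconds; ``t0 > 0``.
    s : float
        Common drift-rate SD, fixed to 1 by default for identifiability.
    """

    b: float
    A: float
    t0: float
    s: float = 1.0

    def __post_init__(self):
        if not np.all(np.isfinite([self.b, self.A, self.t0, self.s])):
            raise ValueError("LBA parameters must be finite")
        if self.A < 0:
            raise ValueError(f"A must be >= 0, got {self.A}")
        if self.b <= self.A:
            raise ValueError(f"b must exceed A, got b={self.b}, A={self.A}")
        if self.t0 <= 0:
            raise ValueError(f"t0 must be positive, got {self.t0}")
        if self.s <= 0:
            raise ValueError(f"s must be positive, got {self.s}")

    def to_dict(self) -> dict:
        return {"b": self.b, "A": self.A, "t0": self.t0, "s": self.s}

    @classmethod
    def from_dict(cls, d: dict) -> "LBAParams":
        return cls(b=d["b"], A=d["A"], t0=d["t0"], s=d.get("s", 1.0))


@dataclass(frozen=True)
class TransformedParams:
    """Unconstrained parameters ``(log(b - A), log A, log t0)``."""

    b_star: float
    A_star: float
    t0_star: float

    def __post_init__(self):
        if not np.all(np.isfinite([self.b_star, self.A_star, self.t0_star])):
            raise ValueError("transformed parameters must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.b_star, self.A_star, self.t0_star])

    @classmethod
    def from_array(cls, a) -> "TransformedParams":
        a = np.asarray(a, dtype=float)
        return cls(float(a[0]), float(a[1]), float(a[2]))


def transform_params(p: LBAParams) -> TransformedParams:
    """Map constrained LBA parameters to the real line.

    ``theta* = (log(b - A), log A, log t0)``.  Raises ``ValueError`` when the
    argument violates ``b > A > 0`` or ``t0 > 0`` (``A = 0`` has no finite
    image under the log map).
    """
    if p.A <= 0:
        raise ValueError("transform requires A > 0")
    return TransformedParams(
        float(np.log(p.b - p.A)), float(np.log(p.A)), float(np.log(p.t0))
    )


def inverse_transform(ts: TransformedParams) -> LBAParams:
    """Map unconstrained parameters back to the natural scale.

    ``A = exp(A*)``, ``b = exp(b*) + A``, ``t0 = exp(t0*)``; the image always
    satisfies the LBA constraints ``b > A > 0``, ``t0 > 0``.
    """
    A = float(np.exp(ts.A_star))
    b = float(np.exp(ts.b_star)) + A
    t0 = float(np.exp(ts.t0_star))
    return LBAParams(b=b, A=A, t0=t0)


def log_jacobian(ts: TransformedParams) -> float:
    """log |det J| of the inverse transform, ``b* + A* + t0*``.

    Equivalently ``log((b - A) * A * t0)``: each coordinate map is an
    exponential (the threshold via the gap ``b - A``), so the Jacobian is
    triangular with the exponentials on the diagonal.
    """
    return float(ts.b_star + ts.A_star + ts.t0_star)


# ---------------------------------------------------------------------------
# single-accumulator first-passage CDF / PDF
# ---------------------------------------------------------------------------

def accumulator_cdf(u, b, A, v, s=1.0):
    """P(single accumulator crosses ``b`` by decision time ``u``).

    ``u`` is time measured from accumulation onset (rt minus ``t0``).  The
    start point is U[0, A] and the drift is N(v, s^2), giving

    ``F(u) = 1 + (b-A-uv)/A * Phi(z1) - (b-uv)/A * Phi(z2)
           + us/A * (phi(z1) - phi(z2))``

    with ``z1 = (b-A-uv)/(us)``, ``z2 = (b-uv)/(us)``.  For ``A`` below a
    small cutoff the point-start limit ``Phi((uv-b)/(us))`` is used.  The
    result is clamped to [0, 1] against floating-point excursions.  The
    defect ``1 - F(inf) = Phi(-v/s)`` is the probability the drift draw is
    negative.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0):
        raise ValueError("decision time u must be positive")
    us = u * s
    z2 = (b - u * v) / us
    if A < _A_LIMIT:
        F = ndtr(-z2)
    else:
        z1 = (b - A - u * v) / us
        F = (
            1.0
            + (b - A - u * v) / A * ndtr(z1)
            - (b - u * v) / A * ndtr(z2)
            + us / A * (_phi(z1) - _phi(z2))
        )
    return np.clip(F, 0.0, 1.0)


def accumulator_pdf(u, b, A, v, s=1.0):
    """First-passage density of a single accumulator at decision time ``u``.

    ``f(u) = (1/A) * [-v*(Phi(z1) - Phi(z2)) + s*(phi(z1) - phi(z2))]``,
    floored at zero against rounding.  Point-start limit for small ``A``:
    ``f(u) = b/(u^2 s) * phi(z2)``.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0):
        raise ValueError("decision time u must be positive")
    us = u * s
    z2 = (b - u * v) / us
    if A < _A_LIMIT:
        f = b / (u * us) * _phi(z2)
    else:
        z1 = (b - A - u * v) / us
        f = (-v * (ndtr(z1) - ndtr(z2)) + s * (_phi(z1) - _phi(z2))) / A
    return np.maximum(f, 0.0)


def _check_trial_args(rts, choices, v):
    rts = np.atleast_1d(np.asarray(rts, dtype=float))
    choices = np.atleast_1d(np.asarray(choices))
    v = np.atleast_2d(np.asarray(v, dtype=float))
    if v.shape[1] != 4:
        raise ValueError(f"drift means must have 4 columns, got shape {v.shape}")
    if not (rts.shape[0] == choices.shape[0] == v.shape[0]):
        raise ValueError("rts, choices and drift means must have equal length")
    if np.any((choices < 1) | (choices > 4)):
        raise ValueError("choices must lie in 1..4")
    if not np.all(np.isfinite(v)):
        raise ValueError("drift means must be finite")
    return rts, choices.astype(int), v


def trial_loglik(rts, choices, v, p: LBAParams):
    """Log defective density of (rt, choice) trials under the LBA.

    ``log f_c(u) + sum_{k != c} log(1 - F_k(u))`` with ``u = rt - t0``;
    returns ``-inf`` for ``rt <= t0``.  Vectorized: ``rts``/``choices`` are
    length-n, ``v`` is (n, 4) (or a single 4-vector broadcast over trials).

    The survival factors are clamped below by a tiny floor before the log so
    the result is finite for any ``rt > t0`` with finite parameters.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim == 1:
        v = np.broadcast_to(v, (np.atleast_1d(rts).shape[0], 4))
    rts, choices, v = _check_trial_args(rts, choices, v)
    out = np.full(rts.shape, -np.inf)
    ok = rts > p.t0
    if not np.any(ok):
        return out if out.size > 1 else float(out[0])
    u = rts[ok][:, None]  # (m, 1)
    vk = v[ok]            # (m, 4)
    u_dec = u - p.t0
    F = accumulator_cdf(np.broadcast_to(u_dec, vk.shape), p.b, p.A, vk, p.s)
    f = accumulator_pdf(np.broadcast_to(u_dec, vk.shape), p.b, p.A, vk, p.s)
    surv = np.log(np.clip(1.0 - np.minimum(F, _CDF_CEIL), _DENSITY_FLOOR, None))
    dens = np.log(np.maximum(f, _DENSITY_FLOOR))
    idx = choices[ok] - 1
    rows = np.arange(vk.shape[0])
    ll = dens[rows, idx] + surv.sum(axis=1) - surv[rows, idx]
    out[ok] = ll
    return out if out.size > 1 else float(out[0])


class TrialGrads(NamedTuple):
    """Log-likelihood and its analytic gradients (per trial)."""

    loglik: np.ndarray      # (n,)
    d_v: np.ndarray         # (n, 4) gradient wrt drift means
    d_theta_star: np.ndarray  # (n, 3) gradient wrt (b*, A*, t0*)


def _cdf_pdf_grads(u, b, A, v, s):
    """CDF, PDF and their partials wrt (v, b, A, u) for one accumulator.

    All arrays broadcast;  ``u`` is decision time.  The closed forms below
    follow from differentiating the defective first-passage expressions; the
    phi-terms largely cancel (e.g. dF/dv reduces to (u/A)(Phi(z2)-Phi(z1))).
    """
    us = u * s
    z2 = (b - u * v) / us
    p2, d2 = ndtr(z2), _phi(z2)
    if np.ndim(A) == 0 and A < _A_LIMIT:
        F = ndtr(-z2)
        f = b / (u * us) * d2
        dF_dv = d2 / s
        dF_db = -d2 / us
        dF_dA = np.zeros_like(F)
        dF_du = f
        df_dv = b * z2 * d2 / (u * u * s * s)
        df_db = d2 / (u * us) * (1.0 - b * z2 / us)
        df_dA = np.zeros_like(F)
        df_du = b * d2 / s * (b * z2 / (us * u ** 3) - 2.0 / u ** 3)
        return F, f, dF_dv, dF_db, dF_dA, dF_du, df_dv, df_db, df_dA, df_du
    z1 = (b - A - u * v) / us
    p1, d1 = ndtr(z1), _phi(z1)
    F = 1.0 + (b - A - u * v) / A * p1 - (b - u * v) / A * p2 + us / A * (d1 - d2)
    f = (-v * (p1 - p2) + s * (d1 - d2)) / A
    dF_dv = (u / A) * (p2 - p1)
    dF_db = (p1 - p2) / A
    dF_dA = (b - u * v) / A ** 2 * (p2 - p1) + us / A ** 2 * (d2 - d1)
    dF_du = f
    df_dv = (p2 - p1) / A + ((b - A) * d1 - b * d2) / (A * us)
    df_db = (b * d2 - (b - A) * d1) / (A * u * us)
    df_dA = -f / A + (b - A) * d1 / (A * u * us)
    df_du = ((b - A) ** 2 * d1 - b ** 2 * d2) / (A * u ** 3 * s)
    return F, f, dF_dv, dF_db, dF_dA, dF_du, df_dv, df_db, df_dA, df_du


def trial_loglik_grads(rts, choices, v, p: LBAParams) -> TrialGrads:
    """Trial log-likelihoods with analytic gradients.

    Returns the log-likelihood plus gradients with respect to the per-trial
    drift means (n, 4) and the transformed parameters ``(b*, A*, t0*)``
    (n, 3), using the chain rule through ``b = exp(b*) + A``, ``A = exp(A*)``,
    ``t0 = exp(t0*)``.  Trials with ``rt <= t0`` get ``-inf`` log-likelihood
    and zero gradients.
    """
    rts, choices, v = _check_trial_args(rts, choices, v)
    n = rts.shape[0]
    ll = np.full(n, -np.inf)
    d_v = np.zeros((n, 4))
    d_ts = np.zeros((n, 3))
    ok = rts > p.t0
    if np.any(ok):
        u = (rts[ok] - p.t0)[:, None]
        vk = v[ok]
        u_b = np.broadcast_to(u, vk.shape)
        F, f, dF_dv, dF_db, dF_dA, dF_du, df_dv, df_db, df_dA, df_du = \
            _cdf_pdf_grads(u_b, p.b, p.A, vk, p.s)
        S = np.clip(1.0 - np.minimum(F, _CDF_CEIL), _DENSITY_FLOOR, None)
        fa = np.maximum(f, _DENSITY_FLOOR)
        idx = choices[ok] - 1
        rows = np.arange(vk.shape[0])
        win = np.zeros_like(F, dtype=bool)
        win[rows, idx] = True
        # log density for winner, log survival for losers
        ll[ok] = np.log(fa[rows, idx]) + np.where(win, 0.0, np.log(S)).sum(axis=1)
        # d loglik / d v_k: winner f'/f, losers -F'/(1-F)
        d_v[ok] = np.where(win, df_dv / fa, -dF_dv / S)
        # d/db, d/dA, d/du accumulate over all four accumulators
        d_b = np.where(win, df_db / fa, -dF_db / S).sum(axis=1)
        d_A = np.where(win, df_dA / fa, -dF_dA / S).sum(axis=1)
        d_u = np.where(win, df_du / fa, -dF_du / S).sum(axis=1)
        d_t0 = -d_u
        # chain rule to (b*, A*, t0*): b = e^{b*} + A, A = e^{A*}, t0 = e^{t0*}
        eb = p.b - p.A
        d_ts[ok, 0] = eb * d_b
        d_ts[ok, 1] = p.A * (d_A + d_b)
        d_ts[ok, 2] = p.t0 * d_t0
    return TrialGrads(ll, d_v, d_ts)


def loglik_grads_batch(rts, choices, v, b, A, t0, s=1.0, u_floor=1e-4):
    """Vectorized log-likelihood and gradients at per-sample parameters.

    Evaluates the LBA trial log-likelihood for ``n`` trials at ``m``
    parameter draws per trial (the Monte-Carlo ELBO needs a different
    ``theta`` sample for every (trial, draw) pair).

    Parameters
    ----------
    rts, choices : arrays (n,)
    v : array (n, 4)
        Drift means (shared across the m draws of a trial).
    b, A, t0 : arrays (n, m)
        Natural-scale parameters per (trial, draw).
    u_floor : float
        Decision times ``rt - t0`` below this are clamped to it, giving an
        astronomically small (floored) density instead of ``-inf`` so a
        stray posterior draw with ``t0 >= rt`` yields a large finite penalty
        rather than aborting the fit; gradients are zeroed there.

    Returns
    -------
    ll : (n, m); d_v : (n, m, 4); d_b, d_A, d_t0 : (n, m)
        Log-likelihood and its gradients on the natural scale.
    """
    rts = np.asarray(rts, dtype=float)
    choices = np.asarray(choices, dtype=int)
    v = np.asarray(v, dtype=float)
    b = np.asarray(b, dtype=float)[..., None]       # (n, m, 1)
    A = np.maximum(np.asarray(A, dtype=float), _A_LIMIT)[..., None]
    t0 = np.asarray(t0, dtype=float)
    u = rts[:, None] - t0                            # (n, m)
    clamped = u < u_floor
    u3 = np.maximum(u, u_floor)[..., None]           # (n, m, 1)
    v3 = v[:, None, :]                               # (n, 1, 4)
    F, f, dF_dv, dF_db, dF_dA, dF_du, df_dv, df_db, df_dA, df_du = \
        _cdf_pdf_grads(u3, b, A, v3, s)
    S = np.clip(1.0 - np.minimum(F, _CDF_CEIL), _DENSITY_FLOOR, None)
    fa = np.maximum(f, _DENSITY_FLOOR)
    win = np.zeros((rts.shape[0], 1, 4), dtype=bool)
    win[np.arange(rts.shape[0]), 0, choices - 1] = True
    ll = np.where(win, np.log(fa), np.log(S)).sum(axis=2)
    dead = win & (f <= _DENSITY_FLOOR)  # floored density: no usable gradient
    d_v = np.where(win, df_dv / fa, -dF_dv / S)
    d_v = np.where(dead, 0.0, d_v)
    per_acc = lambda dfx, dFx: np.where(
        dead, 0.0, np.where(win, dfx / fa, -dFx / S))
    d_b = per_acc(df_db, dF_db).sum(axis=2)
    d_A = per_acc(df_dA, dF_dA).sum(axis=2)
    d_t0 = -per_acc(df_du, dF_du).sum(axis=2)
    d_v = np.where(clamped[..., None], 0.0, d_v)
    zero = np.zeros_like(ll)
    d_b = np.where(clamped, zero, d_b)
    d_A = np.where(clamped, zero, d_A)
    d_t0 = np.where(clamped, zero, d_t0)
    return ll, d_v, d_b, d_A, d_t0


def sample_trials(v_per_trial, p: LBAParams, seed=None, rng=None):
    """Simulate LBA trials at per-trial drift means.

    Parameters
    ----------
    v_per_trial : array (n, 4)
        Mean drift rate for each response on each trial.
    p : LBAParams
    seed : int, optional
        Seed for a fresh generator; ignored if ``rng`` is given.
    rng : numpy.random.Generator, optional

    Returns
    -------
    rts : array (n,)
        Response times (NaN where invalid).
    choices : array (n,)
        Winning response 1..4 (0 where invalid).
    valid : boolean array (n,)
        False where all four sampled drifts were <= 0, leaving rt/choice
        undefined.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    v = np.atleast_2d(np.asarray(v_per_trial, dtype=float))
    if v.shape[1] != 4:
        raise ValueError("v_per_trial must be (n, 4)")
    if not np.all(np.isfinite(v)):
        raise ValueError("drift means must be finite")
    n = v.shape[0]
    start = rng.uniform(0.0, p.A, size=(n, 4)) if p.A > 0 else np.zeros((n, 4))
    d = rng.normal(v, p.s)
    with np.errstate(divide="ignore", invalid="ignore"):
        finish = np.where(d > 0, (p.b - start) / d, np.inf)
    valid = np.isfinite(finish).any(axis=1)
    choices = np.zeros(n, dtype=int)
    rts = np.full(n, np.nan)
    if np.any(valid):
        k = np.argmin(finish[valid], axis=1)
        choices[valid] = k + 1
        rts[valid] = finish[valid, k] + p.t0
    return rts, choices, valid
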