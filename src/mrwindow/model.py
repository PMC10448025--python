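"""Bayesian bivariate-normal mixed-effects model for standardized windows.

Each standardized observation is the pair Y_n = (sWL_n, sWW_n) set by
operator i_n on an image of condition j_n.  The model is

    Y_n ~ BivariateNormal(mu[i_n, j_n], Sigma[i_n])
    mu[i, j, k] = beta[0, k] + beta[1, k] * x1(i) + ... + gamma[i, j, k]

with dummy coding x_c(i) = 1{i = c+1} (operator 1 is the reference), an
operator-specific 2x2 covariance Sigma[i], and an operator-by-condition
random effect gamma[i, j, k] ~ Normal(0, tau[j]^2) whose spread tau[j] is
condition-specific and shared across operators and components.

Priors (weakly informative stand-ins for flat priors): beta ~ N(0, 100^2),
tau_j ~ HalfCauchy(25), Sigma_i decomposed into per-component scales
~ HalfCauchy(25) and a correlation uniform on (-1, 1).

Posterior inference is by a blocked Gibbs sampler: beta and the gamma cells
have exact multivariate-normal full conditionals; the tau and Sigma scale/
correlation parameters are updated by univariate slice sampling on an
unconstrained scale.  The sampler is deterministic given a seed.  The
posterior means of mu over the retained draws are the standardized optimal
windows (soWL, soWW) per operator x condition.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import Frame, ImagingCondition, WindowSetting, WindowingRecord
from .errors import ConvergenceWarning, FrameError, ValidationError

__all__ = [
    "ObservationMatrix",
    "ModelSpec",
    "SamplerSettings",
    "Parameters",
    "PosteriorSamples",
    "RhatReport",
    "FittedModel",
    "encode_design",
    "design_matrix",
    "log_density",
    "fit_mcmc",
    "compute_rhat",
    "extract_mu_hat",
]


# ---------------------------------------------------------------------------
# Data containers


@dataclass
class ObservationMatrix:
    """Stacked standardized pairs with 1-based operator/condition indices."""

    Y: np.ndarray  # (N, 2): columns sWL, sWW
    operator: np.ndarray  # (N,) ints in 1..I
    condition: np.ndarray  # (N,) ints in 1..J
    I: int
    J: int

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        self.operator = np.asarray(self.operator, dtype=int)
        self.condition = np.asarray(self.condition, dtype=int)
        if self.Y.ndim != 2 or self.Y.shape[1] != 2:
            raise ValidationError(f"Y must be (N, 2), got {self.Y.shape}")
        n = self.Y.shape[0]
        if n == 0:
            raise ValidationError("no observations")
        if self.operator.shape != (n,) or self.condition.shape != (n,):
            raise ValidationError("index vectors must match Y's length")
        if not np.all(np.isfinite(self.Y)):
            raise ValidationError("Y contains missing/non-finite values")
        if self.operator.min() < 1 or self.operator.max() > self.I:
            raise ValidationError("operator index out of range")
        if self.condition.min() < 1 or self.condition.max() > self.J:
            raise ValidationError("condition index out of range")

    @property
    def N(self) -> int:
        return self.Y.shape[0]


@dataclass
class ModelSpec:
    """Model dimensions, prior scales, and structural options.

    ``fixed_tau`` / ``fixed_sigma`` pin those parameters at known values
    (point priors), which makes the remaining posterior exactly Gaussian —
    used for validation against a closed-form oracle.  ``condition_only_gamma``
    replaces the operator-by-condition random effect with a condition-only
    effect shared across operators (sensitivity variant).
    """

    I: int = 3
    J: int = 1
    beta_scale: float = 100.0
    tau_scale: float = 25.0
    sigma_scale: float = 25.0
    condition_only_gamma: bool = False
    fixed_tau: Optional[np.ndarray] = None  # (J,)
    fixed_sigma: Optional[np.ndarray] = None  # (I, 2, 2)

    def __post_init__(self) -> None:
        if self.I < 1 or self.J < 1:
            raise ValidationError("I and J must be >= 1")
        if self.fixed_tau is not None:
            self.fixed_tau = np.asarray(self.fixed_tau, dtype=float)
            if self.fixed_tau.shape != (self.J,) or np.any(self.fixed_tau <= 0):
                raise ValidationError("fixed_tau must be (J,) positive")
        if self.fixed_sigma is not None:
            self.fixed_sigma = np.asarray(self.fixed_sigma, dtype=float)
            if self.fixed_sigma.shape != (self.I, 2, 2):
                raise ValidationError("fixed_sigma must be (I, 2, 2)")


@dataclass
class SamplerSettings:
    """MCMC budget: chains, warmup and retained draws per chain, thinning."""

    chains: int = 4
    warmup: int = 1000
    draws: int = 2500
    thin: int = 1

    @classmethod
    def default(cls) -> "SamplerSettings":
        """Desk-scale profile: 4 chains x (1000 warmup + 2500 draws)."""
        return cls()

    @classmethod
    def reference(cls) -> "SamplerSettings":
        """Full-fidelity profile: 4 chains, 50000 iterations per chain of
        which 1000 are warmup, post-warmup draws thinned by 5."""
        return cls(chains=4, warmup=1000, draws=9800, thin=5)

    def __post_init__(self) -> None:
        if self.chains < 1 or self.warmup < 0 or self.draws < 1 or self.thin < 1:
            raise ValidationError("invalid sampler settings")


@dataclass
class Parameters:
    """One point in parameter space (used by log_density and tests)."""

    beta: np.ndarray  # (I, 2): rows = intercept, operator-2 dummy, ...
    gamma: np.ndarray  # (I, J, 2)
    tau: np.ndarray  # (J,)
    sigma: np.ndarray  # (I, 2, 2)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)

    def mu(self) -> np.ndarray:
        """mu[i, j, k] = fixed-effect part + gamma[i, j, k]; shape (I, J, 2)."""
        I = self.beta.shape[0]
        m = design_matrix(I) @ self.beta  # (I, 2)
        return m[:, None, :] + self.gamma


def design_matrix(I: int) -> np.ndarray:
    """Dummy-coding design: row i = (1, 1{i=2}, ..., 1{i=I}); shape (I, I)."""
    D = np.eye(I)
    D[:, 0] = 1.0
    return D


# ---------------------------------------------------------------------------
# Encoding


def encode_design(
    records: Sequence[WindowingRecord], spec: ModelSpec
) -> ObservationMatrix:
    """Stack standardized records into the observation matrix.

    Records must already be in the standardized frame; Y rows follow record
    order, and operator/condition indices are taken from the records.
    """
    if not records:
        raise ValidationError("no records to encode")
    for r in records:
        if r.frame != Frame.STANDARDIZED:
            raise FrameError(
                f"record {r.series_id!r} (operator {r.operator}) is in the "
                f"{r.frame.value} frame; standardize windows before modeling"
            )
    Y = np.array([[r.window.wl, r.window.ww] for r in records], dtype=float)
    op = np.array([r.operator for r in records], dtype=int)
    cond = np.array([r.condition.index for r in records], dtype=int)
    return ObservationMatrix(Y=Y, operator=op, condition=cond, I=spec.I, J=spec.J)


# ---------------------------------------------------------------------------
# Log density (direct parameterization; used as the sampler's ground truth)

_LOG_2PI = float(np.log(2.0 * np.pi))

#: scale parameters (tau, Sigma component sds) are bounded below at exp(floor)
#: so that precisions stay finite on degenerate (zero-variance) data
_LOG_SCALE_FLOOR = float(np.log(1e-8))


def _log_half_cauchy(x: np.ndarray, scale: float) -> np.ndarray:
    return np.log(2.0 / (np.pi * scale)) - np.log1p((x / scale) ** 2)


def log_density(params: Parameters, data: ObservationMatrix, spec: ModelSpec) -> float:
    """Unnormalized log posterior density at ``params``.

    The density is over (beta, gamma, tau, and Sigma's scale/correlation
    decomposition (s1, s2, r)) in their natural units.  Returns -inf for
    non-positive-definite Sigma or non-positive tau.  Parameters pinned by
    ``fixed_tau``/``fixed_sigma`` contribute no prior term.
    """
    beta, gamma, tau, sigma = params.beta, params.gamma, params.tau, params.sigma
    I, J = spec.I, spec.J
    if np.any(tau <= 0):
        return -np.inf
    s1 = np.sqrt(sigma[:, 0, 0])
    s2 = np.sqrt(sigma[:, 1, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        r = sigma[:, 0, 1] / (s1 * s2)
    if (
        np.any(~np.isfinite(s1))
        or np.any(~np.isfinite(s2))
        or np.any(np.abs(r) >= 1.0)
        or np.any(sigma[:, 0, 1] != sigma[:, 1, 0])
    ):
        return -np.inf

    mu_cells = params.mu()  # (I, J, 2)
    mu_n = mu_cells[data.operator - 1, data.condition - 1]  # (N, 2)
    resid = data.Y - mu_n
    lp = 0.0
    det = sigma[:, 0, 0] * sigma[:, 1, 1] - sigma[:, 0, 1] ** 2
    for i in range(I):
        mask = data.operator == i + 1
        if not np.any(mask):
            continue
        d = resid[mask]
        a, b, c = sigma[i, 0, 0], sigma[i, 1, 1], sigma[i, 0, 1]
        quad = (b * d[:, 0] ** 2 - 2 * c * d[:, 0] * d[:, 1] + a * d[:, 1] ** 2) / det[i]
        lp += -0.5 * float(np.sum(quad)) - 0.5 * mask.sum() * (
            _LOG_2PI * 2 + np.log(det[i])
        )

    # gamma prior: N(0, tau_j^2) per entry; in condition-only mode the J*2
    # unique values carry the prior once.
    if spec.condition_only_gamma:
        g = gamma[0]  # (J, 2)
        lp += float(
            np.sum(-0.5 * (g**2) / tau[:, None] ** 2 - 0.5 * _LOG_2PI - np.log(tau)[:, None])
        )
    else:
        lp += float(
            np.sum(
                -0.5 * (gamma**2) / tau[None, :, None] ** 2
                - 0.5 * _LOG_2PI
                - np.log(tau)[None, :, None]
            )
        )

    lp += float(
        np.sum(-0.5 * (beta / spec.beta_scale) ** 2 - 0.5 * _LOG_2PI - np.log(spec.beta_scale))
    )
    if spec.fixed_tau is None:
        lp += float(np.sum(_log_half_cauchy(tau, spec.tau_scale)))
    if spec.fixed_sigma is None:
        lp += float(np.sum(_log_half_cauchy(s1, spec.sigma_scale)))
        lp += float(np.sum(_log_half_cauchy(s2, spec.sigma_scale)))
        lp += I * np.log(0.5)  # correlation uniform on (-1, 1)
    return float(lp)


# ---------------------------------------------------------------------------
# Gibbs sampler


def _slice_sample(logf, x0: float, rng: np.random.Generator, w: float = 1.0,
                  max_steps: int = 50) -> float:
    """Univariate slice sampler with stepping-out and shrinkage (Neal 2003)."""
    y = logf(x0) - rng.exponential()
    u = rng.random()
    lo = x0 - w * u
    hi = lo + w
    steps = max_steps
    while steps > 0 and logf(lo) > y:
        lo -= w
        steps -= 1
    steps = max_steps
    while steps > 0 and logf(hi) > y:
        hi += w
        steps -= 1
    while True:
        x1 = lo + rng.random() * (hi - lo)
        if logf(x1) > y:
            return x1
        if hi - lo < 1e-12:
            return x0
        if x1 < x0:
            lo = x1
        else:
            hi = x1


def _cell_stats(data: ObservationMatrix) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-(i, j) sufficient statistics: counts, sums, raw scatter."""
    I, J = data.I, data.J
    n = np.zeros((I, J))
    s = np.zeros((I, J, 2))
    S = np.zeros((I, J, 2, 2))
    ii = data.operator - 1
    jj = data.condition - 1
    np.add.at(n, (ii, jj), 1.0)
    np.add.at(s, (ii, jj), data.Y)
    np.add.at(S, (ii, jj), data.Y[:, :, None] * data.Y[:, None, :])
    return n, s, S


def _inv2(M: np.ndarray) -> np.ndarray:
    """Batched 2x2 inverse."""
    a = M[..., 0, 0]
    b = M[..., 1, 1]
    c = M[..., 0, 1]
    det = a * b - c * c
    out = np.empty_like(M)
    out[..., 0, 0] = b / det
    out[..., 1, 1] = a / det
    out[..., 0, 1] = -c / det
    out[..., 1, 0] = -c / det
    return out


def _chol2(C: np.ndarray) -> np.ndarray:
    """Batched 2x2 lower Cholesky."""
    l11 = np.sqrt(C[..., 0, 0])
    l21 = C[..., 1, 0] / l11
    l22 = np.sqrt(np.maximum(C[..., 1, 1] - l21 * l21, 1e-300))
    L = np.zeros_like(C)
    L[..., 0, 0] = l11
    L[..., 1, 0] = l21
    L[..., 1, 1] = l22
    return L


def _iw_logpdf_2x2(X: np.ndarray, df: float, scale: np.ndarray) -> float:
    """log density of the 2x2 inverse-Wishart IW(df, scale) at X."""
    from scipy.special import gammaln

    det_s = scale[0, 0] * scale[1, 1] - scale[0, 1] ** 2
    det_x = X[0, 0] * X[1, 1] - X[0, 1] ** 2
    if det_x <= 0:
        return -np.inf
    # tr(scale @ X^{-1})
    tr = (scale[0, 0] * X[1, 1] - 2 * scale[0, 1] * X[0, 1] + scale[1, 1] * X[0, 0]) / det_x
    log_gamma2 = 0.5 * np.log(np.pi) + gammaln(df / 2.0) + gammaln((df - 1.0) / 2.0)
    return float(
        0.5 * df * np.log(det_s)
        - 0.5 * (df + 3.0) * np.log(det_x)
        - 0.5 * tr
        - df * np.log(2.0)
        - log_gamma2
    )


def _iw_rvs_2x2(df: float, scale: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One draw from the 2x2 inverse-Wishart via the Bartlett decomposition."""
    inv_scale = _inv2(scale[None])[0]
    L = _chol2(inv_scale[None])[0]
    A = np.zeros((2, 2))
    A[0, 0] = np.sqrt(rng.chisquare(df))
    A[1, 1] = np.sqrt(rng.chisquare(df - 1.0))
    A[1, 0] = rng.standard_normal()
    LA = L @ A
    W = LA @ LA.T  # Wishart(df, scale^{-1})
    return _inv2(W[None])[0]


class _GibbsState:
    """Mutable sampler state and the blocked full-conditional updates."""

    def __init__(self, data: ObservationMatrix, spec: ModelSpec,
                 rng: np.random.Generator) -> None:
        self.data = data
        self.spec = spec
        self.rng = rng
        self.I, self.J = spec.I, spec.J
        self.D = design_matrix(spec.I)
        self.n, self.s, self.S = _cell_stats(data)
        self.n_op = self.n.sum(axis=1)  # (I,)
        self._init_params()

    def _init_params(self) -> None:
        rng, I, J = self.rng, self.I, self.J
        data = self.data
        ybar = data.Y.mean(axis=0)
        beta = np.zeros((I, 2))
        beta[0] = ybar
        for i in range(1, I):
            mask = data.operator == i + 1
            ref = data.operator == 1
            if mask.any() and ref.any():
                beta[i] = data.Y[mask].mean(axis=0) - data.Y[ref].mean(axis=0)
        self.beta = beta + rng.normal(scale=0.5, size=(I, 2))
        self.gamma = rng.normal(scale=0.1, size=(I, J, 2))
        if self.spec.condition_only_gamma:
            self.gamma[:] = self.gamma[0]
        if self.spec.fixed_tau is not None:
            self.tau = self.spec.fixed_tau.copy()
        else:
            self.tau = np.exp(rng.normal(scale=0.3, size=J))
        if self.spec.fixed_sigma is not None:
            self.sigma = self.spec.fixed_sigma.copy()
        else:
            # within-cell residuals, so between-condition spread does not
            # inflate (or near-degenerate-correlate) the starting covariance
            cell_mean = np.where(
                self.n[:, :, None] > 0,
                self.s / np.maximum(self.n[:, :, None], 1.0),
                0.0,
            )
            resid = data.Y - cell_mean[data.operator - 1, data.condition - 1]
            self.sigma = np.empty((I, 2, 2))
            for i in range(I):
                mask = data.operator == i + 1
                if mask.sum() >= 3:
                    cov = np.cov(resid[mask].T) + 1e-2 * np.eye(2)
                else:
                    cov = np.eye(2)
                self.sigma[i] = cov * np.exp(rng.normal(scale=0.2))
        self.sigma_inv = _inv2(self.sigma)

    # -- full conditionals ---------------------------------------------------

    def update_gamma(self) -> None:
        rng = self.rng
        m = self.D @ self.beta  # (I, 2)
        h_cell = np.einsum(
            "iab,ijb->ija", self.sigma_inv, self.s - self.n[:, :, None] * m[:, None, :]
        )
        if self.spec.condition_only_gamma:
            P = np.einsum("ij,iab->jab", self.n, self.sigma_inv)
            P += (1.0 / self.tau**2)[:, None, None] * np.eye(2)
            h = h_cell.sum(axis=0)  # (J, 2)
            C = _inv2(P)
            mean = np.einsum("jab,jb->ja", C, h)
            L = _chol2(C)
            z = rng.standard_normal((self.J, 2))
            g = mean + np.einsum("jab,jb->ja", L, z)
            self.gamma = np.broadcast_to(g, (self.I, self.J, 2)).copy()
        else:
            P = self.n[:, :, None, None] * self.sigma_inv[:, None, :, :]
            P = P + (1.0 / self.tau**2)[None, :, None, None] * np.eye(2)
            C = _inv2(P)
            mean = np.einsum("ijab,ijb->ija", C, h_cell)
            L = _chol2(C)
            z = rng.standard_normal((self.I, self.J, 2))
            self.gamma = mean + np.einsum("ijab,ijb->ija", L, z)

    def update_beta(self) -> None:
        rng, I = self.rng, self.I
        # residual sums net of gamma, per operator
        r = (self.s - self.n[:, :, None] * self.gamma).sum(axis=1)  # (I, 2)
        A = np.eye(2 * I) / self.spec.beta_scale**2
        b = np.zeros(2 * I)
        for i in range(I):
            d = self.D[i]
            A += self.n_op[i] * np.kron(np.outer(d, d), self.sigma_inv[i])
            b += np.kron(d, self.sigma_inv[i] @ r[i])
        L = np.linalg.cholesky(A)
        mean = np.linalg.solve(A, b)
        x = mean + np.linalg.solve(L.T, rng.standard_normal(2 * I))
        self.beta = x.reshape(I, 2)

    def _residual_scatter(self) -> np.ndarray:
        """T[i] = sum over obs of operator i of (y - mu_cell)(y - mu_cell)^T."""
        m = self.D @ self.beta
        c = m[:, None, :] + self.gamma  # (I, J, 2)
        T = self.S.sum(axis=1)
        T -= np.einsum("ija,ijb->iab", self.s, c)
        T -= np.einsum("ija,ijb->iab", c, self.s)
        T += np.einsum("ij,ija,ijb->iab", self.n, c, c)
        return T

    def _sigma_log_target(self, sigma: np.ndarray, n_i: float, T: np.ndarray) -> float:
        """Likelihood x prior for one operator's Sigma, as a density over the
        matrix entries (the scale/correlation prior carries its Jacobian)."""
        a, b, c = sigma[0, 0], sigma[1, 1], sigma[0, 1]
        det = a * b - c * c
        if det <= 0 or a <= 0 or b <= 0:
            return -np.inf
        s1, s2 = np.sqrt(a), np.sqrt(b)
        if s1 < 1e-8 or s2 < 1e-8:  # numerical floor on degenerate data
            return -np.inf
        tr = (b * T[0, 0] - 2 * c * T[0, 1] + a * T[1, 1]) / det
        lp = -0.5 * n_i * np.log(det) - 0.5 * tr
        scale = self.spec.sigma_scale
        # prior over (s1, s2, r) mapped to matrix measure: d(Sigma) =
        # 4 s1^2 s2^2 d(s1, s2, r)
        lp += _log_half_cauchy(s1, scale) + _log_half_cauchy(s2, scale) + np.log(0.5)
        lp -= np.log(4.0) + 2.0 * np.log(s1) + 2.0 * np.log(s2)
        return float(lp)

    def update_sigma(self) -> None:
        """Independence Metropolis step with an inverse-Wishart proposal.

        Coordinate-wise updates of (s1, s2, r) mix arbitrarily slowly when
        the posterior correlation is near +-1, so each Sigma_i is proposed
        jointly from the likelihood-shaped inverse-Wishart
        IW(n_i + 2, T_i + 0.1 I) and accepted against the stated
        half-Cauchy-scale / uniform-correlation prior.
        """
        if self.spec.fixed_sigma is not None:
            return
        rng = self.rng
        T = self._residual_scatter()
        for i in range(self.I):
            n_i = self.n_op[i]
            df = n_i + 2.0
            S = T[i] + 0.1 * np.eye(2)
            prop = _iw_rvs_2x2(df, S, rng)
            cur = self.sigma[i]
            prop_w = self._sigma_log_target(prop, n_i, T[i]) - _iw_logpdf_2x2(
                prop, df, S
            )
            cur_w = self._sigma_log_target(cur, n_i, T[i]) - _iw_logpdf_2x2(
                cur, df, S
            )
            u = rng.random()  # drawn unconditionally to keep the stream aligned
            if not np.isfinite(cur_w) or np.log(u) < prop_w - cur_w:
                self.sigma[i] = prop
        self.sigma_inv = _inv2(self.sigma)

    def update_tau(self) -> None:
        if self.spec.fixed_tau is not None:
            return
        rng = self.rng
        scale = self.spec.tau_scale
        if self.spec.condition_only_gamma:
            ss = np.sum(self.gamma[0] ** 2, axis=-1)  # (J,)
            count = 2.0
        else:
            ss = np.sum(self.gamma**2, axis=(0, 2))  # (J,)
            count = 2.0 * self.I
        for j in range(self.J):
            ssj = float(ss[j])

            def logpost(u: float) -> float:
                if u < _LOG_SCALE_FLOOR:
                    return -np.inf
                t = np.exp(u)
                return float(
                    -count * u - 0.5 * ssj * np.exp(-2 * u) + _log_half_cauchy(t, scale) + u
                )

            self.tau[j] = np.exp(_slice_sample(logpost, float(np.log(self.tau[j])), rng))

    def recenter(self) -> None:
        """Exact Gibbs moves along the mu-invariant translation directions.

        beta0_k + delta with gamma[:, :, k] - delta (and likewise each
        operator-dummy coefficient against its own gamma row) leaves the
        likelihood untouched; the conditional for delta is Gaussian from the
        beta and gamma priors.  Sampling these directions explicitly breaks
        the slow random walk between the fixed effect and the mean of the
        random effects.
        """
        rng = self.rng
        inv_tau2 = 1.0 / self.tau**2  # (J,)
        b2 = self.spec.beta_scale**2
        cond_only = self.spec.condition_only_gamma
        n_ops = 1 if cond_only else self.I
        for k in range(2):
            # intercept vs all gamma cells
            prec = 1.0 / b2 + n_ops * inv_tau2.sum()
            g = self.gamma[:1, :, k] if cond_only else self.gamma[:, :, k]
            lin = -self.beta[0, k] / b2 + float(np.sum(g * inv_tau2[None, :]))
            delta = lin / prec + rng.standard_normal() / np.sqrt(prec)
            self.beta[0, k] += delta
            self.gamma[:, :, k] -= delta
            if cond_only:
                continue
            # each operator-dummy coefficient vs that operator's gamma row
            for c in range(1, self.I):
                prec = 1.0 / b2 + inv_tau2.sum()
                lin = -self.beta[c, k] / b2 + float(
                    np.sum(self.gamma[c, :, k] * inv_tau2)
                )
                delta = lin / prec + rng.standard_normal() / np.sqrt(prec)
                self.beta[c, k] += delta
                self.gamma[c, :, k] -= delta

    def sweep(self) -> None:
        self.update_gamma()
        self.update_beta()
        self.recenter()
        self.update_sigma()
        self.update_tau()

    def mu(self) -> np.ndarray:
        return (self.D @ self.beta)[:, None, :] + self.gamma


@dataclass
class PosteriorSamples:
    """Retained post-warmup draws, shaped (chains, draws, ...)."""

    beta: np.ndarray  # (C, S, I, 2)
    gamma: np.ndarray  # (C, S, I, J, 2)
    tau: np.ndarray  # (C, S, J)
    sigma: np.ndarray  # (C, S, I, 2, 2)
    mu: np.ndarray  # (C, S, I, J, 2)
    spec: ModelSpec
    settings: SamplerSettings
    seed: int

    @property
    def chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.beta.shape[1]

    def to_inference_data(self):
        """Package draws as an arviz InferenceData for diagnostics."""
        import arviz as az

        data = {"beta": self.beta, "tau": self.tau, "sigma": self.sigma, "mu": self.mu}
        if not self.spec.condition_only_gamma:
            data["gamma"] = self.gamma
        else:
            data["gamma"] = self.gamma[:, :, :1]  # unique values only
        return az.from_dict(posterior=data)

    def mu_summary(self) -> Dict[str, np.ndarray]:
        """Posterior mean/sd/MCSE/ESS/Rhat for every mu cell, each (I, J, 2)."""
        import arviz as az

        idata = self.to_inference_data()
        post = idata.posterior["mu"]
        return {
            "mean": self.mu.mean(axis=(0, 1)),
            "sd": self.mu.std(axis=(0, 1), ddof=1),
            "mcse": az.mcse(idata, var_names=["mu"]).to_array().values[0],
            "ess": az.ess(idata, var_names=["mu"]).to_array().values[0],
            "rhat": az.rhat(idata, var_names=["mu"], method="split").to_array().values[0],
        }


def fit_mcmc(
    data: ObservationMatrix,
    spec: ModelSpec,
    sampler: Optional[SamplerSettings] = None,
    seed: int = 0,
) -> PosteriorSamples:
    """Run the blocked Gibbs sampler; deterministic given seed and settings.

    Empty (i, j) cells are permitted — their gamma draw is prior-driven,
    which is exactly the mechanism by which the model extrapolates to a
    condition an operator never adjusted — but are reported in a warning.
    """
    sampler = sampler or SamplerSettings.default()
    n, _, _ = _cell_stats(data)
    if np.any(n == 0):
        empty = [
            f"(operator {i + 1}, condition {j + 1})"
            for i, j in zip(*np.nonzero(n == 0))
        ]
        warnings.warn(
            "cells with no observations (gamma is prior-driven there): "
            + ", ".join(empty),
            ConvergenceWarning,
        )

    C, S = sampler.chains, sampler.draws
    I, J = spec.I, spec.J
    out_beta = np.empty((C, S, I, 2))
    out_gamma = np.empty((C, S, I, J, 2))
    out_tau = np.empty((C, S, J))
    out_sigma = np.empty((C, S, I, 2, 2))
    out_mu = np.empty((C, S, I, J, 2))

    seeds = np.random.SeedSequence(seed).spawn(C)
    for c in range(C):
        rng = np.random.default_rng(seeds[c])
        state = _GibbsState(data, spec, rng)
        for _ in range(sampler.warmup):
            state.sweep()
        for d in range(S):
            for _ in range(sampler.thin):
                state.sweep()
            out_beta[c, d] = state.beta
            out_gamma[c, d] = state.gamma
            out_tau[c, d] = state.tau
            out_sigma[c, d] = state.sigma
            out_mu[c, d] = state.mu()

    return PosteriorSamples(
        beta=out_beta,
        gamma=out_gamma,
        tau=out_tau,
        sigma=out_sigma,
        mu=out_mu,
        spec=spec,
        settings=sampler,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Diagnostics and extraction


@dataclass
class RhatReport:
    """Per-parameter split-Rhat values and the overall convergence verdict."""

    table: pd.DataFrame  # columns: parameter, rhat
    max_rhat: float
    converged: bool  # all split-Rhat < 1.1

    THRESHOLD = 1.1


def compute_rhat(samples: PosteriorSamples) -> RhatReport:
    """Split-Rhat for every scalar parameter (needs >= 2 chains).

    Parameters held exactly constant across all draws (pinned tau/Sigma)
    are excluded: Rhat is undefined at zero variance.
    """
    import arviz as az

    if samples.chains < 2:
        raise ValidationError("Rhat requires at least 2 chains")
    idata = samples.to_inference_data()
    rhat = az.rhat(idata, method="split")
    rows = []
    for name in rhat.data_vars:
        vals = np.asarray(rhat[name].values)
        draws = np.asarray(idata.posterior[name].values)
        flat_draws = draws.reshape(draws.shape[0] * draws.shape[1], -1)
        const = np.ptp(flat_draws, axis=0) == 0
        for k, (v, is_const) in enumerate(zip(vals.ravel(), const)):
            if is_const:
                continue
            idx = np.unravel_index(k, vals.shape) if vals.shape else ()
            label = name + ("[" + ",".join(map(str, idx)) + "]" if idx else "")
            rows.append((label, float(v)))
    table = pd.DataFrame(rows, columns=["parameter", "rhat"])
    max_rhat = float(table["rhat"].max()) if len(table) else 1.0
    return RhatReport(table=table, max_rhat=max_rhat,
                      converged=bool(max_rhat < RhatReport.THRESHOLD))


@dataclass
class FittedModel:
    """Posterior-mean table of standardized optimal windows per cell.

    ``mu_hat[i-1, j-1]`` is (soWL, soWW) for operator i and the condition
    with index j; ``conditions`` lists the conditions in index order.
    """

    mu_hat: np.ndarray  # (I, J, 2)
    conditions: List[ImagingCondition]
    convergence: Dict = field(default_factory=dict)

    @property
    def I(self) -> int:
        return self.mu_hat.shape[0]

    @property
    def J(self) -> int:
        return self.mu_hat.shape[1]

    def lookup(self, operator: int, condition: ImagingCondition) -> WindowSetting:
        """(soWL, soWW) for one operator x condition, standardized frame."""
        if not 1 <= operator <= self.I:
            raise ValidationError(f"operator {operator} out of 1..{self.I}")
        j = condition.index
        if not 1 <= j <= self.J:
            raise ValidationError(f"condition index {j} out of 1..{self.J}")
        so_wl, so_ww = self.mu_hat[operator - 1, j - 1]
        return WindowSetting(wl=float(so_wl), ww=float(so_ww))

    def save(self, path) -> None:
        """Write the soWL/soWW table as TSV plus a JSON convergence sidecar."""
        path = Path(path)
        rows = []
        for i in range(self.I):
            for j, cond in enumerate(self.conditions):
                rows.append(
                    {
                        "operator": i + 1,
                        "sequence": cond.sequence,
                        "region": cond.region,
                        "soWL": repr(float(self.mu_hat[i, j, 0])),
                        "soWW": repr(float(self.mu_hat[i, j, 1])),
                    }
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        sidecar = path.with_suffix(path.suffix + ".convergence.json")
        sidecar.write_text(json.dumps(self.convergence, indent=1, default=str))

    @classmethod
    def load(cls, path, registry) -> "FittedModel":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        conds = []
        for _, row in df[df["operator"] == 1].iterrows():
            conds.append(registry.intern(str(row["sequence"]), str(row["region"])))
        I = int(df["operator"].max())
        J = len(conds)
        mu_hat = np.empty((I, J, 2))
        for _, row in df.iterrows():
            cond = registry.intern(str(row["sequence"]), str(row["region"]))
            mu_hat[int(row["operator"]) - 1, cond.index - 1] = (
                float(row["soWL"]),
                float(row["soWW"]),
            )
        convergence = {}
        sidecar = path.with_suffix(path.suffix + ".convergence.json")
        if sidecar.exists():
            convergence = json.loads(sidecar.read_text())
        return cls(mu_hat=mu_hat, conditions=conds, convergence=convergence)


def extract_mu_hat(
    samples: PosteriorSamples,
    spec: ModelSpec,
    conditions: Sequence[ImagingCondition],
    rhat: Optional[RhatReport] = None,
) -> FittedModel:
    """Posterior means of mu as the soWL/soWW table.

    Every I x J cell is filled, including cells never observed.  A cell with
    non-positive mean soWW is flagged with a warning (it cannot be used as a
    display window).  If ``rhat`` is omitted it is computed here; a failed
    verdict downgrades to a warning, never a silent pass.
    """
    if len(conditions) != spec.J:
        raise ValidationError(f"expected {spec.J} conditions, got {len(conditions)}")
    if rhat is None and samples.chains >= 2:
        rhat = compute_rhat(samples)
    if rhat is not None and not rhat.converged:
        warnings.warn(
            f"MCMC may not have converged: max split-Rhat = {rhat.max_rhat:.3f} "
            f">= {RhatReport.THRESHOLD}",
            ConvergenceWarning,
        )
    mu_hat = samples.mu.mean(axis=(0, 1))
    bad = np.argwhere(mu_hat[:, :, 1] <= 0)
    if len(bad):
        cells = ", ".join(f"(operator {i + 1}, condition {j + 1})" for i, j in bad)
        warnings.warn(f"non-positive mean soWW in cells: {cells}", ConvergenceWarning)
    convergence = {
        "sampler": "blocked-gibbs",
        "seed": samples.seed,
        "settings": {
            "chains": samples.settings.chains,
            "warmup": samples.settings.warmup,
            "draws": samples.settings.draws,
            "thin": samples.settings.thin,
        },
    }
    if rhat is not None:
        convergence["max_rhat"] = rhat.max_rhat
        convergence["converged"] = rhat.converged
    return FittedModel(
        mu_hat=mu_hat, conditions=list(conditions), convergence=convergence
    )
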