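"""Restricted-maximum-likelihood inversion with covariance components.

Solves the linear model Y = H beta + eps under zero-mean Gaussian
assumptions on both the sources (covariance C_P) and the sensor noise
(covariance C_N), with each covariance expressed as a nonnegative linear
combination of fixed symmetric components:

    C_N = sum_i lam_N,i Q_N,i        C_P = sum_i lam_P,i Q_P,i

The hyperparameters lam are estimated by maximising the log-likelihood of
the data under the marginal model cov(Y) = H C_P H' + C_N (columns of Y
treated as i.i.d. realisations), using Fisher scoring on log-coefficients
with Levenberg-Marquardt damping.  The source estimate is the posterior
mean  beta_hat = C_P H' (H C_P H' + C_N)^-1 Y  at the optimum.

When both sides have a single identity component with fixed coefficients,
the posterior mean reduces to Tikhonov (ridge) regularisation with
lambda = lam_N / lam_P.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

logger = logging.getLogger(__name__)

__all__ = [
    "LinearInverseProblem",
    "CovarianceModel",
    "ReMLResult",
    "ReMLOptions",
    "reml_fit",
    "posterior_mean",
    "tikhonov_solve",
]

#: relative jitter added to the marginal covariance diagonal
_JITTER = 1e-10


@dataclass(frozen=True)
class LinearInverseProblem:
    """Measurements Y (channels x time, a vector is treated as one column)
    and forward matrix H (channels x sources)."""

    Y: np.ndarray
    H: np.ndarray

    def __post_init__(self):
        Y = np.atleast_2d(np.asarray(self.Y, float))
        if Y.shape[0] == 1 and self.H.shape[0] != 1:
            Y = Y.T
        object.__setattr__(self, "Y", Y)
        object.__setattr__(self, "H", np.asarray(self.H, float))
        if self.Y.shape[0] != self.H.shape[0]:
            raise ValueError(
                f"Y has {self.Y.shape[0]} channels but H has {self.H.shape[0]}"
            )
        if np.isnan(self.Y).any() or np.isnan(self.H).any():
            raise ValueError("Y and H must be NaN-free")


@dataclass
class CovarianceModel:
    """Ordered covariance components Q_i with coefficients lam_i >= 0.

    ``components`` may hold dense symmetric matrices or 1-D arrays, the
    latter interpreted as diagonals (the common case for i.i.d. and
    weighted-variance priors).  ``fixed=True`` freezes the coefficients at
    their given values during fitting.
    """

    components: list
    coefficients: np.ndarray | None = None
    side: str = "prior"  # "noise" | "prior"
    fixed: bool = False

    def __post_init__(self):
        if not self.components:
            raise ValueError("need at least one covariance component")
        comps = []
        for Q in self.components:
            Q = np.asarray(Q, float)
            if Q.ndim == 2 and not np.allclose(Q, Q.T, atol=1e-12):
                raise ValueError("covariance components must be symmetric")
            comps.append(Q)
        self.components = comps
        if self.coefficients is None:
            self.coefficients = np.ones(len(comps))
        else:
            self.coefficients = np.asarray(self.coefficients, float).copy()
            if np.any(self.coefficients < 0):
                raise ValueError("coefficients must be nonnegative")

    @property
    def n_components(self) -> int:
        return len(self.components)

    def assemble(self, coefficients=None) -> np.ndarray:
        lam = self.coefficients if coefficients is None else coefficients
        n = self.components[0].shape[0]
        C = np.zeros((n, n))
        for lam_i, Q in zip(lam, self.components):
            if Q.ndim == 1:
                C[np.diag_indices(n)] += lam_i * Q
            else:
                C += lam_i * Q
        return C

    @staticmethod
    def identity(n: int, side: str, coefficient: float = 1.0, fixed: bool = False):
        return CovarianceModel(
            components=[np.ones(n)],
            coefficients=np.array([coefficient]),
            side=side,
            fixed=fixed,
        )


@dataclass
class ReMLOptions:
    tol: float = 1e-6          # relative objective change for convergence
    max_iter: int = 128
    max_step: float = 4.0      # cap on log-coefficient updates
    lam_floor: float = 1e-12   # coefficients cannot collapse below this


@dataclass
class ReMLResult:
    beta_hat: np.ndarray
    lambda_noise: np.ndarray
    lambda_prior: np.ndarray
    objective_trace: np.ndarray
    converged: bool
    n_iter: int


def _sandwich(H, Q):
    """H Q H' for dense or diagonal Q."""
    if Q.ndim == 1:
        return (H * Q[None, :]) @ H.T
    return H @ Q @ H.T


def posterior_mean(problem: LinearInverseProblem, C_N: np.ndarray, C_P) -> np.ndarray:
    """Posterior-mean source estimate C_P H' (H C_P H' + C_N)^-1 Y.

    ``C_P`` may be a dense matrix or a 1-D diagonal.  The estimate is
    invariant to scaling C_N and C_P by a common constant.
    """
    H, Y = problem.H, problem.Y
    C_P = np.asarray(C_P, float)
    V = _sandwich(H, C_P) + C_N
    V = V + _JITTER * np.mean(np.diag(V)) * np.eye(V.shape[0])
    W = linalg.solve(V, Y, assume_a="pos")
    if C_P.ndim == 1:
        return C_P[:, None] * (H.T @ W)
    return C_P @ (H.T @ W)


def tikhonov_solve(problem: LinearInverseProblem, lam: float) -> np.ndarray:
    """Ridge solution argmin ||Y - H b||^2 + lam ||b||^2 in closed form."""
    if lam <= 0:
        raise ValueError(f"ridge weight must be positive, got {lam}")
    H, Y = problem.H, problem.Y
    E = H.shape[0]
    # dual form keeps the factorisation at channel size
    return H.T @ linalg.solve(H @ H.T + lam * np.eye(E), Y, assume_a="pos")


def _component_sandwiches(problem, noise_model, prior_model):
    """Marginal-covariance derivatives dV/dlam_i for every component."""
    H = problem.H
    A = []
    for Q in noise_model.components:
        A.append(np.diag(Q) if Q.ndim == 1 else Q)
    for Q in prior_model.components:
        A.append(_sandwich(H, Q))
    return A


def _initial_coefficients(problem, A, free):
    """Split the empirical data variance equally across free components."""
    Y = problem.Y
    T = Y.shape[1]
    total = float(np.trace(Y @ Y.T)) / max(T, 1)
    k = len(A)
    lam = np.empty(k)
    for i, Ai in enumerate(A):
        tr = float(np.trace(Ai))
        lam[i] = (total / k) / tr if tr > 0 else 1.0
    return np.maximum(lam, 1e-12)


def reml_fit(
    problem: LinearInverseProblem,
    noise_model: CovarianceModel,
    prior_model: CovarianceModel,
    options: ReMLOptions | None = None,
) -> ReMLResult:
    """Estimate covariance hyperparameters and the posterior-mean sources.

    Maximises F(lam) = -1/2 [ T log|V| + tr(V^-1 Y Y') ] with
    V = sum lam_N,i Q_N,i + H (sum lam_P,i Q_P,i) H' by Fisher scoring on
    log(lam) with Levenberg-Marquardt damping; steps that decrease the
    objective are rejected and retried with stronger damping, so the
    accepted objective trace is non-decreasing.
    """
    opts = options or ReMLOptions()
    H, Y = problem.H, problem.Y
    E, T = Y.shape[0], Y.shape[1]

    if not np.any(Y):
        warnings.warn("all-zero measurements: returning zero source estimate")
        return ReMLResult(
            beta_hat=np.zeros((H.shape[1], T)),
            lambda_noise=np.asarray(noise_model.coefficients, float),
            lambda_prior=np.asarray(prior_model.coefficients, float),
            objective_trace=np.array([]),
            converged=True,
            n_iter=0,
        )

    kN = noise_model.n_components
    A = _component_sandwiches(problem, noise_model, prior_model)
    k = len(A)
    fixed = np.zeros(k, bool)
    if noise_model.fixed:
        fixed[:kN] = True
    if prior_model.fixed:
        fixed[kN:] = True

    lam = np.empty(k)
    lam_given = np.concatenate(
        [np.asarray(noise_model.coefficients, float), np.asarray(prior_model.coefficients, float)]
    )
    if fixed.all():
        lam = lam_given
    else:
        lam_init = _initial_coefficients(problem, A, ~fixed)
        lam = np.where(fixed, lam_given, lam_init)

    S = Y @ Y.T
    jitter_eye = np.eye(E)

    def objective_and_grad(lam):
        V = sum(l * Ai for l, Ai in zip(lam, A))
        V = V + _JITTER * np.mean(np.diag(V)) * jitter_eye
        try:
            cf = linalg.cho_factor(V)
        except linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "marginal covariance is singular after jitter"
            ) from err
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        Vinv = linalg.cho_solve(cf, jitter_eye)
        F = -0.5 * (T * logdet + float(np.sum(Vinv * S)))
        VA = [Vinv @ Ai for Ai in A]
        VS = Vinv @ S
        g = np.array(
            [
                0.5 * (float(np.sum(VAi * VS.T)) - T * float(np.trace(VAi)))
                for VAi in VA
            ]
        )
        I = np.empty((k, k))
        for i in range(k):
            for j in range(i, k):
                I[i, j] = I[j, i] = 0.5 * T * float(np.sum(VA[i] * VA[j].T))
        return F, g, I

    trace = []
    converged = False
    n_iter = 0
    if fixed.all():
        F, _, _ = objective_and_grad(lam)
        trace.append(F)
        converged = True
    else:
        free = ~fixed
        damping = 1e-6
        F, g, I = objective_and_grad(lam)
        trace.append(F)
        for n_iter in range(1, opts.max_iter + 1):
            # Fisher scoring in log-space on the free coefficients
            gl = (g * lam)[free]
            Il = (I * np.outer(lam, lam))[np.ix_(free, free)]
            accepted = False
            for _ in range(32):
                M = Il + damping * np.diag(np.maximum(np.diag(Il), 1e-12))
                try:
                    step = np.linalg.solve(M, gl)
                except np.linalg.LinAlgError:
                    damping *= 10
                    continue
                step = np.clip(step, -opts.max_step, opts.max_step)
                lam_new = lam.copy()
                lam_new[free] = np.maximum(
                    lam[free] * np.exp(step), opts.lam_floor
                )
                try:
                    F_new, g_new, I_new = objective_and_grad(lam_new)
                except np.linalg.LinAlgError:
                    damping *= 10
                    continue
                if F_new >= F - 1e-9 * abs(F):
                    accepted = True
                    break
                damping *= 10
            if not accepted:
                logger.info("ReML: no acceptable step at iteration %d", n_iter)
                break
            damping = max(damping / 10, 1e-8)
            dF = F_new - F
            lam, F, g, I = lam_new, F_new, g_new, I_new
            trace.append(F)
            if abs(dF) < opts.tol * max(abs(F), 1.0):
                converged = True
                break
        logger.info(
            "ReML: %d iterations, objective %.6g, converged=%s", n_iter, F, converged
        )

    lam_noise = lam[:kN]
    lam_prior = lam[kN:]
    C_N = noise_model.assemble(lam_noise)
    # keep prior assembly diagonal when all prior components are diagonal
    if all(Q.ndim == 1 for Q in prior_model.components):
        C_P = np.zeros(prior_model.components[0].shape[0])
        for l, Q in zip(lam_prior, prior_model.components):
            C_P += l * Q
    else:
        C_P = prior_model.assemble(lam_prior)
    beta = posterior_mean(problem, C_N, C_P)
    return ReMLResult(
        beta_hat=beta,
        lambda_noise=lam_noise,
        lambda_prior=lam_prior,
        objective_trace=np.asarray(trace),
        converged=converged,
        n_iter=n_iter,
    )
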