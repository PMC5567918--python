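"""Laplace-approximate logistic mixed model with crossed random intercepts.

The model for observation *i* on dyad ``d(i)`` = {a(i), b(i)} is

    logit P(y_i = 1) = x_i' beta + u_{d(i)} + v_{a(i)} + v_{b(i)},
    u_d ~ N(0, sigma_dyad^2),  v_j ~ N(0, sigma_bird^2),

with the bird intercepts shared across every dyad containing the bird
(crossed random effects nested within dyad).  No installed Python package
fits this structure by maximum likelihood, so the machinery lives here.

Random effects are scaled, ``u = sigma * b`` with ``b ~ N(0, I)``, so the
variance components can reach zero smoothly; at ``sigma = 0`` the marginal
likelihood reduces exactly to ordinary logistic regression.  The inner
problem (joint mode of (beta, b), or of b alone at fixed beta) is solved by
damped Newton iterations exploiting the sparse random-effect design; the
outer problem optimises the profiled Laplace likelihood over the two
standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, sparse
from scipy.linalg import cho_factor, cho_solve

_BETA_BOUND = 15.0  # |beta| beyond this is treated as separation


@dataclass
class GlmmControl:
    max_inner: int = 100
    inner_tol: float = 1e-10
    outer_tol: float = 1e-6
    fix_sigma_dyad: float | None = None
    fix_sigma_bird: float | None = None


@dataclass
class LaplaceFit:
    beta: np.ndarray
    se: np.ndarray
    sigma_dyad: float
    sigma_bird: float
    loglik: float
    converged: bool
    separation: bool
    n_obs: int
    random_modes: np.ndarray


def _logistic_loglik(y, eta):
    # sum y*eta - log(1 + exp(eta)), stable for large |eta|
    return float(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))


def build_random_design(dyad_idx, bird_a_idx, bird_b_idx, n_dyads, n_birds):
    """Sparse (n x (n_dyads + n_birds)) indicator design for (u, v)."""
    n = len(dyad_idx)
    rows = np.repeat(np.arange(n), 3)
    cols = np.column_stack(
        [dyad_idx, n_dyads + bird_a_idx, n_dyads + bird_b_idx]
    ).ravel()
    data = np.ones(3 * n)
    Z = sparse.csr_matrix((data, (rows, cols)), shape=(n, n_dyads + n_birds))
    return Z


def _penalized_mode(y, X, Z, scale, beta, b, optimize_beta, control):
    """Damped Newton for the joint penalized log-likelihood.

    ``scale`` is the per-column standard deviation of the scaled random
    effects (length q).  When ``optimize_beta`` is False beta is held fixed
    and only b is updated.  Returns (beta, b, W, chol of C, converged) where
    C = S Z' W Z S + I is the b-block Hessian at the mode.
    """
    p = X.shape[1]
    Zs = Z.multiply(scale[None, :]).tocsr()
    converged = False
    c_factor = None
    for _ in range(control.max_inner):
        eta = X @ beta + Zs @ b
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        r = y - mu
        g_b = Zs.T @ r - b
        C = (Zs.T @ sparse.diags(w) @ Zs).toarray()
        C[np.diag_indices_from(C)] += 1.0
        c_factor = cho_factor(C, lower=True)
        if optimize_beta:
            g_beta = X.T @ r
            A = X.T @ (w[:, None] * X)
            B = Zs.T @ (w[:, None] * X)  # q x p
            CinvB = cho_solve(c_factor, B)
            CinvGb = cho_solve(c_factor, g_b)
            S_beta = A - B.T @ CinvB  # Schur complement
            try:
                step_beta = np.linalg.solve(S_beta, g_beta - B.T @ CinvGb)
            except np.linalg.LinAlgError:
                step_beta = np.linalg.lstsq(S_beta, g_beta - B.T @ CinvGb,
                                            rcond=None)[0]
            step_b = CinvGb - CinvB @ step_beta
        else:
            step_beta = np.zeros(p)
            step_b = cho_solve(c_factor, g_b)
        # damped update on the penalized objective
        f0 = _logistic_loglik(y, eta) - 0.5 * float(b @ b)
        alpha = 1.0
        for _ in range(30):
            beta_new = beta + alpha * step_beta
            b_new = b + alpha * step_b
            eta_new = X @ beta_new + Zs @ b_new
            f1 = _logistic_loglik(y, eta_new) - 0.5 * float(b_new @ b_new)
            if f1 >= f0 - 1e-12:
                break
            alpha *= 0.5
        beta, b = beta_new, b_new
        grad_norm = max(
            float(np.abs(g_b).max(initial=0.0)),
            float(np.abs(X.T @ r).max(initial=0.0)) if optimize_beta else 0.0,
        )
        step_max = max(
            float(np.abs(alpha * step_b).max(initial=0.0)),
            float(np.abs(alpha * step_beta).max(initial=0.0)),
        )
        if grad_norm < control.inner_tol * (1.0 + abs(f0)) or step_max < 1e-12:
            converged = True
            break
    # recompute curvature at the final mode
    eta = X @ beta + Zs @ b
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    C = (Zs.T @ sparse.diags(w) @ Zs).toarray()
    C[np.diag_indices_from(C)] += 1.0
    c_factor = cho_factor(C, lower=True)
    return beta, b, w, c_factor, converged


def _laplace_from_mode(y, X, Z, scale, beta, b, c_factor):
    Zs = Z.multiply(scale[None, :]).tocsr()
    eta = X @ beta + Zs @ b
    logdet = 2.0 * float(np.sum(np.log(np.diag(c_factor[0]))))
    return _logistic_loglik(y, eta) - 0.5 * float(b @ b) - 0.5 * logdet


def laplace_loglik(y, X, Z, n_dyads, sigma_dyad, sigma_bird, beta,
                   control: GlmmControl | None = None):
    """Laplace marginal log-likelihood at fixed (beta, sigma).

    Modes over the random effects only; useful for external comparison
    against quadrature on models with a single grouping factor
    (set ``sigma_bird = 0``).
    """
    control = control or GlmmControl()
    q = Z.shape[1]
    scale = np.r_[np.full(n_dyads, float(sigma_dyad)),
                  np.full(q - n_dyads, float(sigma_bird))]
    beta = np.asarray(beta, dtype=float)
    b = np.zeros(q)
    beta, b, _, c_factor, _ = _penalized_mode(
        y, X, Z, scale, beta, b, optimize_beta=False, control=control
    )
    return _laplace_from_mode(y, X, Z, scale, beta, b, c_factor)


def fit_laplace_glmm(y, X, dyad_idx, bird_a_idx, bird_b_idx,
                     control: GlmmControl | None = None) -> LaplaceFit:
    """Maximum (Laplace) likelihood fit of the crossed-intercept logit model.

    The fixed effects are profiled out in the inner Newton solve; the outer
    optimisation runs over the two standard deviations (on a square-root
    scale so zero is attainable).  Variance components can be pinned via the
    control's ``fix_sigma_*`` fields, in which case the model degenerates
    gracefully (both pinned to zero gives plain logistic regression).
    """
    control = control or GlmmControl()
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    n_dyads = int(np.max(dyad_idx)) + 1 if len(dyad_idx) else 0
    n_birds = int(max(np.max(bird_a_idx), np.max(bird_b_idx))) + 1 if n else 0
    Z = build_random_design(dyad_idx, bird_a_idx, bird_b_idx, n_dyads, n_birds)
    q = Z.shape[1]

    state = {"beta": np.zeros(p), "b": np.zeros(q)}

    def scale_vec(sd, sb):
        return np.r_[np.full(n_dyads, sd), np.full(n_birds, sb)]

    def profiled_nll(sd, sb):
        beta, b, _, c_factor, _ = _penalized_mode(
            y, X, Z, scale_vec(sd, sb), state["beta"].copy(),
            state["b"].copy(), optimize_beta=True, control=control,
        )
        state["beta"], state["b"] = beta, b
        return -_laplace_from_mode(y, X, Z, scale_vec(sd, sb), beta, b,
                                   c_factor), beta, b

    free = []
    if control.fix_sigma_dyad is None:
        free.append("dyad")
    if control.fix_sigma_bird is None:
        free.append("bird")

    def unpack(z):
        zz = iter(z)
        sd = (next(zz) ** 2 if "dyad" in free else control.fix_sigma_dyad)
        sb = (next(zz) ** 2 if "bird" in free else control.fix_sigma_bird)
        return float(sd), float(sb)

    outer_ok = True
    if free:
        x0 = np.full(len(free), np.sqrt(0.7))

        def objective(z):
            return profiled_nll(*unpack(z))[0]

        res = optimize.minimize(
            objective, x0, method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": control.outer_tol,
                     "maxfev": 400},
        )
        sd, sb = unpack(res.x)
        outer_ok = bool(res.success)
    else:
        sd, sb = float(control.fix_sigma_dyad), float(control.fix_sigma_bird)

    nll, beta, b = profiled_nll(sd, sb)
    # final curvature for SEs
    scale = scale_vec(sd, sb)
    beta, b, w, c_factor, inner_ok = _penalized_mode(
        y, X, Z, scale, beta, b, optimize_beta=True, control=control
    )
    loglik = _laplace_from_mode(y, X, Z, scale, beta, b, c_factor)
    Zs = Z.multiply(scale[None, :]).tocsr()
    A = X.T @ (w[:, None] * X)
    B = Zs.T @ (w[:, None] * X)
    S_beta = A - B.T @ cho_solve(c_factor, B)
    try:
        vcov = np.linalg.inv(S_beta)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(S_beta)
    se = np.sqrt(np.maximum(np.diag(vcov), 0.0))
    separation = bool(np.any(np.abs(beta) > _BETA_BOUND))
    return LaplaceFit(
        beta=beta, se=se, sigma_dyad=sd, sigma_bird=sb, loglik=loglik,
        converged=bool(outer_ok and inner_ok and not separation),
        separation=separation, n_obs=n, random_modes=scale * b,
    )
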