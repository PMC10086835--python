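"""Penalized maximum-likelihood fitting of the cumulative logistic mixed model.

The model: an ordinal response ``y_ij`` in 1..M_y arises from a continuous
latent response ``l_ij = f(trait_i, x_ij) + u_i + eps_ij`` cut at increasing
thresholds ``theta_1 < ... < theta_{M_y - 1}`` (anchored at ``theta_1 = -1``),
with subject random intercepts ``u_i ~ N(0, sigma_u^2)`` and standard logistic
errors.  Equivalently ``logit P(Y_ij <= m) = theta_m - f(.) - u_i``.

Fitting maximizes the marginal likelihood -- the random intercept integrated
out by Gauss-Hermite quadrature -- minus the quadratic linearity penalty
``(lambda/2) zeta' P zeta``.  The optimizer works on a fixed-node quadrature
in the standardized scale ``u = sigma_u * z`` (exact analytic gradients, the
sigma dependence entering only through the node positions); the reported
log-likelihood is recomputed with adaptive quadrature centered at the
per-subject posterior mode.  Penalized problems are preconditioned by
whitening the penalty eigen-directions so quasi-Newton steps stay well scaled
for shrinkage parameters up to 1e8.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize
from scipy.special import log_expit, logsumexp

from .panel import KeySet, OrdinalPanel, TraitSummary
from .penalty import CoefLayout, PenaltySpec, zeta_to_f

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "FitResult",
    "DEFAULT_LAMBDA_GRID",
    "category_logprob",
    "marginal_loglik",
    "fit",
    "select_lambda",
    "edf",
    "aic",
]

DEFAULT_LAMBDA_GRID = np.logspace(-2.0, 6.0, 17)


# ---------------------------------------------------------------------------
# specs and results


@dataclass
class ModelSpec:
    """What to fit: parametrization, penalty, link structure, quadrature.

    mode is one of ``linear`` (3 fixed effects: intercept, trait deviation,
    state deviation), ``unpenalized`` or ``penalized`` (both on the full
    state-trait parametrization; unpenalized is the lambda = 0 special case).
    """

    m_y: int
    mode: str = "penalized"
    layout: CoefLayout | None = None
    penalty: PenaltySpec | None = None
    lambda_: float | str = "auto"
    quadrature_nodes: int = 15  # adaptive GH nodes for reported log-likelihood
    fit_nodes: int = 21  # fixed-node GH used inside the optimizer
    lagged: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("linear", "unpenalized", "penalized"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "penalized" and self.penalty is None:
            raise ValueError("mode='penalized' requires a PenaltySpec")


@dataclass
class FitResult:
    """Estimates, diagnostics, and information criteria for one fit."""

    mode: str
    zeta_hat: np.ndarray  # linear mode: (beta0, beta1, beta2) (+ beta_lag)
    theta_hat: np.ndarray
    sigma_u_hat: float
    u_hat: dict
    lambda_: float
    loglik: float
    edf_fixed: float
    edf_parts: dict
    edf_aic: float  # shrinkage-uncertainty corrected EDF tr(2M - M^2) used in AIC
    aic: float
    converged: bool
    grad_norm: float
    n_obs: int
    n_subjects: int
    n_iter: int
    layout: CoefLayout | None = None
    f_hat: dict | None = None  # f on representative cells (state-trait modes)
    f_hat_obs: np.ndarray | None = None  # fixed-effect latent part per row
    beta_lag: float | None = None
    hessian_fixed: np.ndarray | None = None  # negative Hessian, fixed effects
    gh_loglik: float = np.nan  # fixed-node quadrature value at the optimum
    global_median: int | None = None

    @property
    def coef_names(self) -> list:
        if self.mode == "linear":
            names = ["beta0", "beta1", "beta2"]
        else:
            names = self.layout.names
        if self.beta_lag is not None:
            names = names + ["beta_lag"]
        return names

    def implied_f(self, cells) -> dict:
        """f on the given cells: estimated surface, or for the linear mode
        b0 + b1 (r - global median) + b2 (s - r)."""
        if self.mode == "linear":
            b0, b1, b2 = self.zeta_hat[:3]
            g = self.global_median
            return {(r, s): b0 + b1 * (r - g) + b2 * (s - r) for r, s in cells}
        f = dict(self.f_hat)
        return {c: f[c] for c in cells}

    def summary_dict(self) -> dict:
        return {
            "mode": self.mode,
            "coefficients": dict(zip(self.coef_names, map(float, self.zeta_hat))),
            "theta": [float(t) for t in self.theta_hat],
            "sigma_u": float(self.sigma_u_hat),
            "lambda": float(self.lambda_),
            "loglik": float(self.loglik),
            "edf_fixed": float(self.edf_fixed),
            "edf_aic": float(self.edf_aic),
            "edf_parts": {k: float(v) for k, v in self.edf_parts.items()},
            "aic": float(self.aic),
            "converged": bool(self.converged),
            "grad_norm": float(self.grad_norm),
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
        }


# ---------------------------------------------------------------------------
# data preparation


@dataclass
class _ModelData:
    X: np.ndarray
    y: np.ndarray
    starts: np.ndarray
    subj_idx: np.ndarray
    subjects: list
    m_y: int

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def _design(
    spec: ModelSpec, panel: OrdinalPanel, traits: TraitSummary, keys: KeySet | None
) -> _ModelData:
    df = panel.data
    subj = df["subject"].to_numpy()
    # rows are sorted by subject at load; group boundaries for reduceat
    change = np.flatnonzero(np.r_[True, subj[1:] != subj[:-1]])
    subjects = list(subj[change])
    subj_idx = np.cumsum(np.r_[False, subj[1:] != subj[:-1]])
    x = df["x"].to_numpy()
    trait = df["subject"].map(traits.person_median).to_numpy()
    if spec.mode == "linear":
        g = traits.global_median
        X = np.column_stack(
            [np.ones(len(df)), (trait - g).astype(float), (x - trait).astype(float)]
        )
    else:
        layout = spec.layout
        X = np.zeros((len(df), layout.n_params))
        X[:, 0] = 1.0
        tau_col = {r: layout.tau_index(r) for r in layout.tau_levels}
        gam_col = {c: layout.gamma_index(c) for c in layout.gamma_cells}
        merge = keys.merge_map if keys is not None else {}
        trait_only = not layout.gamma_cells
        for i, (r, s) in enumerate(zip(trait, x)):
            cell = (int(r), int(s))
            cell = merge.get(cell, cell)
            if trait_only:  # trait-only model: every obs reads f(r, r)
                cell = (int(r), int(r))
            rr, ss = cell
            if rr != layout.ref_trait:
                X[i, tau_col[rr]] = 1.0
            if rr != ss:
                X[i, gam_col[(rr, ss)]] = 1.0
    if spec.lagged:
        if "y_lag" not in df.columns:
            raise ValueError("lagged model requires a y_lag column")
        X = np.column_stack([X, df["y_lag"].to_numpy(dtype=float)])
    y = df["y"].to_numpy(dtype=np.int64)
    return _ModelData(
        X=X, y=y, starts=change, subj_idx=subj_idx, subjects=subjects, m_y=panel.m_y
    )


@lru_cache(maxsize=8)
def _hermgauss(n: int):
    t, w = np.polynomial.hermite.hermgauss(n)
    return t, np.log(w) - 0.5 * np.log(np.pi)


# ---------------------------------------------------------------------------
# category probability kernel


def _cat_terms(A, B, order: int = 0):
    """Stable log P(theta_{m-1} < l <= theta_m) and its u-derivative pieces.

    A = upper - eta - u (may be +inf), B = lower - eta - u (may be -inf).
    Returns logp [, d = dlogp/du, E1 = pdf(A)/p, E0 = pdf(B)/p [, c = d2logp/du2]].
    """
    with np.errstate(invalid="ignore", over="ignore"):
        logFA = log_expit(A)
        logFmB = log_expit(-B)
        gap = B - A  # -inf when either bound is infinite; both finite: < 0
        gap = np.where(np.isnan(gap), -np.inf, gap)
        logp = logFA + logFmB + np.log(-np.expm1(gap))
        if order == 0:
            return logp
        # logistic pdf via log f(z) = 2 log F(z) - z; -inf at infinite bounds
        logfA = 2.0 * logFA - A
        logfB = 2.0 * logFmB + B
        E1 = np.exp(logfA - logp)
        E0 = np.exp(logfB - logp)
        d = E0 - E1
        if order == 1:
            return logp, d, E1, E0
        # f'(z) = f(z) (1 - 2 F(z)); the E terms vanish at infinite bounds
        kA = 1.0 - 2.0 * np.exp(logFA)
        kB = 1.0 + 2.0 * np.expm1(logFmB)  # = 1 - 2 F(B)
        c = E1 * kA - E0 * kB - d * d
    return logp, d, E1, E0, c


def category_logprob(eta, theta, m: int) -> np.ndarray | float:
    """log P(Y = m | eta) for the cumulative logistic model.

    ``theta`` are the M_y - 1 increasing cutpoints; theta_0 = -inf and
    theta_{M_y} = +inf are implicit, so probabilities over m = 1..M_y sum to 1.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(np.diff(theta) <= 0):
        raise ValueError("cutpoints must be strictly increasing")
    m_y = theta.size + 1
    if not 1 <= m <= m_y:
        raise ValueError(f"category {m} outside 1..{m_y}")
    pad = np.concatenate([[-np.inf], theta, [np.inf]])
    eta = np.asarray(eta, dtype=float)
    out = _cat_terms(pad[m] - eta, pad[m - 1] - eta)
    return out if out.shape else float(out)


def _theta_from_delta(delta: np.ndarray) -> np.ndarray:
    th = np.empty(delta.size + 1)
    th[0] = -1.0
    th[1:] = -1.0 + np.cumsum(np.exp(delta))
    return th


def _bounds(md: _ModelData, theta: np.ndarray):
    pad = np.concatenate([[-np.inf], theta, [np.inf]])
    return pad[md.y], pad[md.y - 1]


# ---------------------------------------------------------------------------
# fixed-node quadrature objective (exact analytic gradient)


def _gh_eval(params, md: _ModelData, t_nodes, log_w, P=None, lam: float = 0.0):
    """Negative penalized GH log-likelihood and its gradient.

    params = (zeta, delta, log sigma_u); nodes u_k = sqrt(2) sigma t_k.
    """
    q = md.X.shape[1]
    m_y = md.m_y
    zeta = params[:q]
    delta = params[q : q + m_y - 2]
    logsig = params[-1]
    sigma = np.exp(logsig)
    theta = _theta_from_delta(delta)
    up, lo = _bounds(md, theta)
    eta = md.X @ zeta
    u = np.sqrt(2.0) * sigma * t_nodes
    A = up[:, None] - eta[:, None] - u[None, :]
    B = lo[:, None] - eta[:, None] - u[None, :]
    logp, d, E1, E0 = _cat_terms(A, B, order=1)
    a = np.add.reduceat(logp, md.starts, axis=0) + log_w[None, :]
    lli = logsumexp(a, axis=1)
    ll = float(lli.sum())
    r = np.exp(a - lli[:, None])
    R = r[md.subj_idx]
    g_eta = (R * d).sum(axis=1)
    g_zeta = md.X.T @ g_eta
    e1 = (R * E1).sum(axis=1)
    e0 = (R * E0).sum(axis=1)
    g_th = np.bincount(md.y - 1, weights=e1, minlength=m_y)[: m_y - 1]
    lower_ok = md.y >= 2
    g_th -= np.bincount(
        np.where(lower_ok, md.y - 2, 0),
        weights=np.where(lower_ok, e0, 0.0),
        minlength=m_y,
    )[: m_y - 1]
    tail = np.cumsum(g_th[::-1])[::-1]
    g_delta = np.exp(delta) * tail[1:]
    S = np.add.reduceat(d, md.starts, axis=0)
    g_logsig = float((r * S * u[None, :]).sum())
    grad = np.concatenate([g_zeta, g_delta, [g_logsig]])
    pen = 0.0
    if P is not None and lam > 0.0:
        Pz = P @ zeta
        pen = 0.5 * lam * float(zeta @ Pz)
        grad = grad.copy()
        grad[:q] -= lam * Pz
    return -(ll - pen), -grad, ll


def _hessian_zeta(params, md: _ModelData, t_nodes, log_w) -> np.ndarray:
    """Negative Hessian of the (unpenalized) GH log-likelihood w.r.t. zeta."""
    q = md.X.shape[1]
    m_y = md.m_y
    zeta = params[:q]
    delta = params[q : q + m_y - 2]
    sigma = np.exp(params[-1])
    theta = _theta_from_delta(delta)
    up, lo = _bounds(md, theta)
    eta = md.X @ zeta
    u = np.sqrt(2.0) * sigma * t_nodes
    A = up[:, None] - eta[:, None] - u[None, :]
    B = lo[:, None] - eta[:, None] - u[None, :]
    logp, d, E1, E0, c = _cat_terms(A, B, order=2)
    a = np.add.reduceat(logp, md.starts, axis=0) + log_w[None, :]
    lli = logsumexp(a, axis=1)
    r = np.exp(a - lli[:, None])
    cbar = (r[md.subj_idx] * c).sum(axis=1)
    M1 = md.X.T @ (md.X * cbar[:, None])
    K = t_nodes.size
    V = np.stack(
        [np.add.reduceat(md.X * d[:, k : k + 1], md.starts, axis=0) for k in range(K)]
    )  # (K, I, q)
    M2 = np.einsum("ik,kip,kiq->pq", r, V, V, optimize=True)
    m = np.einsum("ik,kip->ip", r, V)
    M3 = m.T @ m
    H = -(M1 + M2 - M3)
    return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# adaptive quadrature (reported log-likelihood, posterior modes)


def _posterior_modes(md: _ModelData, zeta, theta, sigma):
    """Per-subject mode and curvature of log p(y_i | u) + log N(u; 0, sigma^2)."""
    up, lo = _bounds(md, theta)
    eta = md.X @ zeta
    u = np.zeros(md.n_subjects)
    h = np.full(md.n_subjects, -1.0 / sigma**2)
    for _ in range(100):
        uo = u[md.subj_idx]
        _, d, _, _, c = _cat_terms(up - eta - uo, lo - eta - uo, order=2)
        g = np.add.reduceat(d, md.starts) - u / sigma**2
        h = np.add.reduceat(c, md.starts) - 1.0 / sigma**2
        step = np.clip(-g / h, -5.0, 5.0)
        u = u + step
        if np.max(np.abs(g)) < 1e-12:
            break
    return u, h


def _agq_loglik(md: _ModelData, zeta, theta, sigma, n_nodes: int):
    """Adaptive Gauss-Hermite marginal log-likelihood; returns (ll, u_hat)."""
    if sigma < 1e-10:  # degenerate mixture: independent ordinal likelihood
        up, lo = _bounds(md, theta)
        eta = md.X @ zeta
        logp = _cat_terms(up - eta, lo - eta)
        return float(logp.sum()), np.zeros(md.n_subjects)
    u_hat, curv = _posterior_modes(md, zeta, theta, sigma)
    s_hat = 1.0 / np.sqrt(-curv)
    t, log_w = _hermgauss(n_nodes)
    U = u_hat[:, None] + np.sqrt(2.0) * s_hat[:, None] * t[None, :]
    up, lo = _bounds(md, theta)
    eta = md.X @ zeta
    Uo = U[md.subj_idx]
    logp = _cat_terms(up[:, None] - eta[:, None] - Uo, lo[:, None] - eta[:, None] - Uo)
    gsum = np.add.reduceat(logp, md.starts, axis=0)
    h = gsum - U**2 / (2.0 * sigma**2) - np.log(sigma) - 0.5 * np.log(2.0 * np.pi)
    # log_w from _hermgauss already includes -log(sqrt(pi)); undo for raw weights
    lli = (
        0.5 * np.log(2.0)
        + np.log(s_hat)
        + logsumexp(log_w + 0.5 * np.log(np.pi) + t**2 + h, axis=1)
    )
    if not np.all(np.isfinite(lli)):
        bad = md.subjects[int(np.flatnonzero(~np.isfinite(lli))[0])]
        raise FloatingPointError(f"non-finite marginal likelihood for subject {bad!r}")
    return float(lli.sum()), u_hat


def marginal_loglik(
    spec: ModelSpec,
    panel: OrdinalPanel,
    traits: TraitSummary,
    zeta,
    theta,
    sigma_u: float,
    keys: KeySet | None = None,
) -> float:
    """Marginal log-likelihood at given parameters, by adaptive quadrature
    (``spec.quadrature_nodes`` nodes centered at each subject's posterior mode)."""
    theta = np.asarray(theta, dtype=float)
    if np.any(np.diff(theta) <= 0):
        raise ValueError("cutpoints must be strictly increasing")
    md = _design(spec, panel, traits, keys)
    ll, _ = _agq_loglik(md, np.asarray(zeta, float), theta, float(sigma_u), spec.quadrature_nodes)
    return ll


# ---------------------------------------------------------------------------
# fitting


def _initial_params(md: _ModelData) -> np.ndarray:
    counts = np.bincount(md.y, minlength=md.m_y + 1)[1:]
    if np.any(counts == 0):
        empty = [m + 1 for m in range(md.m_y) if counts[m] == 0]
        raise ValueError(f"empty response categories: {empty}")
    cum = np.cumsum(counts)[:-1] / counts.sum()
    logit = np.log(cum / (1.0 - cum))
    theta0 = logit - logit[0] - 1.0  # shift so theta_1 = -1
    delta0 = np.log(np.diff(theta0))
    q = md.X.shape[1]
    return np.concatenate([np.zeros(q), delta0, [0.0]])


def _padded_penalty(spec: ModelSpec, q: int) -> np.ndarray | None:
    if spec.mode != "penalized" or spec.penalty is None:
        return None
    P = spec.penalty.p_matrix
    if P.shape[0] == q:
        return P
    out = np.zeros((q, q))  # lagged column (or extras) carry no penalty
    out[: P.shape[0], : P.shape[1]] = P
    return out


def fit(
    spec: ModelSpec,
    panel: OrdinalPanel,
    traits: TraitSummary,
    keys: KeySet | None = None,
    lam: float = 0.0,
    *,
    init: np.ndarray | None = None,
    gtol: float = 1e-6,
    ftol: float = 1e-8,
    maxiter: int = 500,
    _md: _ModelData | None = None,
) -> FitResult:
    """Maximize the penalized marginal log-likelihood for one lambda.

    Deterministic: cutpoints initialized from pooled cumulative response
    frequencies (shifted so theta_1 = -1), zeta = 0, sigma_u = 1, unless a
    warm-start ``init`` is given.  Convergence: relative objective change
    below ``ftol`` or projected-gradient max norm below ``gtol``, within
    ``maxiter`` quasi-Newton iterations.  Non-convergence is flagged, not
    raised.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    md = _design(spec, panel, traits, keys) if _md is None else _md
    q = md.X.shape[1]
    m_y = md.m_y
    t_nodes, log_w = _hermgauss(spec.fit_nodes)
    P = _padded_penalty(spec, q)
    x0 = _initial_params(md) if init is None else np.asarray(init, dtype=float)

    use_precond = P is not None and lam > 0.0
    if use_precond:
        evals, Q = np.linalg.eigh(P)
        evals = np.clip(evals, 0.0, None)
        scale = 1.0 / np.sqrt(1.0 + lam * evals)
        T = Q * scale[None, :]
        Tinv = (Q * (1.0 / scale)[None, :]).T  # = diag(1/scale) Q^T

        def to_nat(popt):
            out = popt.copy()
            out[:q] = T @ popt[:q]
            return out

        def to_opt(pnat):
            out = pnat.copy()
            out[:q] = Tinv @ pnat[:q]
            return out

    else:

        def to_nat(popt):
            return popt

        def to_opt(pnat):
            return pnat

    last_ll = [np.nan]

    def objective(popt):
        pnat = to_nat(popt)
        f, g, ll = _gh_eval(pnat, md, t_nodes, log_w, P=P, lam=lam)
        last_ll[0] = ll
        if use_precond:
            g = g.copy()
            g[:q] = T.T @ g[:q]
        return f, g

    # log sigma_u bounded below so a boundary sigma_u -> 0 cannot stall the
    # line search; e^-8 is numerically zero relative to the logistic errors
    bounds = [(None, None)] * (q + m_y - 2) + [(-8.0, 8.0)]
    res = minimize(
        objective,
        to_opt(x0),
        jac=True,
        bounds=bounds,
        method="L-BFGS-B",
        options={
            "maxiter": maxiter,
            "maxfun": 20 * maxiter,
            "ftol": ftol,
            "gtol": gtol,
            "maxcor": 25,
        },
    )
    params = to_nat(res.x)
    _, grad_nat, gh_ll = _gh_eval(params, md, t_nodes, log_w, P=P, lam=lam)
    zeta = params[:q]
    theta = _theta_from_delta(params[q : q + m_y - 2])
    sigma = float(np.exp(params[-1]))
    loglik, u_hat = _agq_loglik(md, zeta, theta, sigma, spec.quadrature_nodes)
    H = _hessian_zeta(params, md, t_nodes, log_w)

    if spec.mode == "linear":
        edf_fixed, parts, edf_corr = 3.0, {"alpha": 1.0, "tau": 1.0, "gamma": 1.0}, 3.0
        layout = None
        f_hat = None
    else:
        layout = spec.layout
        edf_fixed, parts, edf_corr = _edf_full(H, P, lam, layout)
        f_hat = zeta_to_f(zeta[: layout.n_params], layout)
    aic_val = -2.0 * loglik + 2.0 * (edf_corr + (m_y - 2) + 1)

    converged = bool(res.success)
    if not converged:
        logger.warning("fit did not converge: %s", res.message)
    return FitResult(
        mode=spec.mode,
        zeta_hat=zeta,
        theta_hat=theta,
        sigma_u_hat=sigma,
        u_hat=dict(zip(md.subjects, u_hat)),
        lambda_=lam,
        loglik=loglik,
        edf_fixed=edf_fixed,
        edf_parts=parts,
        edf_aic=edf_corr,
        aic=aic_val,
        converged=converged,
        grad_norm=float(np.max(np.abs(grad_nat))),
        n_obs=md.n_obs,
        n_subjects=md.n_subjects,
        n_iter=int(res.nit),
        layout=layout,
        f_hat=f_hat,
        f_hat_obs=md.X[:, : (3 if spec.mode == "linear" else spec.layout.n_params)]
        @ zeta[: (3 if spec.mode == "linear" else spec.layout.n_params)],
        beta_lag=float(zeta[-1]) if spec.lagged else None,
        hessian_fixed=H,
        gh_loglik=gh_ll,
        global_median=traits.global_median,
    )


def _edf_full(H: np.ndarray, P: np.ndarray | None, lam: float, layout):
    """(classical EDF, per-term partition, corrected EDF tr(2M - M^2))."""
    p = H.shape[0]
    if P is None or lam == 0.0:
        diag = np.ones(p)
        total = float(p)
        total_corr = float(p)
    else:
        try:
            M = np.linalg.solve(H + lam * P, H)
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError(
                "singular penalized information; increase lambda or merge rare cells"
            ) from e
        diag = np.diag(M)
        total = float(np.trace(M))
        total_corr = float(2.0 * total - np.einsum("ij,ji->", M, M))
    parts = {}
    if layout is not None:
        parts["alpha"] = float(diag[0])
        parts["tau"] = float(diag[layout.tau_slice].sum())
        parts["gamma"] = float(diag[layout.gamma_slice].sum())
        if p > layout.n_params:  # unpenalized extras (e.g. lagged response)
            parts["extra"] = float(diag[layout.n_params :].sum())
    return total, parts, total_corr


def edf(H: np.ndarray, P: np.ndarray | None, lam: float, layout: CoefLayout | None):
    """Effective degrees of freedom trace[(H + lambda P)^{-1} H], partitioned.

    H is the negative Hessian of the unpenalized log-likelihood at the
    estimate, restricted to fixed effects.  At lambda = 0 the EDF equals the
    parameter count exactly; as lambda grows it falls to the penalty null
    space dimension (3 for the full state-trait penalty).
    """
    total, parts, _ = _edf_full(H, P, lam, layout)
    return total, parts


def aic(fit_result: FitResult) -> float:
    """AIC = -2 loglik + 2 (EDF + #free cutpoints + 1 for sigma_u).

    The fixed-effect complexity term is the corrected EDF tr(2M - M^2) with
    M = (H + lambda P)^{-1} H, which accounts for the uncertainty in the
    data-driven shrinkage parameter; it coincides with the classical trace
    EDF (and with the raw parameter count) at lambda = 0, and falls to the
    penalty null-space dimension as lambda grows.
    """
    return fit_result.aic


def select_lambda(
    spec: ModelSpec,
    panel: OrdinalPanel,
    traits: TraitSummary,
    keys: KeySet | None = None,
    grid: np.ndarray | None = None,
    *,
    linear_init: FitResult | None = None,
    return_path: bool = False,
    early_stop: int = 0,
    ftol: float = 1e-8,
):
    """Choose lambda on a grid by a Laplace-approximate marginal criterion.

    For each lambda the model is refitted (warm-started along the descending
    grid) and scored by the penalized log-likelihood plus the correction
    ``+ 1/2 rank(P) log(lambda) - 1/2 logdet(H + lambda P)`` that integrates
    the penalized coefficients out as random effects.  Ties break toward more
    shrinkage (larger lambda).  ``early_stop > 0`` abandons the descending
    path after that many consecutive criterion decreases (the criterion is
    unimodal in lambda in regular problems).
    """
    if spec.mode != "penalized":
        raise ValueError("select_lambda requires a penalized ModelSpec")
    grid = DEFAULT_LAMBDA_GRID if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(grid < 0):
        raise ValueError("lambda grid must be non-empty and >= 0")
    grid = np.sort(grid)[::-1]

    from .penalty import f_to_zeta  # local import to avoid cycle at module load

    md_q = spec.layout.n_params + (1 if spec.lagged else 0)
    init = None
    if linear_init is None:
        lin_spec = ModelSpec(
            m_y=spec.m_y,
            mode="linear",
            quadrature_nodes=spec.quadrature_nodes,
            fit_nodes=spec.fit_nodes,
        )
        linear_init = fit(lin_spec, panel, traits)
    f_lin = linear_init.implied_f(spec.layout.cells)
    zeta0 = f_to_zeta(f_lin, spec.layout)
    if spec.lagged:
        zeta0 = np.concatenate([zeta0, [0.0]])
    delta0 = np.log(np.diff(linear_init.theta_hat))
    init = np.concatenate(
        [zeta0, delta0, [np.log(max(linear_init.sigma_u_hat, 1e-8))]]
    )

    rank_p = spec.penalty.rank
    P = _padded_penalty(spec, md_q)
    md = _design(spec, panel, traits, keys)
    best = None
    best_crit = -np.inf
    path = []
    n_below = 0
    drop_tol = 0.5  # criterion units (log-likelihood scale)
    for lam in grid:
        res = fit(spec, panel, traits, keys, lam, init=init, ftol=ftol, _md=md)
        if res.converged:
            init = np.concatenate(
                [
                    res.zeta_hat,
                    np.log(np.diff(res.theta_hat)),
                    [np.log(max(res.sigma_u_hat, 1e-8))],
                ]
            )  # warm start the next (smaller) lambda
            if lam > 0:
                pen_ll = res.gh_loglik - 0.5 * lam * float(
                    res.zeta_hat @ (P @ res.zeta_hat)
                )
                sign, logdet = np.linalg.slogdet(res.hessian_fixed + lam * P)
                crit = (
                    pen_ll + 0.5 * rank_p * np.log(lam) - 0.5 * logdet
                    if sign > 0
                    else -np.inf
                )
            else:
                crit = -np.inf
        else:
            crit = -np.inf
        path.append((float(lam), float(crit), res))
        if crit > best_crit:
            best_crit = crit
            best = res
            n_below = 0
        elif crit < best_crit - drop_tol:
            n_below += 1
        if early_stop and n_below >= early_stop and np.isfinite(best_crit):
            break
    if best is None or not np.isfinite(best_crit):
        raise RuntimeError("no lambda on the grid produced a converged fit")
    if return_path:
        return best.lambda_, best, path
    return best.lambda_, best
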