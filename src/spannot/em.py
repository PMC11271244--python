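"""Negative-binomial count model and EM refinement of spot labels.

Counts follow a spatial Poisson point process whose Gamma-distributed
intensity integrates out to a negative binomial: C_gs | l_s = r ~
NB(alpha_gsr, sigma_s * mu_gsr). The mean decomposes into a per-spot
baseline plus a marker overexpression term anchored at each pattern's
skeleton average, and the inverse dispersion is a radial-basis-function of
the scaled mean. EM alternates exact posterior computation with
adaptive-moment gradient ascent on the expected complete-data
log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import digamma, expit, gammaln
from skimage import morphology

__all__ = [
    "EMConfig",
    "EMState",
    "RBFDispersion",
    "skeletonize_mask",
    "pattern_mean_anchor",
    "nb_logpmf",
    "rbf_alpha",
    "mean_model",
    "softplus",
    "posterior",
    "q_function",
    "fit_em",
    "renew_labels",
]

ALPHA_FLOOR = 1e-6


def softplus(x):
    return np.logaddexp(0.0, np.asarray(x, dtype=float))


@dataclass
class EMConfig:
    """Optimizer and convergence settings for the EM fit."""

    learning_rate: float = 0.1
    max_inner: int = 100_000      # cap on Adam steps per M-step
    inner_check: int = 10         # objective evaluated every this many steps
    inner_tol: float = 1e-4       # relative best-objective gain per check window
    max_sweeps: int = 20
    tol: float = 1e-4             # relative |dQ| between sweeps
    stop_rule: str = "relative"   # "absolute" reproduces the printed |dQ| < 1e4 rule
    abs_tol: float = 1e4
    prior_weighting: str = "per-gene"  # prior terms inside the per-gene sum, or "per-spot"
    dirichlet_conc: float = 0.01
    n_rbf: int = 10
    baseline: str = "gene"        # baseline resolution: one per gene, or "spot" (per gene per spot)
    seed: int = 0


@dataclass
class RBFDispersion:
    """Inverse dispersion alpha(m) = sum_i a_i exp(-(m - x_i)^2 / b).

    Centers are evenly spaced on [0, max count]; the width constant b is
    twice the squared center spacing, used as the denominator of the
    squared distance so the basis overlaps smoothly at any count scale.
    alpha is clamped below at 1e-6.
    """

    coefficients: np.ndarray
    centers: np.ndarray
    b: float

    @classmethod
    def initialize(cls, max_count: float, n_rbf: int = 10) -> "RBFDispersion":
        centers = np.linspace(0.0, max(float(max_count), 1.0), n_rbf)
        spacing = centers[1] - centers[0] if n_rbf > 1 else 1.0
        return cls(
            coefficients=np.ones(n_rbf),
            centers=centers,
            b=2.0 * spacing**2,
        )


def rbf_alpha(a, centers, b, m):
    """Evaluate the RBF inverse dispersion at scaled means ``m`` (clamped)."""
    a = np.asarray(a, dtype=float)
    centers = np.asarray(centers, dtype=float)
    m = np.asarray(m, dtype=float)
    basis = np.exp(-((m[..., None] - centers) ** 2) / b)
    return np.maximum(basis @ a, ALPHA_FLOOR)


def nb_logpmf(c, alpha, m):
    """Log pmf of NB with inverse dispersion ``alpha`` and mean ``m``.

    Computed via log-gamma throughout; finite for alpha up to ~1e8.
    """
    c = np.asarray(c, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    m = np.asarray(m, dtype=float)
    if np.any(alpha <= 0) or np.any(m <= 0) or np.any(c < 0):
        raise ValueError("require c >= 0, alpha > 0, m > 0")
    tot = alpha + m
    return (
        gammaln(c + alpha)
        - gammaln(alpha)
        - gammaln(c + 1.0)
        + alpha * (np.log(alpha) - np.log(tot))
        + c * (np.log(m) - np.log(tot))
    )


def mean_model(beta_raw, beta_anchor, rho, delta_raw):
    """NB mean mu_gsr = softplus(beta_raw) + anchor * rho * (1 + softplus(delta_raw)).

    The softplus reparameterizations keep the baseline positive and the
    overexpression factor strictly above 1.
    """
    base = softplus(beta_raw)  # (G, S)
    delta = 1.0 + softplus(delta_raw)  # (G, R)
    marker = np.asarray(beta_anchor) * np.asarray(rho) * delta  # (G, R)
    return base[:, :, None] + marker[:, None, :]


def skeletonize_mask(mask) -> np.ndarray:
    """1-pixel-wide skeleton of a binary mask (area-1 components survive)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    return morphology.skeletonize(mask)


def pattern_mean_anchor(counts, labels, skeletons, pixel_map, marker_rows=None):
    """Per-gene-per-pattern anchor: mean raw count over skeleton spots.

    ``skeletons`` is an (I, J, R) boolean stack. Patterns with an empty
    skeleton (or none of their spots on it) fall back to the mean over all
    spots labeled with that pattern; a pattern with no spots at all falls
    back to the gene-wide mean.
    """
    counts = np.asarray(counts, dtype=float)
    if marker_rows is not None:
        counts = counts[np.asarray(marker_rows, dtype=int)]
    labels = np.asarray(labels, dtype=int)
    R = skeletons.shape[2]
    G = counts.shape[0]
    pix = pixel_map.pixel_of_spot
    anchors = np.zeros((G, R), dtype=float)
    for r in range(R):
        on_skel = skeletons[pix[:, 0], pix[:, 1], r]
        sel = on_skel
        if not sel.any():
            sel = labels == r
        if not sel.any():
            anchors[:, r] = counts.mean(axis=1)
        else:
            anchors[:, r] = counts[:, sel].mean(axis=1)
    return anchors


def posterior(counts, sigma, pi, alpha, mu, dirichlet_conc: float = 0.01):
    """E-step posterior p_sr, computed in log space and row-normalized.

    The Dirichlet hyper-prior enters as an additive pseudocount on pi.
    ``alpha`` and ``mu`` are (G, S, R); ``counts`` is (G, S).
    """
    pi_eff = np.asarray(pi, dtype=float) + dirichlet_conc
    pi_eff = pi_eff / pi_eff.sum(axis=1, keepdims=True)
    m = sigma[None, :, None] * mu
    ll = nb_logpmf(np.asarray(counts, dtype=float)[:, :, None], alpha, m)
    with np.errstate(divide="ignore"):  # log 0 -> -inf is the intended limit
        logpost = np.log(pi_eff) + ll.sum(axis=0)  # (S, R)
    logpost = logpost - logpost.max(axis=1, keepdims=True)
    p = np.exp(logpost)
    return p / p.sum(axis=1, keepdims=True)


def _dirichlet_logpdf(pi, conc):
    R = pi.shape[1]
    const = gammaln(R * conc) - R * gammaln(conc)
    return const + (conc - 1.0) * np.log(np.clip(pi, 1e-300, None)).sum(axis=1)


def q_function(counts, sigma, p_sr, pi, alpha, mu, dirichlet_conc: float = 0.01,
               prior_weighting: str = "per-gene") -> float:
    """Expected complete-data log-likelihood.

    Prior terms (log pi_sr and the Dirichlet hyper-prior log p(pi_s)) sit
    inside the per-gene sum by default, i.e. are weighted by the number of
    genes; "per-spot" counts them once per spot instead.
    """
    counts = np.asarray(counts, dtype=float)
    G = counts.shape[0]
    m = sigma[None, :, None] * mu
    ll = nb_logpmf(counts[:, :, None], alpha, m).sum(axis=0)  # (S, R)
    log_pi = np.log(np.clip(pi, 1e-300, None))
    log_hyper = _dirichlet_logpdf(pi, dirichlet_conc)[:, None]
    w = float(G) if prior_weighting == "per-gene" else 1.0
    per_sr = ll + w * (log_pi + log_hyper)
    return float(np.sum(p_sr * per_sr))


@dataclass
class EMState:
    """Fitted parameters and EM trace."""

    beta_raw: np.ndarray       # (G, S)
    delta_raw: np.ndarray      # (G, R)
    dispersion: RBFDispersion
    beta_anchor: np.ndarray    # (G, R), fixed
    rho: np.ndarray            # (G, R) in {0, 1}
    posterior_: Optional[np.ndarray] = None
    q_history: list = field(default_factory=list)
    converged: bool = False

    @property
    def delta(self) -> np.ndarray:
        """Overexpression factors delta_gr (> 1 where rho = 1)."""
        return 1.0 + softplus(self.delta_raw)

    def mu(self) -> np.ndarray:
        return mean_model(self.beta_raw, self.beta_anchor, self.rho, self.delta_raw)


def _weighted_loglik_and_grads(counts, sigma, p_sr, state: EMState):
    """Posterior-weighted NB log-likelihood and analytic gradients.

    Returns the objective and gradients w.r.t. beta_raw, delta_raw and the
    RBF coefficients, accounting for alpha's dependence on the mean.
    """
    G, S = counts.shape
    disp = state.dispersion
    mu = state.mu()  # (G, S, R)
    m = sigma[None, :, None] * mu
    diff = m[..., None] - disp.centers  # (G, S, R, B)
    basis = np.exp(-(diff**2) / disp.b)
    alpha_raw = basis @ disp.coefficients
    clamped = alpha_raw < ALPHA_FLOOR
    alpha = np.maximum(alpha_raw, ALPHA_FLOOR)

    c = counts[:, :, None]
    tot = alpha + m
    ll = (
        gammaln(c + alpha) - gammaln(alpha) - gammaln(c + 1.0)
        + alpha * (np.log(alpha) - np.log(tot))
        + c * (np.log(m) - np.log(tot))
    )
    w = p_sr[None, :, :]  # (1, S, R)
    obj = float(np.sum(w * ll))

    dll_dm = c / m - (alpha + c) / tot
    dll_dalpha = digamma(c + alpha) - digamma(alpha) + np.log(alpha / tot) + (m - c) / tot
    dll_dalpha = np.where(clamped, 0.0, dll_dalpha)
    dalpha_dm = np.einsum("gsrb,b->gsr", basis * (-2.0 * diff / disp.b), disp.coefficients)
    g_m = w * (dll_dm + dll_dalpha * dalpha_dm)  # dObj/dm per element
    g_mu = g_m * sigma[None, :, None]

    g_base = g_mu.sum(axis=2)  # (G, S)
    if state.beta_raw.shape[1] == 1:
        grad_beta = g_base.sum(axis=1, keepdims=True) * expit(state.beta_raw)
    else:
        grad_beta = g_base * expit(state.beta_raw)
    sig_delta = expit(state.delta_raw)  # (G, R)
    grad_delta = g_mu.sum(axis=1) * state.beta_anchor * state.rho * sig_delta
    grad_a = np.einsum("gsr,gsrb->b", w * dll_dalpha, basis)
    return obj, grad_beta, grad_delta, grad_a


class _Adam:
    def __init__(self, shapes, lr):
        self.lr = lr
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params, grads):
        self.t += 1
        out = []
        for k, (p, g) in enumerate(zip(params, grads)):
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            out.append(p + self.lr * mhat / (np.sqrt(vhat) + self.eps))
        return out


def _m_step(counts, sigma, p_sr, state: EMState, cfg: EMConfig):
    """Adam ascent on the posterior-weighted log-likelihood.

    Keeps the best-objective parameters seen, so the M-step never returns
    something worse than its starting point.
    """
    params = [state.beta_raw, state.delta_raw, state.dispersion.coefficients]
    opt = _Adam([p.shape for p in params], cfg.learning_rate)

    def set_params(ps):
        state.beta_raw, state.delta_raw = ps[0], ps[1]
        state.dispersion.coefficients = ps[2]

    obj, *grads = _weighted_loglik_and_grads(counts, sigma, p_sr, state)
    best_obj, best = obj, [p.copy() for p in params]
    prev_best = best_obj
    for it in range(1, cfg.max_inner + 1):
        params = opt.step(params, grads)
        set_params(params)
        obj, *grads = _weighted_loglik_and_grads(counts, sigma, p_sr, state)
        if not np.isfinite(obj):
            raise FloatingPointError("non-finite M-step objective")
        if obj > best_obj:
            best_obj, best = obj, [p.copy() for p in params]
        if it % cfg.inner_check == 0:
            # stop once a full check window no longer improves the best value
            if best_obj - prev_best <= cfg.inner_tol * (abs(prev_best) + 1.0):
                break
            prev_best = best_obj
    set_params(best)
    return best_obj


def fit_em(counts, sigma, pi, beta_anchor, rho, config: Optional[EMConfig] = None) -> EMState:
    """EM fit of the count model given a fixed MRF prior.

    Parameters
    ----------
    counts : (G, S) raw counts of the marker-list genes.
    sigma : (S,) size factors.
    pi : (S, R) spot-type prior from the MRF model.
    beta_anchor : (G, R) fixed anchors (skeleton averages in the pipeline).
    rho : (G, R) binary marker-pattern indicators.
    """
    cfg = config or EMConfig()
    counts = np.asarray(counts, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    pi = np.asarray(pi, dtype=float)
    beta_anchor = np.asarray(beta_anchor, dtype=float)
    rho = np.asarray(rho, dtype=float)
    G, S = counts.shape
    R = pi.shape[1]
    rng = np.random.default_rng(cfg.seed)
    beta_shape = (G, 1) if cfg.baseline == "gene" else (G, S)
    state = EMState(
        beta_raw=rng.standard_normal(beta_shape),
        delta_raw=np.zeros((G, R)),
        dispersion=RBFDispersion.initialize(counts.max(), cfg.n_rbf),
        beta_anchor=beta_anchor,
        rho=rho,
    )
    q_prev = None
    for sweep in range(cfg.max_sweeps):
        disp = state.dispersion
        mu = state.mu()
        m = sigma[None, :, None] * mu
        alpha = rbf_alpha(disp.coefficients, disp.centers, disp.b, m)
        p_sr = posterior(counts, sigma, pi, alpha, mu, cfg.dirichlet_conc)
        state.posterior_ = p_sr
        _m_step(counts, sigma, p_sr, state, cfg)
        mu = state.mu()
        m = sigma[None, :, None] * mu
        alpha = rbf_alpha(state.dispersion.coefficients, state.dispersion.centers,
                          state.dispersion.b, m)
        q = q_function(counts, sigma, p_sr, pi, alpha, mu,
                       cfg.dirichlet_conc, cfg.prior_weighting)
        state.q_history.append(q)
        if q_prev is not None:
            dq = abs(q - q_prev)
            stop = (dq < cfg.abs_tol) if cfg.stop_rule == "absolute" else (
                dq <= cfg.tol * (abs(q_prev) + 1.0)
            )
            if stop:
                state.converged = True
                break
        q_prev = q
    # final E-step with fitted parameters
    mu = state.mu()
    m = sigma[None, :, None] * mu
    alpha = rbf_alpha(state.dispersion.coefficients, state.dispersion.centers,
                      state.dispersion.b, m)
    state.posterior_ = posterior(counts, sigma, pi, alpha, mu, cfg.dirichlet_conc)
    return state


def renew_labels(p_sr, method: str = "argmax", pixel_map=None, params=None,
                 pattern_names=None):
    """Final label assignment from the posterior.

    "argmax" takes the per-spot posterior mode (ties to the lowest index);
    "imgbase" rasterizes the posterior into a pattern-image stack and
    re-runs the detector's segmentation stages on it, which preserves
    structural continuity.
    """
    p_sr = np.asarray(p_sr, dtype=float)
    if method == "argmax":
        return np.argmax(p_sr, axis=1).astype(int)
    if method == "imgbase":
        from .detector import DetectorParams, detect_from_stack

        if pixel_map is None:
            raise ValueError("imgbase renewal needs a pixel map")
        params = params or DetectorParams()
        R = p_sr.shape[1]
        stack = np.stack([pixel_map.rasterize(p_sr[:, r]) for r in range(R)], axis=2)
        stack[~pixel_map.mask] = 0.0
        names = pattern_names if pattern_names is not None else [str(r) for r in range(R)]
        ann = detect_from_stack(stack, pixel_map, names, params)
        return ann.labels
    raise ValueError(f"unknown renewal method: {method!r}")
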