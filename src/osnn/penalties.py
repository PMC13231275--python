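"""Minimax concave penalty (MCP), hierarchical sparse-group penalty, ridge term,
and the local quadratic approximation (LQA) surrogate used by the optimizer.

The hierarchical penalty combines a *group* MCP on each group norm
||kappa_j|| = ||(b_j, eta_j1, ..., eta_jq)|| with an *individual* MCP on each
interaction coefficient eta_jd.  A zero group removes the main effect and all its
interactions together, which is exactly the strong-hierarchy constraint: an
interaction can survive only inside a surviving group.

The LQA surrogate replaces the nonsmooth penalty with sum_j w_bj * b_j^2 +
sum_jd w_jd * eta_jd^2, with weights refreshed at the current iterate so that the
surrogate gradient matches the exact penalty gradient there (``standard_lqa``
mode).  An alternative parse of the group coefficient, carrying an extra
|coef|/||kappa|| factor, is kept behind ``surrogate_mode='as_printed'`` for
fidelity experiments; it does not satisfy gradient tangency and is not the
default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import DenseParams, SparseLayerCoefs

__all__ = [
    "PenaltyConfig",
    "LQAWeights",
    "mcp",
    "mcp_grad",
    "hierarchical_penalty",
    "individual_penalty",
    "ridge_penalty",
    "lqa_weights",
    "lqa_weights_individual",
]


@dataclass(frozen=True)
class PenaltyConfig:
    """Tuning parameters of the penalized loss.

    lambda_ridge (lambda) scales the ridge term on the dense weight matrices;
    lambda_group (lambda_1) the group MCP on ||kappa_j||; lambda_indiv (lambda_2)
    the individual MCP on each eta_jd.  xi > 1 is the MCP concavity (fixed at 3
    by default); lqa_eps regularizes the LQA denominators.
    """

    lambda_ridge: float = 0.0
    lambda_group: float = 0.0
    lambda_indiv: float = 0.0
    xi: float = 3.0
    lqa_eps: float = 1e-8
    surrogate_mode: str = "standard_lqa"

    def __post_init__(self) -> None:
        if self.xi <= 1.0:
            raise ValueError(f"xi must exceed 1, got {self.xi}")
        if self.lqa_eps <= 0:
            raise ValueError("lqa_eps must be positive")
        if min(self.lambda_ridge, self.lambda_group, self.lambda_indiv) < 0:
            raise ValueError("penalty strengths must be nonnegative")
        if self.surrogate_mode not in ("standard_lqa", "as_printed"):
            raise ValueError(f"unknown surrogate_mode {self.surrogate_mode!r}")


@dataclass
class LQAWeights:
    """Quadratic coefficients of the LQA surrogate: sum w_b b^2 + sum w_eta eta^2."""

    w_b: np.ndarray    # (p,)
    w_eta: np.ndarray  # (p, q)


def mcp(t: np.ndarray | float, lam: float, xi: float) -> np.ndarray | float:
    """Minimax concave penalty rho(t; lam, xi) = lam * int_0^|t| (1 - x/(lam xi))_+ dx.

    Closed form: lam|t| - t^2/(2 xi) for |t| <= lam*xi, else lam^2 xi / 2.
    Even in t, nondecreasing in |t|, saturating at lam*xi.
    """
    if xi <= 0:
        raise ValueError(f"xi must be positive, got {xi}")
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    a = np.abs(np.asarray(t, dtype=float))
    out = np.where(a <= lam * xi, lam * a - a**2 / (2.0 * xi), 0.5 * lam**2 * xi)
    return float(out) if np.ndim(t) == 0 else out


def mcp_grad(t: np.ndarray | float, lam: float, xi: float) -> np.ndarray | float:
    """Derivative of the MCP: sign(t) * (lam - |t|/xi)_+ ; zero beyond saturation."""
    if xi <= 0:
        raise ValueError(f"xi must be positive, got {xi}")
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    tt = np.asarray(t, dtype=float)
    out = np.sign(tt) * np.maximum(lam - np.abs(tt) / xi, 0.0)
    return float(out) if np.ndim(t) == 0 else out


def hierarchical_penalty(sparse: SparseLayerCoefs, cfg: PenaltyConfig) -> float:
    """Sparse-group penalty: sum_j rho(||kappa_j||; lam1) + sum_jd rho(eta_jd; lam2)."""
    norms = sparse.group_norms()
    pen = mcp(norms, cfg.lambda_group, cfg.xi).sum()
    pen += mcp(sparse.eta, cfg.lambda_indiv, cfg.xi).sum()
    return float(pen)


def individual_penalty(sparse: SparseLayerCoefs, cfg: PenaltyConfig) -> float:
    """Flat per-coefficient MCP (no group term, no hierarchy):
    sum_j rho(b_j; lam1) + sum_jd rho(eta_jd; lam2)."""
    pen = mcp(sparse.b, cfg.lambda_group, cfg.xi).sum()
    pen += mcp(sparse.eta, cfg.lambda_indiv, cfg.xi).sum()
    return float(pen)


def ridge_penalty(dense: DenseParams, lambda_ridge: float) -> float:
    """lambda * sum_l ||W_l||_F^2 over the dense weight matrices; biases excluded."""
    return float(lambda_ridge * sum((W**2).sum() for W in dense.weights))


def lqa_weights(sparse_current: SparseLayerCoefs, cfg: PenaltyConfig) -> LQAWeights:
    """Quadratic surrogate weights for the hierarchical penalty at the current iterate.

    standard_lqa mode:
        w_b[j]    = rho'_{lam1}(||kappa_j||) / (2 (||kappa_j|| + eps))
        w_eta[jd] = w_b[j] + rho'_{lam2}(|eta_jd|) / (2 (|eta_jd| + eps))
    so that d/d(coef) of the surrogate equals the exact pen1 gradient at the
    expansion point (with eps = 0 and nonzero iterates).  as_printed mode carries
    an extra |coef| / (||kappa_j|| + eps) factor on the group contribution.
    """
    eps = cfg.lqa_eps
    norms = sparse_current.group_norms()
    g_group = mcp_grad(norms, cfg.lambda_group, cfg.xi) / (2.0 * (norms + eps))
    g_indiv = mcp_grad(np.abs(sparse_current.eta), cfg.lambda_indiv, cfg.xi) / (
        2.0 * (np.abs(sparse_current.eta) + eps)
    )
    if cfg.surrogate_mode == "as_printed":
        w_b = g_group * np.abs(sparse_current.b) / (norms + eps)
        w_eta = (
            g_group[:, None] * np.abs(sparse_current.eta) / (norms[:, None] + eps)
            + g_indiv
        )
    else:
        w_b = g_group
        w_eta = g_group[:, None] + g_indiv
    return LQAWeights(w_b=w_b, w_eta=w_eta)


def lqa_weights_individual(
    sparse_current: SparseLayerCoefs, cfg: PenaltyConfig
) -> LQAWeights:
    """LQA weights for the flat per-coefficient penalty (no-hierarchy ablation)."""
    eps = cfg.lqa_eps
    ab = np.abs(sparse_current.b)
    ae = np.abs(sparse_current.eta)
    w_b = mcp_grad(ab, cfg.lambda_group, cfg.xi) / (2.0 * (ab + eps))
    w_eta = mcp_grad(ae, cfg.lambda_indiv, cfg.xi) / (2.0 * (ae + eps))
    return LQAWeights(w_b=w_b, w_eta=w_eta)
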