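"""Design matrix, covariance structure, and the profiled −2 log-likelihood.

The observation vector y for one gene is multivariate normal,

    y ~ N(Wθ, V),   V = σ²(Ṽ(α) + γI)      (OU)
    y ~ N(1θ0, V),  V = σ²(S + γI)          (BM, α = 0)

where Ṽ has entries (1/2α)·e^{−α(T_i+T_j−2s_ij)}·(1−e^{−2αs_ij}) depending
only on the species of each row, S is the shared-time (BM) kernel s_ij, and
γσ² is the within-species replicate variance. For fixed (α, γ) the GLS
estimates σ̂², θ̂ are closed-form, leaving a 2-parameter profile objective

    Ũ(α, γ) = n(1 + log 2πσ̂²(α, γ)) + log det(Ṽ + γI).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .trees import LineageEpochs, RegimePainting, SharedTimeMatrix

__all__ = [
    "GAMMA_MIN",
    "WeightMatrix",
    "ScaledCovariance",
    "ou_weight_matrix",
    "ou_scaled_covariance",
    "bm_scaled_covariance",
    "profile_sigma_theta",
    "neg2_loglik_full",
    "neg2_loglik_profile",
]

#: Lower bound on γ: γ = 0 with replicated species makes Ṽ + γI singular
#: (duplicate rows), so the optimization box is (GAMMA_MIN, 1].
GAMMA_MIN = 1e-6


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class WeightMatrix:
    """(Σ_i M_i) × R design matrix mapping regime optima to expected values."""

    values: np.ndarray
    regime_names: list[str]


@dataclass(frozen=True)
class ScaledCovariance:
    """Covariance without the σ² scale and the γI replicate term.

    ``kind`` is "OU" (entries Ṽ) or "BM" (entries s_ij); the full model
    covariance is σ²(values + γI).
    """

    values: np.ndarray
    kind: str


def ou_weight_matrix(
    epochs: LineageEpochs,
    painting: RegimePainting,
    alpha: float,
    species_index: np.ndarray,
    merge_root: bool = True,
) -> WeightMatrix:
    """OU design matrix W at attraction strength ``alpha``.

    Column r of the row for an observation of species i receives

        Σ_τ [e^{−α(T_i − t_iτ)} − e^{−α(T_i − t_iτ−1)}] β_{i,r}^τ,

    and the root-state weight e^{−αT_i} is absorbed into the root regime's
    column (``merge_root=True``, default), so rows sum to 1 and the model
    has exactly R optima. With ``merge_root=False`` the root state keeps a
    separate leading column (R+1 columns, free root-state parameter).
    """
    if not alpha > 0:
        raise ModelError(f"alpha must be positive, got {alpha}")
    R = painting.n_regimes
    n_sp = len(epochs.times)
    cols = R if merge_root else R + 1
    per_species = np.zeros((n_sp, cols))
    for i in range(n_sp):
        t = epochs.times[i]
        T = t[-1]
        # e^{-α(T - t_τ)} at the κ(i)+1 epoch boundaries
        decay = np.exp(-alpha * (T - t))
        seg = decay[1:] - decay[:-1]  # per branch segment, telescopes to 1 - e^{-αT}
        root_w = float(decay[0])  # e^{-αT_i}
        off = 0 if merge_root else 1
        for seg_w, node in zip(seg, epochs.branch_nodes[i]):
            r = int(painting.branch_regime[node])
            per_species[i, off + r] += seg_w
        if merge_root:
            per_species[i, painting.root_regime] += root_w
        else:
            per_species[i, 0] = root_w
    W = per_species[species_index]
    names = list(painting.regime_names)
    if not merge_root:
        names = ["root"] + names
    return WeightMatrix(W, names)


def ou_scaled_covariance(
    s: SharedTimeMatrix, alpha: float, species_index: np.ndarray
) -> ScaledCovariance:
    """Ṽ entries (1/2α)e^{−α(T_i+T_j−2s_ij)}(1−e^{−2αs_ij}), expanded to
    replicate rows. Stable at small α via expm1 (Ṽ → S as α → 0⁺)."""
    if not alpha > 0:
        raise ModelError(f"alpha must be positive, got {alpha}")
    sv = s.values
    T = np.diag(sv)
    d = T[:, None] + T[None, :] - 2.0 * sv
    base = np.exp(-alpha * d) * (-np.expm1(-2.0 * alpha * sv)) / (2.0 * alpha)
    return ScaledCovariance(base[np.ix_(species_index, species_index)], "OU")


def bm_scaled_covariance(s: SharedTimeMatrix, species_index: np.ndarray) -> ScaledCovariance:
    """BM kernel: entry ((i,k),(j,l)) = s_ij, expanded to replicate rows."""
    return ScaledCovariance(s.values[np.ix_(species_index, species_index)], "BM")


def _factor(C: np.ndarray, gamma: float):
    A = C + gamma * np.eye(C.shape[0])
    try:
        cf = cho_factor(A, lower=True)
    except LinAlgError as exc:
        raise ModelError(f"covariance not positive definite at gamma={gamma}") from exc
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    return cf, logdet


def profile_sigma_theta(
    y: np.ndarray, W: WeightMatrix | np.ndarray, C: ScaledCovariance | np.ndarray, gamma: float
) -> tuple[float, np.ndarray]:
    """Closed-form GLS estimates (σ̂², θ̂) at fixed (α implicit in C, γ).

    θ̂ = (Wᵀ A⁻¹ W)⁻¹ Wᵀ A⁻¹ y and σ̂² = (y − Wθ̂)ᵀ A⁻¹ (y − Wθ̂) / n with
    A = C + γI and n = Σ_i M_i (the total observation count).
    """
    Wv = W.values if isinstance(W, WeightMatrix) else np.asarray(W)
    Cv = C.values if isinstance(C, ScaledCovariance) else np.asarray(C)
    y = np.asarray(y, dtype=float)
    cf, _ = _factor(Cv, gamma)
    AiW = cho_solve(cf, Wv)
    Aiy = cho_solve(cf, y)
    G = Wv.T @ AiW
    try:
        theta = np.linalg.solve(G, Wv.T @ Aiy)
    except np.linalg.LinAlgError as exc:
        names = W.regime_names if isinstance(W, WeightMatrix) else None
        raise ModelError(f"rank-deficient design matrix (regimes {names})") from exc
    r = y - Wv @ theta
    sigma2 = float(r @ cho_solve(cf, r)) / len(y)
    return sigma2, theta


def neg2_loglik_full(
    y: np.ndarray,
    W: WeightMatrix | np.ndarray,
    C: ScaledCovariance | np.ndarray,
    sigma2: float,
    gamma: float,
    theta: np.ndarray,
) -> float:
    """Exact −2 log L = n log 2π + log det V + (y−Wθ)ᵀV⁻¹(y−Wθ), V = σ²(C+γI)."""
    Wv = W.values if isinstance(W, WeightMatrix) else np.asarray(W)
    Cv = C.values if isinstance(C, ScaledCovariance) else np.asarray(C)
    y = np.asarray(y, dtype=float)
    if not sigma2 > 0:
        raise ModelError(f"sigma2 must be positive, got {sigma2}")
    n = len(y)
    cf, logdetA = _factor(Cv, gamma)
    r = y - Wv @ np.atleast_1d(theta)
    quad = float(r @ cho_solve(cf, r)) / sigma2
    return n * np.log(2.0 * np.pi) + n * np.log(sigma2) + logdetA + quad


def neg2_loglik_profile(
    y: np.ndarray, W: WeightMatrix | np.ndarray, C: ScaledCovariance | np.ndarray, gamma: float
) -> tuple[float, float, np.ndarray]:
    """Profiled objective Ũ = n(1 + log 2πσ̂²) + log det(C + γI).

    Returns (Ũ, σ̂², θ̂); Ũ equals :func:`neg2_loglik_full` at (σ̂², θ̂).
    """
    Wv = W.values if isinstance(W, WeightMatrix) else np.asarray(W)
    Cv = C.values if isinstance(C, ScaledCovariance) else np.asarray(C)
    y = np.asarray(y, dtype=float)
    n = len(y)
    cf, logdetA = _factor(Cv, gamma)
    AiW = cho_solve(cf, Wv)
    Aiy = cho_solve(cf, y)
    G = Wv.T @ AiW
    try:
        theta = np.linalg.solve(G, Wv.T @ Aiy)
    except np.linalg.LinAlgError as exc:
        names = W.regime_names if isinstance(W, WeightMatrix) else None
        raise ModelError(f"rank-deficient design matrix (regimes {names})") from exc
    r = y - Wv @ theta
    sigma2 = float(r @ cho_solve(cf, r)) / n
    if sigma2 <= 0:
        # zero-residual degenerate data; report the limit value
        return -np.inf, 0.0, theta
    u = n * (1.0 + np.log(2.0 * np.pi * sigma2)) + logdetA
    return float(u), sigma2, theta
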