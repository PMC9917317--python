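"""Per-gene maximum-likelihood fits of the three nested evolutionary models.

Three models are fitted to one gene's replicated observations:

* ``bm`` — neutral drift (α = 0), parameters (θ0, σ², γ);
* ``ou1`` — constrained evolution, single optimum, parameters (α, σ², γ, θ0);
* ``adaptive`` — multi-regime OU, parameters (α, σ², γ, θ_1..θ_R).

σ² and θ are profiled out in closed form, so BM needs a 1-D search over γ
and the OU models a 2-D search over (log α, logit γ). The search scans a
coarse 4×4 grid, runs Nelder-Mead from the best three grid points, and
polishes the winner with L-BFGS-B; fitting is fully deterministic.

The replicate-averaging baseline collapses replicates to their species mean
first and fits the same models with γ fixed at 0 (no within-species term).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import expit, logit

from . import model_core as mc
from .expression import ExpressionMatrix, ObservationVector, averaged_matrix, observation_vector
from .model_core import GAMMA_MIN
from .trees import PhyloTree, RegimePainting, lineage_epochs, shared_time_matrix

__all__ = [
    "FitResult",
    "fit_bm",
    "fit_ou_constrained",
    "fit_ou_adaptive",
    "fit_gene_models",
    "fit_averaged_baseline",
]

#: Optimization box for α (per unit branch-length). The lower bound sits far
#: below any resolvable attraction strength so the OU fit can reach the BM
#: boundary; kernels are expm1-stable there.
ALPHA_FLOOR = 1e-9


@dataclass(frozen=True)
class FitResult:
    """One fitted model for one gene."""

    kind: str  # "bm" | "ou1" | "adaptive"
    alpha: float | None
    sigma2: float
    gamma: float | None
    theta: dict[str, float]
    neg2_loglik: float
    n_params: int
    converged: bool
    n_evals: int
    message: str = ""
    degenerate: bool = False

    @property
    def alpha_gamma_exceeds_half(self) -> bool:
        """Flag: fitted within-species variance exceeds the asymptotic
        between-species variance σ²/2α (i.e. α̂γ̂ > 1/2)."""
        if self.alpha is None or self.gamma is None:
            return False
        return self.alpha * self.gamma > 0.5


@dataclass
class _Workspace:
    """Per-(tree, painting) precomputation shared across likelihood evaluations."""

    obs: ObservationVector
    tree: PhyloTree
    painting: RegimePainting | None = None
    merge_root: bool = True

    def __post_init__(self) -> None:
        if self.tree.n_tips < 2:
            raise mc.ModelError("at least 2 species required for a fit")
        self.epochs = lineage_epochs(self.tree)
        self.s = shared_time_matrix(self.tree)
        self.idx = self.obs.species_index
        self.y = self.obs.y
        counts = np.bincount(self.idx, minlength=self.tree.n_tips)
        if counts.min() < 1:
            raise mc.ModelError("every tree tip needs at least one replicate")
        self.replicated = bool(counts.max() >= 2)
        self.bm_cov = mc.bm_scaled_covariance(self.s, self.idx)
        self.ones = mc.WeightMatrix(np.ones((len(self.y), 1)), ["theta0"])

    def bm_profile(self, gamma: float):
        return mc.neg2_loglik_profile(self.y, self.ones, self.bm_cov, gamma)

    def ou_profile(self, alpha: float, gamma: float):
        C = mc.ou_scaled_covariance(self.s, alpha, self.idx)
        if self.painting is None:
            W = self.ones
        else:
            W = mc.ou_weight_matrix(
                self.epochs, self.painting, alpha, self.idx, merge_root=self.merge_root
            )
        return mc.neg2_loglik_profile(self.y, W, C, gamma), W


def _theta_dict(theta: np.ndarray, names: list[str]) -> dict[str, float]:
    return {n: float(v) for n, v in zip(names, np.atleast_1d(theta))}


def _degenerate_result(ws: _Workspace, kind: str, n_params: int, names: list[str]) -> FitResult:
    c = float(ws.y[0])
    theta = {n: c for n in names}
    return FitResult(
        kind=kind,
        alpha=None if kind == "bm" else float("nan"),
        sigma2=0.0,
        gamma=GAMMA_MIN if ws.replicated else 0.0,
        theta=theta,
        neg2_loglik=-np.inf,
        n_params=n_params,
        converged=True,
        n_evals=0,
        message="constant observations; sigma2 -> 0",
        degenerate=True,
    )


def fit_bm(obs: ObservationVector, tree: PhyloTree) -> FitResult:
    """Replicate-aware Brownian-motion (neutral) fit.

    1-D search of the profiled objective over γ ∈ (γ_min, 1]; σ̂² and θ̂0 come
    from the GLS closed forms with the all-ones design and the shared-time
    kernel. With a single replicate everywhere γ is unidentifiable and is
    fixed at 0 (the replicate-averaged special case).
    """
    ws = _Workspace(obs, tree)
    if np.ptp(ws.y) == 0:
        return _degenerate_result(ws, "bm", 3 if ws.replicated else 2, ["theta0"])
    if not ws.replicated:
        u, sigma2, theta = ws.bm_profile(0.0)
        return FitResult(
            "bm", None, sigma2, 0.0, _theta_dict(theta, ["theta0"]), u, 2, True, 1,
            message="single replicate per species; gamma fixed at 0",
        )
    evals = [0]

    def f(g: float) -> float:
        evals[0] += 1
        return ws.bm_profile(g)[0]

    grid = np.geomspace(1e-4, 1.0, 9)
    grid_vals = [f(g) for g in grid]
    k = int(np.argmin(grid_vals))
    lo = grid[max(k - 1, 0)] if k > 0 else GAMMA_MIN
    hi = grid[min(k + 1, len(grid) - 1)]
    res = minimize_scalar(f, bounds=(max(lo, GAMMA_MIN), hi), method="bounded",
                          options={"xatol": 1e-10})
    gamma = float(res.x) if res.fun <= min(grid_vals) else float(grid[k])
    u, sigma2, theta = ws.bm_profile(gamma)
    return FitResult(
        "bm", None, sigma2, gamma, _theta_dict(theta, ["theta0"]), u, 3,
        bool(res.success), evals[0],
    )


def _ou_minimize(
    ws: _Workspace,
    gamma_free: bool,
    extra_starts: tuple[tuple[float, float], ...] = (),
) -> tuple[float, float, float, int, bool, str]:
    """2-D (or 1-D when γ is fixed at 0) profiled minimization.

    Returns (α̂, γ̂, Ũ, n_evals, converged, message).
    """
    depth = ws.tree.depth
    alpha_hi = 1e3 / depth
    lu_lo, lu_hi = np.log(ALPHA_FLOOR), np.log(alpha_hi)
    evals = [0]

    def profile(alpha: float, gamma: float) -> float:
        evals[0] += 1
        (u, _, _), _ = ws.ou_profile(alpha, gamma)
        return u if np.isfinite(u) else 1e300

    if not gamma_free:
        def f1(lu: float) -> float:
            return profile(float(np.exp(np.clip(lu, lu_lo, lu_hi))), 0.0)

        grid = np.log(np.geomspace(1e-3 / depth, 1e2 / depth, 12))
        vals = [f1(x) for x in grid]
        k = int(np.argmin(vals))
        lo = grid[max(k - 1, 0)] if k > 0 else lu_lo
        hi = grid[min(k + 1, len(grid) - 1)] if k < len(grid) - 1 else lu_hi
        res = minimize_scalar(f1, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10})
        best_lu = float(res.x) if res.fun <= vals[k] else float(grid[k])
        alpha = float(np.exp(np.clip(best_lu, lu_lo, lu_hi)))
        return alpha, 0.0, profile(alpha, gamma=0.0), evals[0], bool(res.success), ""

    def to_gamma(v: float) -> float:
        return GAMMA_MIN + (1.0 - GAMMA_MIN) * float(expit(v))

    def to_v(g: float) -> float:
        frac = np.clip((g - GAMMA_MIN) / (1.0 - GAMMA_MIN), 1e-12, 1 - 1e-12)
        return float(logit(frac))

    def f(z: np.ndarray) -> float:
        lu = float(np.clip(z[0], lu_lo, lu_hi))
        return profile(float(np.exp(lu)), to_gamma(float(np.clip(z[1], -40, 40))))

    # 4x4 coarse grid over the plausible box
    alphas = np.geomspace(1e-3 / depth, 1e2 / depth, 4)
    gammas = np.array([1e-4, 2.2e-3, 4.6e-2, 0.98])
    cand = [np.array([np.log(a), to_v(g)]) for a in alphas for g in gammas]
    cand += [np.array([np.log(a), to_v(g)]) for a, g in extra_starts]
    cand_vals = np.array([f(z) for z in cand])
    order = np.argsort(cand_vals)
    starts = [cand[i] for i in order[:3]]
    # extra starts are always honored as simplex starts
    starts += [cand[i] for i in range(16, len(cand)) if i not in order[:3]]

    best_z, best_val = starts[0], cand_vals[order[0]]
    ok, msg = True, ""
    for z0 in starts:
        r = minimize(f, z0, method="Nelder-Mead",
                     options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 400})
        if r.fun < best_val:
            best_val, best_z = r.fun, r.x
    r = minimize(f, best_z, method="L-BFGS-B",
                 bounds=[(lu_lo, lu_hi), (-40.0, 40.0)])
    if r.fun < best_val:
        best_val, best_z = r.fun, r.x
        ok = bool(r.success)
        msg = str(r.message)
    alpha = float(np.exp(np.clip(best_z[0], lu_lo, lu_hi)))
    gamma = to_gamma(float(np.clip(best_z[1], -40, 40)))
    return alpha, gamma, float(best_val), evals[0], ok, msg


def _fit_ou(
    obs: ObservationVector,
    tree: PhyloTree,
    painting: RegimePainting | None,
    kind: str,
    extra_starts: tuple[tuple[float, float], ...] = (),
    merge_root: bool = True,
) -> FitResult:
    ws = _Workspace(obs, tree, painting=painting, merge_root=merge_root)
    R = 1 if painting is None else painting.n_regimes
    names = ["theta0"] if painting is None else list(painting.regime_names)
    if not merge_root:
        names = ["root"] + names
        R += 1
    n_params = 1 + 1 + R + (1 if ws.replicated else 0)  # alpha, sigma2, thetas, gamma
    if np.ptp(ws.y) == 0:
        return _degenerate_result(ws, kind, n_params, names)
    alpha, gamma, u, n_evals, ok, msg = _ou_minimize(
        ws, gamma_free=ws.replicated, extra_starts=extra_starts
    )
    (u, sigma2, theta), W = ws.ou_profile(alpha, gamma)
    return FitResult(
        kind, alpha, sigma2, gamma if ws.replicated else 0.0,
        _theta_dict(theta, W.regime_names), float(u), n_params, ok, n_evals, msg,
    )


def fit_ou_constrained(
    obs: ObservationVector,
    tree: PhyloTree,
    extra_starts: tuple[tuple[float, float], ...] = (),
) -> FitResult:
    """Single-optimum OU fit (constrained/stabilizing selection)."""
    return _fit_ou(obs, tree, None, "ou1", extra_starts=extra_starts)


def fit_ou_adaptive(
    obs: ObservationVector,
    tree: PhyloTree,
    painting: RegimePainting,
    extra_starts: tuple[tuple[float, float], ...] = (),
    merge_root: bool = True,
) -> FitResult:
    """Multi-regime OU fit (adaptive shifts); one optimum per painted regime."""
    if painting.n_regimes < 2:
        raise mc.ModelError("adaptive fit needs at least 2 regimes")
    return _fit_ou(obs, tree, painting, "adaptive",
                   extra_starts=extra_starts, merge_root=merge_root)


def fit_gene_models(
    obs: ObservationVector,
    tree: PhyloTree,
    painting: RegimePainting | None = None,
) -> dict[str, FitResult]:
    """Fit BM, constrained OU, and (if a painting is given) the adaptive model.

    The constrained fit is seeded with the BM optimum at the α floor and the
    adaptive fit with the constrained optimum, so the nested-optimum chain
    U_BM ≥ U_OU1 ≥ U_adaptive holds to numerical precision.
    """
    out: dict[str, FitResult] = {}
    out["bm"] = fit_bm(obs, tree)
    seed_g = out["bm"].gamma if out["bm"].gamma else GAMMA_MIN
    out["ou1"] = fit_ou_constrained(obs, tree, extra_starts=((ALPHA_FLOOR * 10, seed_g),))
    if painting is not None:
        f1 = out["ou1"]
        has_alpha = f1.alpha is not None and np.isfinite(f1.alpha)
        extra = ((f1.alpha, f1.gamma if f1.gamma else GAMMA_MIN),) if has_alpha else ()
        out["adaptive"] = fit_ou_adaptive(obs, tree, painting, extra_starts=extra)
    return out


def fit_averaged_baseline(
    mat: ExpressionMatrix,
    gene,
    tree: PhyloTree,
    painting: RegimePainting | None = None,
    kind: str = "ou1",
) -> FitResult:
    """Replicate-averaging comparison baseline.

    Replicates are collapsed to their species mean first; the same OU/BM
    machinery then runs with one observation per species and γ fixed at 0.
    """
    avg = averaged_matrix(mat)
    obs = observation_vector(avg, gene, tree)
    if kind == "bm":
        return fit_bm(obs, tree)
    if kind == "ou1":
        return fit_ou_constrained(obs, tree)
    if kind == "adaptive":
        if painting is None:
            raise mc.ModelError("adaptive baseline needs a regime painting")
        return fit_ou_adaptive(obs, tree, painting)
    raise mc.ModelError(f"unknown model kind {kind!r}")


def fit_gene_models_averaged(
    mat: ExpressionMatrix,
    gene,
    tree: PhyloTree,
    painting: RegimePainting | None = None,
) -> dict[str, FitResult]:
    """BM + OU1 (+ adaptive) fits of the replicate-averaging baseline."""
    avg = averaged_matrix(mat)
    obs = observation_vector(avg, gene, tree)
    return fit_gene_models(obs, tree, painting)
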