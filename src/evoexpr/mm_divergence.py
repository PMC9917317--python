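"""Michaelis-Menten summarization of expression-divergence kinetics.

For a gene group and a reference species, the divergence of each other
species is 1 − S where S is the squared Spearman correlation between the
replicate-averaged expression profiles, plotted against the patristic
distance x from the reference tip. The saturating relationship is
summarized by the Michaelis-Menten curve

    f(x) = x·Vmax / (K + x),

where Vmax is the asymptotic (equilibrium) divergence and K the distance at
which half of Vmax is reached (f(K) = Vmax/2 identically).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import spearmanr

from .expression import ExpressionMatrix, replicate_mean
from .trees import PhyloTree, shared_time_matrix

__all__ = [
    "DivergencePoints",
    "MMFit",
    "expression_divergence_points",
    "fit_michaelis_menten",
    "michaelis_menten",
]


class DivergenceError(ValueError):
    pass


@dataclass(frozen=True)
class DivergencePoints:
    """One divergence point per non-reference species."""

    points: pd.DataFrame  # columns: species, x, y
    reference: str
    group: str = ""


@dataclass(frozen=True)
class MMFit:
    vmax: float
    k: float
    rss: float
    converged: bool
    n_points: int
    message: str = ""

    def predict(self, x) -> np.ndarray:
        return michaelis_menten(np.asarray(x, dtype=float), self.vmax, self.k)


def michaelis_menten(x, vmax, k):
    return x * vmax / (k + x)


def expression_divergence_points(
    mat: ExpressionMatrix,
    genes,
    tree: PhyloTree,
    reference: str,
    group: str = "",
) -> DivergencePoints:
    """Divergence 1 − ρ² of each species from the reference over a gene group.

    ρ is the Spearman correlation of replicate-averaged expression across the
    group's genes; x is the patristic distance from the reference tip
    (T_ref + T_sp − 2 s_ref,sp). Sign-invariant: perfectly reversed ranks
    also give zero divergence.
    """
    genes = list(genes)
    if len(genes) < 3:
        raise DivergenceError("need at least 3 genes for a rank correlation")
    if reference not in tree.tip_labels:
        raise DivergenceError(f"reference {reference!r} is not a tip of the tree")
    sub = ExpressionMatrix(mat.data[mat.data["gene"].isin(genes)].reset_index(drop=True))
    means = replicate_mean(sub).pivot(index="gene", columns="species", values="value")
    means = means.reindex(index=genes)
    if means.isna().any().any():
        missing = means.columns[means.isna().any()].tolist()
        raise DivergenceError(f"missing replicate means for species {missing}")
    s = shared_time_matrix(tree)
    tips = tree.tip_labels
    iref = tips.index(reference)
    ref_vec = means[reference].to_numpy()
    if np.ptp(ref_vec) == 0:
        raise DivergenceError(f"constant expression in reference {reference!r}")
    rows = []
    for j, sp in enumerate(tips):
        if sp == reference:
            continue
        v = means[sp].to_numpy()
        if np.ptp(v) == 0:
            raise DivergenceError(f"constant expression in species {sp!r}")
        rho = spearmanr(ref_vec, v).statistic
        x = s.values[iref, iref] + s.values[j, j] - 2.0 * s.values[iref, j]
        rows.append({"species": sp, "x": float(x), "y": float(1.0 - rho**2)})
    return DivergencePoints(pd.DataFrame(rows), reference, group)


def fit_michaelis_menten(points: DivergencePoints) -> MMFit:
    """Plain nonlinear least squares of y ≈ x·Vmax/(K + x).

    f(0) = 0 by construction (no intercept, the origin is implied, not a data
    point). Initialization Vmax0 = max y, K0 = median x; bounds keep the
    asymptote interpretable (Vmax ≤ 1.5, K ≤ 10·max x).
    """
    df = points.points
    x = df["x"].to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=float)
    if len(np.unique(x)) < 2:
        raise DivergenceError("need at least 2 points with distinct distances")
    if np.all(y == 0):
        return MMFit(0.0, float("nan"), 0.0, False, len(x),
                     "all-zero divergence; K unidentifiable")
    p0 = (max(float(y.max()), 1e-6), float(np.median(x)))
    bounds = ([1e-9, 1e-9], [1.5, 10.0 * float(x.max())])
    try:
        popt, _ = curve_fit(michaelis_menten, x, y, p0=p0, bounds=bounds, maxfev=20000)
        converged = True
        msg = ""
    except RuntimeError as exc:  # max evaluations exceeded
        popt = p0
        converged = False
        msg = str(exc)
    vmax, k = float(popt[0]), float(popt[1])
    rss = float(np.sum((y - michaelis_menten(x, vmax, k)) ** 2))
    return MMFit(vmax, k, rss, converged, len(x), msg)
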