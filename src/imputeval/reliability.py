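"""Predicting per-SNP imputation reliability from LD, MAF and reference size.

Three simple functions each explain part of the reliability (squared
accuracy, r^2) of imputing a sequence SNP from a lower-density panel:

* ``r2_dist = 1 / (4*Ne*c + 1)`` — expected LD between the imputed SNP
  and its panel neighbour ``c`` Morgan away, in a population of
  effective size ``Ne`` (Sved's decay).
* ``r2_dmaf`` — the general upper limit of LD between two loci whose
  minor-allele frequencies differ by ``dMAF``: loci with very different
  frequencies cannot be strongly correlated regardless of distance.
  Two published typesettings of this bound are in circulation; both are
  implemented (``ratio_linear``, the default, reaches 0 at dMAF = 0.5;
  ``ratio_squared`` does not) and reports must state which was used.
* ``r2_maf = Vmax * MAF / (Km + MAF)`` — an empirical Michaelis-Menten
  curve in the imputed SNP's own MAF, fitted per reference-group size.
  ``Vmax`` is the reliability ceiling and ``Km`` the MAF at half the
  ceiling; a larger reference group shows up as a smaller ``Km``.

The overall prediction multiplies the three, taking for each SNP the
best of its five nearest panel neighbours by the ``r2_dist * r2_dmaf``
product (the nearest SNP is not necessarily the one in highest LD).
:func:`max_r2_exact` gives the exact attainable maximum of r^2 for two
binary loci with given margins, a hard upper bound the ``r2_dmaf``
approximation can be checked against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .evaluate import MarkerStats

__all__ = [
    "DMAF_VARIANTS",
    "r2_dist",
    "r2_dmaf",
    "max_r2_exact",
    "MichaelisMentenReliability",
    "fit_michaelis_menten",
    "mm_value",
    "select_best_neighbor",
    "predict_reliability",
]

DMAF_VARIANTS = ("ratio_linear", "ratio_squared")


def r2_dist(ne: float, c) -> np.ndarray | float:
    """Expected LD at genetic distance ``c`` Morgan: ``1/(4*Ne*c + 1)``."""
    if ne <= 0:
        raise ValueError("Ne must be positive")
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("genetic distance must be non-negative")
    out = 1.0 / (4.0 * ne * c + 1.0)
    return out if out.ndim else float(out)


def r2_dmaf(dmaf, variant: str = "ratio_linear") -> np.ndarray | float:
    """Upper limit of LD given a minor-allele-frequency difference."""
    d = np.asarray(dmaf, dtype=float)
    if np.any((d < 0) | (d > 0.5)):
        raise ValueError("dMAF must lie in [0, 0.5]")
    if variant == "ratio_linear":
        out = (1.0 - 2.0 * d) / (1.0 + 2.0 * d)
    elif variant == "ratio_squared":
        out = 1.0 - 4.0 * d**2 / (d + 1.0)
    else:
        raise ValueError(f"unknown dMAF variant {variant!r}")
    return out if out.ndim else float(out)


def max_r2_exact(maf_a: float, maf_b: float) -> float:
    """Exact maximal squared correlation of two binary loci.

    Over all joint distributions with minor-allele frequencies
    ``maf_a`` and ``maf_b``, the disequilibrium ``D`` is bounded by
    ``min(p(1-q), q(1-p))`` in coupling phase and ``min(pq, (1-p)(1-q))``
    in repulsion; the attainable maximum of
    ``r^2 = D^2 / (p(1-p)q(1-q))`` takes the larger of the two.
    Symmetric in its arguments.
    """
    p, q = float(maf_a), float(maf_b)
    for x in (p, q):
        if not (0.0 < x <= 0.5):
            raise ValueError("MAFs must lie in (0, 0.5]")
    d_coupling = min(p * (1 - q), q * (1 - p))
    d_repulsion = min(p * q, (1 - p) * (1 - q))
    d = max(d_coupling, d_repulsion)
    return d * d / (p * (1 - p) * q * (1 - q))


def _mm(maf, vmax, km):
    return vmax * maf / (km + maf)


class MichaelisMentenReliability(BaseEstimator, RegressorMixin):
    """Michaelis-Menten fit of reliability against MAF.

    Fitted by nonlinear least squares on binned (MAF, mean r^2) points.
    Initial values are ``Vmax = max(r^2)`` and ``Km`` = the MAF at which
    the reliability first reaches half that maximum.

    Attributes
    ----------
    Vmax_, Km_ : float
        Parameter estimates; the fitted curve equals ``Vmax_/2`` at
        ``MAF = Km_`` by construction of the model.
    Vmax_se_, Km_se_ : float
        Asymptotic standard errors from the fit covariance.
    n_bins_ : int
    """

    def __init__(self, param_tol: float = 1e-10, max_iterations: int = 10_000):
        self.param_tol = param_tol
        self.max_iterations = max_iterations

    def fit(self, maf: np.ndarray, reliability: np.ndarray) -> "MichaelisMentenReliability":
        x = np.asarray(maf, dtype=float).ravel()
        y = np.asarray(reliability, dtype=float).ravel()
        if x.shape != y.shape:
            raise ValueError("maf and reliability must be aligned")
        if len(x) < 3:
            raise ValueError("need at least 3 bins to fit the curve")
        if np.ptp(y) == 0:
            raise ValueError("reliability data are flat; the fit is degenerate")
        vmax0 = float(y.max())
        half = vmax0 / 2.0
        above = np.flatnonzero(y >= half)
        km0 = float(x[above[0]]) if len(above) else float(np.median(x))
        km0 = max(km0, 1e-4)
        try:
            popt, pcov = curve_fit(
                _mm, x, y,
                p0=[vmax0, km0],
                xtol=self.param_tol,
                maxfev=self.max_iterations,
            )
        except RuntimeError as err:  # pragma: no cover - pathological data
            raise RuntimeError(f"Michaelis-Menten fit did not converge: {err}")
        self.Vmax_ = float(popt[0])
        self.Km_ = float(popt[1])
        se = np.sqrt(np.diag(pcov))
        self.Vmax_se_ = float(se[0])
        self.Km_se_ = float(se[1])
        self.n_bins_ = len(x)
        return self

    def predict(self, maf: np.ndarray) -> np.ndarray:
        if not hasattr(self, "Vmax_"):
            raise ValueError("model is not fitted")
        return _mm(np.asarray(maf, dtype=float), self.Vmax_, self.Km_)


def fit_michaelis_menten(
    bin_maf: np.ndarray, bin_reliability: np.ndarray
) -> MichaelisMentenReliability:
    """Fit the reliability-vs-MAF curve on binned means."""
    return MichaelisMentenReliability().fit(bin_maf, bin_reliability)


def mm_value(vmax: float, km: float, maf) -> np.ndarray | float:
    """Evaluate ``Vmax*MAF/(Km+MAF)``; rounding happens only in reports."""
    maf = np.asarray(maf, dtype=float)
    if np.any((maf < 0) | (maf > 0.5)):
        raise ValueError("MAF must lie in [0, 0.5]")
    out = _mm(maf, vmax, km)
    return out if out.ndim else float(out)


def select_best_neighbor(
    neighbor_morgan: np.ndarray,
    neighbor_dmaf: np.ndarray,
    ne: float = 1000.0,
    variant: str = "ratio_linear",
) -> tuple[int, float, float, float]:
    """Best of up to five panel neighbours by ``r2_dist * r2_dmaf``.

    ``neighbor_morgan``/``neighbor_dmaf`` are aligned vectors ordered
    nearest first (NaN-padded).  Ties go to the smaller distance; the
    nearest-first ordering already encodes the lower-position tie rule.
    Returns ``(index, r2_dist, r2_dmaf, product)``.
    """
    c = np.asarray(neighbor_morgan, dtype=float)
    d = np.asarray(neighbor_dmaf, dtype=float)
    ok = ~np.isnan(c)
    if not ok.any():
        raise ValueError("no panel neighbours available")
    prod = np.full(len(c), -np.inf)
    rd = np.zeros(len(c))
    rm = np.zeros(len(c))
    rd[ok] = r2_dist(ne, c[ok])
    rm[ok] = r2_dmaf(np.clip(d[ok], 0, 0.5), variant)
    prod[ok] = rd[ok] * rm[ok]
    # stable argmax over (-product, distance, original order)
    order = np.lexsort((np.arange(len(c)), np.where(ok, c, np.inf), -prod))
    best = int(order[0])
    return best, float(rd[best]), float(rm[best]), float(prod[best])


def predict_reliability(
    stats: MarkerStats,
    mmfit: MichaelisMentenReliability,
    ne: float = 1000.0,
    variant: str = "ratio_linear",
) -> pd.DataFrame:
    """Per-marker reliability prediction ``r2_dist * r2_dmaf * r2_maf``.

    Components are clipped to [0, 1] (``Vmax`` slightly above 1 can
    push the MAF term past the ceiling) and stored separately; the
    total is their product.
    """
    n = len(stats.marker_indices)
    rows = np.empty((n, 4))
    chosen = np.empty(n, dtype=np.int64)
    for i in range(n):
        best, rd, rm, _ = select_best_neighbor(
            stats.neighbor_morgan[i], stats.neighbor_dmaf[i], ne=ne, variant=variant
        )
        chosen[i] = best
        rows[i, 0] = rd
        rows[i, 1] = rm
    rows[:, 0] = np.clip(rows[:, 0], 0.0, 1.0)
    rows[:, 1] = np.clip(rows[:, 1], 0.0, 1.0)
    rows[:, 2] = np.clip(mmfit.predict(stats.maf), 0.0, 1.0)
    rows[:, 3] = rows[:, 0] * rows[:, 1] * rows[:, 2]
    return pd.DataFrame(
        {
            "marker_index": stats.marker_indices,
            "maf": stats.maf,
            "chosen_neighbor": chosen,
            "r2_dist": rows[:, 0],
            "r2_dmaf": rows[:, 1],
            "r2_maf": rows[:, 2],
            "r2_total": rows[:, 3],
        }
    )
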