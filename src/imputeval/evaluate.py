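"""Imputation accuracy metrics, filtering and covariate binning.

Accuracy ``r`` is the Pearson correlation between observed genotypes
(0/1/2) and imputed B-allele dosages, computed per SNP (pooled over all
validation individuals of a scenario) and per individual (over that
individual's evaluated markers).  A correlation requires variation in
both vectors, so markers whose observed genotypes or dosages are
constant within any validation group are removed first; the same rule a
sequencing study applies before correlating called and imputed
genotypes.

Per-individual accuracy can be reported raw, after centering both
vectors by the per-marker mean observed genotype, or additionally
standardised by the per-marker observed genotype standard deviation.
Centering removes the allele-frequency component that inflates raw
per-individual correlations.

For the reliability analysis, markers are sorted by a covariate
(distance to the nearest panel SNP, MAF, MAF difference, or predicted
reliability) and cut into consecutive bins of 1000, reporting the mean
covariate and mean observed reliability (r^2) per bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sim import GenotypeMatrix, MarkerMap
from .panels import PanelDefinition

__all__ = [
    "MarkerStats",
    "filter_informative",
    "accuracy_per_snp",
    "accuracy_per_snp_matrix",
    "accuracy_per_individual",
    "compute_marker_stats",
    "bin_by_covariate",
]

N_NEIGHBORS = 5


def filter_informative(
    observed: np.ndarray,
    dosages: np.ndarray,
    validation_groups: list[np.ndarray],
) -> np.ndarray:
    """Mask of markers informative in every validation group.

    A marker is kept iff, within each validation group, the observed
    genotypes are non-constant and the dosages are non-constant.
    ``observed`` and ``dosages`` are aligned (N, L) arrays;
    ``validation_groups`` holds row-index arrays, one per group.
    """
    observed = np.asarray(observed)
    dosages = np.asarray(dosages)
    if observed.shape != dosages.shape:
        raise ValueError("observed and dosages must be aligned")
    keep = np.ones(observed.shape[1], dtype=bool)
    for rows in validation_groups:
        rows = np.asarray(rows)
        if len(rows) == 0:
            raise ValueError("empty validation group")
        obs_g = observed[rows]
        dos_g = dosages[rows]
        keep &= np.ptp(obs_g, axis=0) > 0
        keep &= np.ptp(dos_g, axis=0) > 0
    return keep


def accuracy_per_snp(observed: np.ndarray, dosage: np.ndarray) -> float:
    """Pearson correlation of one marker's observed genotypes vs dosages."""
    observed = np.asarray(observed, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    if np.ptp(observed) == 0 or np.ptp(dosage) == 0:
        raise ValueError(
            "constant vector reached the correlation; markers must be "
            "filtered with filter_informative first"
        )
    return float(np.corrcoef(observed, dosage)[0, 1])


def accuracy_per_snp_matrix(observed: np.ndarray, dosages: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlations for pre-filtered markers."""
    obs = np.asarray(observed, dtype=np.float64)
    dos = np.asarray(dosages, dtype=np.float64)
    oc = obs - obs.mean(axis=0)
    dc = dos - dos.mean(axis=0)
    num = (oc * dc).sum(axis=0)
    den = np.sqrt((oc**2).sum(axis=0) * (dc**2).sum(axis=0))
    if np.any(den == 0):
        raise ValueError("constant column reached the correlation")
    return num / den


def accuracy_per_individual(
    observed: np.ndarray,
    dosage: np.ndarray,
    mode: str = "raw",
    marker_means: np.ndarray | None = None,
    marker_sds: np.ndarray | None = None,
) -> float:
    """Accuracy for one individual over its evaluated markers.

    ``marker_means``/``marker_sds`` are the per-marker mean and standard
    deviation of the observed genotypes over the validation individuals
    of the fold; they are required for the ``centered`` and
    ``standardized`` modes.  Returns NaN when the correlation is
    undefined (all markers constant for this individual).
    """
    obs = np.asarray(observed, dtype=float)
    dos = np.asarray(dosage, dtype=float)
    if obs.shape != dos.shape or obs.ndim != 1:
        raise ValueError("observed and dosage must be aligned vectors")
    if len(obs) < 2:
        raise ValueError("need at least 2 evaluated markers")
    if mode == "raw":
        a, b = obs, dos
    elif mode in ("centered", "standardized"):
        if marker_means is None:
            raise ValueError(f"mode {mode!r} requires marker_means")
        a = obs - marker_means
        b = dos - marker_means
        if mode == "standardized":
            if marker_sds is None:
                raise ValueError("mode 'standardized' requires marker_sds")
            with np.errstate(invalid="ignore", divide="ignore"):
                a = a / marker_sds
                b = b / marker_sds
            ok = marker_sds > 0
            a, b = a[ok], b[ok]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if len(a) < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class MarkerStats:
    """Per-marker covariates for the reliability analysis.

    All arrays are aligned with ``marker_indices``, the non-panel
    markers being evaluated.  Neighbor arrays have one row per marker
    and :data:`N_NEIGHBORS` columns ordered nearest first, padded with
    -1 / NaN near chromosome ends.
    """

    marker_indices: np.ndarray
    maf: np.ndarray
    nearest_panel_index: np.ndarray
    distance_bp: np.ndarray
    distance_morgan: np.ndarray
    dmaf_nearest: np.ndarray
    neighbor_indices: np.ndarray
    neighbor_morgan: np.ndarray
    neighbor_dmaf: np.ndarray


def compute_marker_stats(
    marker_map: MarkerMap,
    panel: PanelDefinition,
    genos: GenotypeMatrix,
    marker_indices: np.ndarray | None = None,
) -> MarkerStats:
    """Distance/MAF covariates of non-panel markers w.r.t. a panel.

    For each evaluated marker: the nearest panel SNP by physical
    distance (ties to the lower position), its distance in bp and
    Morgan, the marker's own MAF (from the full genotype set), and the
    five nearest panel SNPs with their genetic distances and absolute
    MAF differences.
    """
    if len(panel) == 0:
        raise ValueError("panel is empty")
    maf_all = genos.maf()
    pos = marker_map.positions_bp
    pos_m = marker_map.positions_morgan
    panel_idx = panel.marker_indices
    panel_pos = pos[panel_idx]

    if marker_indices is None:
        marker_indices = np.setdiff1d(np.arange(len(marker_map)), panel_idx)
    marker_indices = np.asarray(marker_indices)
    n = len(marker_indices)

    nn_index = np.full(n, -1, dtype=np.int64)
    dist_bp = np.zeros(n, dtype=np.int64)
    dist_m = np.zeros(n)
    dmaf_nn = np.zeros(n)
    nb_idx = np.full((n, N_NEIGHBORS), -1, dtype=np.int64)
    nb_morgan = np.full((n, N_NEIGHBORS), np.nan)
    nb_dmaf = np.full((n, N_NEIGHBORS), np.nan)

    ins = np.searchsorted(panel_pos, pos[marker_indices])
    for i, (mk, at) in enumerate(zip(marker_indices, ins)):
        lo = max(0, at - N_NEIGHBORS)
        hi = min(len(panel_idx), at + N_NEIGHBORS)
        cand = np.arange(lo, hi)
        d = np.abs(panel_pos[cand] - pos[mk])
        # nearest first; ties broken toward the lower position
        order = np.lexsort((panel_pos[cand], d))
        cand = cand[order][:N_NEIGHBORS]
        k = len(cand)
        sel = panel_idx[cand]
        nb_idx[i, :k] = sel
        nb_morgan[i, :k] = np.abs(pos_m[sel] - pos_m[mk])
        nb_dmaf[i, :k] = np.abs(maf_all[sel] - maf_all[mk])
        nn_index[i] = sel[0]
        dist_bp[i] = abs(pos[sel[0]] - pos[mk])
        dist_m[i] = abs(pos_m[sel[0]] - pos_m[mk])
        dmaf_nn[i] = nb_dmaf[i, 0]

    return MarkerStats(
        marker_indices=marker_indices,
        maf=maf_all[marker_indices],
        nearest_panel_index=nn_index,
        distance_bp=dist_bp,
        distance_morgan=dist_m,
        dmaf_nearest=dmaf_nn,
        neighbor_indices=nb_idx,
        neighbor_morgan=nb_morgan,
        neighbor_dmaf=nb_dmaf,
    )


def bin_by_covariate(
    values: np.ndarray,
    covariate: np.ndarray,
    bin_size: int = 1000,
    positions: np.ndarray | None = None,
) -> pd.DataFrame:
    """Bin markers by a covariate and summarise reliability per bin.

    Markers are stably sorted by the covariate (ties by position) and
    sliced into consecutive runs of ``bin_size``; the last bin may be
    smaller.  ``values`` are per-marker accuracies ``r``; the summary
    reports the mean covariate and the mean of ``r^2`` per bin.
    """
    values = np.asarray(values, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if values.shape != covariate.shape:
        raise ValueError("values and covariate must be aligned")
    if len(values) == 0:
        return pd.DataFrame(
            columns=["bin_index", "covariate_mean", "reliability_mean", "n_markers"]
        )
    if positions is None:
        positions = np.arange(len(values))
    order = np.lexsort((np.asarray(positions), covariate))
    rows = []
    for b, start in enumerate(range(0, len(values), bin_size)):
        sl = order[start : start + bin_size]
        rows.append(
            {
                "bin_index": b,
                "covariate_mean": covariate[sl].mean(),
                "reliability_mean": (values[sl] ** 2).mean(),
                "n_markers": len(sl),
            }
        )
    return pd.DataFrame(rows)
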