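"""Marker panels: array-style ascertainment, masking, overlap bookkeeping.

Commercial SNP arrays are not random subsets of sequence variants: their
markers are ascertained toward high minor-allele frequency and roughly
even physical spacing.  :func:`build_panel` emulates both features with
a windowed greedy pick; :func:`mask_to_panel` plays the role of masking
a validation individual's sequence genotypes down to the array content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

from .sim import GenotypeMatrix, MarkerMap, MISSING

__all__ = [
    "PanelDefinition",
    "build_panel",
    "mask_to_panel",
    "panel_overlap_report",
    "percent_of_sequence",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero (report-style rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent_of_sequence(panel_count: int, sequence_count: int) -> float:
    """Panel size as a percentage of the sequence marker count, 2 dp."""
    if sequence_count <= 0:
        raise ValueError("sequence_count must be positive")
    return round_half_up(100.0 * panel_count / sequence_count, 2)


@dataclass
class PanelDefinition:
    """An ordered subset of markers on a shared map.

    ``marker_indices`` index into the :class:`~imputeval.sim.MarkerMap`
    that all panels of a study share (the "sequence" marker set).
    """

    name: str
    marker_indices: np.ndarray
    marker_map: MarkerMap
    ascertainment: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = np.asarray(self.marker_indices, dtype=np.int64)
        if idx.ndim != 1:
            raise ValueError("marker_indices must be one-dimensional")
        if len(idx) and (np.any(np.diff(idx) <= 0)):
            raise ValueError("marker_indices must be strictly increasing")
        if len(idx) and (idx[0] < 0 or idx[-1] >= len(self.marker_map)):
            raise ValueError("marker_indices out of range for the marker map")
        self.marker_indices = idx

    def __len__(self) -> int:
        return len(self.marker_indices)

    @property
    def positions_bp(self) -> np.ndarray:
        return self.marker_map.positions_bp[self.marker_indices]

    def is_subset_of(self, other: "PanelDefinition") -> bool:
        return bool(np.isin(self.marker_indices, other.marker_indices).all())


def build_panel(
    marker_map: MarkerMap,
    genos: GenotypeMatrix,
    maf_min: float,
    target_count: int,
    name: str = "panel",
    within: PanelDefinition | None = None,
    exclude_positions_bp: np.ndarray | None = None,
) -> PanelDefinition:
    """Ascertain an approximately evenly spaced, high-MAF panel.

    The chromosome span is cut into ``target_count`` windows; in each
    window the eligible marker (MAF >= ``maf_min``) with the highest MAF
    is picked.  Empty windows are skipped and the shortfall is backfilled
    by repeatedly placing a marker inside the largest remaining inter-
    marker gap.  Pass ``within`` to restrict candidates to an existing
    panel, which guarantees nestedness.  ``exclude_positions_bp`` drops
    candidate positions up front, emulating array positions that do not
    segregate in the sequence data and so leave coverage gaps.
    """
    if not marker_map.same_markers(genos.marker_map):
        raise ValueError("marker_map does not match the genotype matrix")
    maf = genos.maf()
    candidates = np.flatnonzero(maf >= maf_min)
    if within is not None:
        candidates = candidates[np.isin(candidates, within.marker_indices)]
    if exclude_positions_bp is not None:
        dropped = np.isin(marker_map.positions_bp[candidates], exclude_positions_bp)
        candidates = candidates[~dropped]
    if len(candidates) < target_count:
        raise ValueError(
            f"only {len(candidates)} markers have MAF >= {maf_min}; "
            f"{target_count} requested"
        )

    pos = marker_map.positions_bp
    span_lo = pos[candidates].min()
    span_hi = pos[candidates].max()
    edges = np.linspace(span_lo, span_hi + 1, target_count + 1)

    chosen: list[int] = []
    taken = np.zeros(len(pos), dtype=bool)
    for w in range(target_count):
        in_win = candidates[
            (pos[candidates] >= edges[w]) & (pos[candidates] < edges[w + 1])
        ]
        in_win = in_win[~taken[in_win]]
        if len(in_win) == 0:
            continue
        best = in_win[np.argmax(maf[in_win])]
        chosen.append(int(best))
        taken[best] = True

    # backfill: drop a marker into the largest remaining gap each round
    while len(chosen) < target_count:
        free = candidates[~taken[candidates]]
        sel = np.sort(np.asarray(chosen, dtype=np.int64))
        gap_edges = np.concatenate(([span_lo], pos[sel], [span_hi]))
        gaps = np.diff(gap_edges)
        for g in np.argsort(gaps)[::-1]:
            lo, hi = gap_edges[g], gap_edges[g + 1]
            inside = free[(pos[free] > lo) & (pos[free] < hi)]
            if len(inside) == 0:
                inside = free  # no eligible marker in any gap interior
            best = inside[np.argmax(maf[inside])]
            chosen.append(int(best))
            taken[best] = True
            break

    indices = np.sort(np.asarray(chosen, dtype=np.int64))
    return PanelDefinition(
        name=name,
        marker_indices=indices,
        marker_map=marker_map,
        ascertainment={"maf_min": maf_min, "target_count": target_count},
    )


def mask_to_panel(genos: GenotypeMatrix, panel: PanelDefinition) -> GenotypeMatrix:
    """Set every genotype outside the panel to missing."""
    if not panel.marker_map.same_markers(genos.marker_map):
        raise ValueError("panel and genotypes use different marker maps")
    masked = np.full_like(genos.genotypes, MISSING)
    masked[:, panel.marker_indices] = genos.genotypes[:, panel.marker_indices]
    return GenotypeMatrix(
        genotypes=masked,
        marker_map=genos.marker_map,
        individual_ids=list(genos.individual_ids),
        source_hap_indices=genos.source_hap_indices,
    )


def panel_overlap_report(panels: list[PanelDefinition]) -> dict:
    """Pairwise overlap counts and percentages of the sequence set.

    Percentages are relative to the number of markers on the shared map
    (the sequence panel) and rounded half-up to two decimals, the
    convention used in study reports.
    """
    if not panels:
        raise ValueError("no panels given")
    base = panels[0].marker_map
    for p in panels[1:]:
        if not p.marker_map.same_markers(base):
            raise ValueError("panels reference different marker maps")
    n_seq = len(base)
    report: dict = {
        "n_sequence_markers": n_seq,
        "panel_sizes": {p.name: len(p) for p in panels},
        "percent_of_sequence": {
            p.name: round_half_up(100.0 * len(p) / n_seq, 2) for p in panels
        },
        "pairwise_overlap": {},
    }
    for i, a in enumerate(panels):
        for b in panels[i + 1 :]:
            n = int(np.isin(a.marker_indices, b.marker_indices).sum())
            report["pairwise_overlap"][(a.name, b.name)] = n
    return report
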