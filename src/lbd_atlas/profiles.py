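"""Per-genome profiles of highly plant-specific LBDs.

For each genome, counts how many of its LBDs belong to clusters with a high
broad-lifestyle DPS and the proportion these represent of all its LBDs,
stratified by lifestyle class. Classes are mutually exclusive with priority
symbiont > phytopathogen > other plant-associated > non-plant-associated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .clustering import LBDCluster
from .io_formats import LifestyleDB
from .lbd_extract import LBDRecord
from .specificity import DPSRecord

LIFESTYLE_CLASSES = ("symb", "phyto", "other_pab", "non_pab")

DEFAULT_PROPORTION_BINS = tuple(np.linspace(0.0, 1.0, 11))  # deciles
DEFAULT_COUNT_BIN_WIDTH = 5


@dataclass(frozen=True)
class GenomeProfile:
    species_id: str
    lifestyle_class: str
    n_lbds: int
    n_high_dps: int

    @property
    def proportion(self) -> float:
        return self.n_high_dps / self.n_lbds if self.n_lbds else 0.0


def lifestyle_class(species_id: str, db: LifestyleDB) -> str:
    if species_id in db.symb:
        return "symb"
    if species_id in db.phyto:
        return "phyto"
    if species_id in db.broad:
        return "other_pab"
    return "non_pab"


def genome_profiles(
    lbds: Sequence[LBDRecord],
    clusters: Sequence[LBDCluster],
    dps_records: Sequence[DPSRecord],
    db: LifestyleDB,
    threshold: float = 80.0,
) -> list:
    """One :class:`GenomeProfile` per species carrying at least one CR LBD.

    An LBD is high-DPS iff the cluster containing it has
    ``dps_broad >= threshold``. Every LBD must be assigned to exactly one
    cluster.
    """
    cluster_of: dict = {}
    for c in clusters:
        for mid in c.member_lbd_ids:
            cluster_of[mid] = c.cluster_id
    dps_of = {r.cluster_id: r.dps_broad for r in dps_records}

    totals: dict = {}
    highs: dict = {}
    for lbd in lbds:
        if lbd.lbd_id not in cluster_of:
            raise ValueError(f"LBD {lbd.lbd_id} has no cluster assignment")
        totals[lbd.species_id] = totals.get(lbd.species_id, 0) + 1
        if dps_of[cluster_of[lbd.lbd_id]] >= threshold:
            highs[lbd.species_id] = highs.get(lbd.species_id, 0) + 1
    return [
        GenomeProfile(
            species_id=sp,
            lifestyle_class=lifestyle_class(sp, db),
            n_lbds=totals[sp],
            n_high_dps=highs.get(sp, 0),
        )
        for sp in sorted(totals)
    ]


def _check_bins(edges: Sequence[float]) -> np.ndarray:
    arr = np.asarray(edges, dtype=float)
    if arr.ndim != 1 or len(arr) < 2 or np.any(np.diff(arr) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    return arr


def profile_histograms(
    profiles: Sequence[GenomeProfile],
    proportion_bins: Sequence[float] = DEFAULT_PROPORTION_BINS,
    count_bins: Sequence[float] | None = None,
) -> tuple:
    """Species counts per bin per lifestyle class.

    Returns ``(proportion_table, count_table)``; each table maps
    lifestyle class → array of per-bin species counts. Bins are half-open
    ``[lo, hi)`` with the final bin closed (numpy convention), so a
    proportion of exactly 0.5 with edges ``[0, 0.5, 1]`` lands in the upper
    bin. Species with zero LBDs are excluded from the proportion histogram.
    """
    p_edges = _check_bins(proportion_bins)
    if count_bins is None:
        max_count = max((p.n_high_dps for p in profiles), default=0)
        upper = max(DEFAULT_COUNT_BIN_WIDTH, DEFAULT_COUNT_BIN_WIDTH * (
            max_count // DEFAULT_COUNT_BIN_WIDTH + 1))
        count_bins = np.arange(0, upper + 1, DEFAULT_COUNT_BIN_WIDTH)
    c_edges = _check_bins(count_bins)

    prop_table: dict = {}
    count_table: dict = {}
    for cls in LIFESTYLE_CLASSES:
        members = [p for p in profiles if p.lifestyle_class == cls]
        props = [p.proportion for p in members if p.n_lbds > 0]
        counts = [p.n_high_dps for p in members]
        prop_table[cls], _ = np.histogram(props, bins=p_edges)
        count_table[cls], _ = np.histogram(counts, bins=c_edges)
    return (prop_table, p_edges), (count_table, c_edges)
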