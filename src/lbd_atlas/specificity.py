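"""Degree-of-plant-specificity (DPS) scoring of LBD clusters.

DPS of a cluster against a reference species set R is the percentage of the
cluster's *distinct* member species that belong to R. Three nested
reference sets are scored: all plant-associated bacteria (broad), the
phytopathogen subset and the plant-symbiont subset, so for every cluster
``dps_phyto <= dps_broad`` and ``dps_symb <= dps_broad``. The statistic is
species-level: adding another sequence from an already-present species
leaves it unchanged. A sequence-weighted variant is available for
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from .clustering import LBDCluster
from .io_formats import LifestyleDB

#: The two conventional "high specificity" DPS percentage cutoffs.
HIGH_DPS_THRESHOLDS = (50.0, 80.0)


@dataclass(frozen=True)
class DPSRecord:
    """The three specificity percentages of one cluster (unrounded)."""

    cluster_id: int
    dps_broad: float
    dps_phyto: float
    dps_symb: float
    n_species: int
    size: int

    def as_row(self) -> dict:
        return {
            "cluster_id": self.cluster_id,
            "size": self.size,
            "n_species": self.n_species,
            "dps_broad": round_pct(self.dps_broad),
            "dps_phyto": round_pct(self.dps_phyto),
            "dps_symb": round_pct(self.dps_symb),
        }


def round_pct(value: float) -> str:
    """Percentage formatted to 2 decimals, rounding half up (output only;
    comparisons always use unrounded values)."""
    return str(Decimal(repr(value)).quantize(Decimal("0.01"), ROUND_HALF_UP))


def compute_dps(
    cluster: LBDCluster,
    db: LifestyleDB,
    weighting: str = "species",
    lbd_species: Mapping[str, str] | None = None,
) -> DPSRecord:
    """Score one cluster against the three lifestyle reference sets.

    ``weighting="species"`` (default) uses distinct member species;
    ``weighting="sequences"`` weights by member sequences and requires
    *lbd_species* (lbd_id → species_id).
    """
    if not cluster.member_species:
        raise ValueError(f"cluster {cluster.cluster_id} has no member species")
    if weighting == "species":
        units = list(cluster.member_species)
    elif weighting == "sequences":
        if lbd_species is None:
            raise ValueError("sequence weighting requires lbd_species")
        units = [lbd_species[mid] for mid in cluster.member_lbd_ids]
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    n = len(units)
    pct = {
        name: 100.0 * sum(1 for u in units if u in ref) / n
        for name, ref in db.sets().items()
    }
    return DPSRecord(
        cluster_id=cluster.cluster_id,
        dps_broad=pct["broad"],
        dps_phyto=pct["phyto"],
        dps_symb=pct["symb"],
        n_species=len(cluster.member_species),
        size=cluster.size,
    )


def compute_all_dps(
    clusters: Sequence[LBDCluster], db: LifestyleDB, weighting: str = "species",
    lbd_species: Mapping[str, str] | None = None,
) -> list:
    return [compute_dps(c, db, weighting, lbd_species) for c in clusters]


def high_dps(
    records: Iterable[DPSRecord],
    threshold: float = 50.0,
    which: str = "broad",
    exclude_singletons: bool = True,
) -> list:
    """Clusters whose DPS against *which* reaches *threshold* (inclusive).

    Singletons are excluded by default: specificity of a one-sequence
    cluster carries no grouping information.
    """
    if not 0 <= threshold <= 100:
        raise ValueError("threshold must be in [0, 100]")
    attr = f"dps_{which}"
    out = []
    for rec in records:
        if exclude_singletons and rec.size == 1:
            continue
        if getattr(rec, attr) >= threshold:
            out.append(rec)
    return out


def dps_by_type(
    high_records: Sequence[DPSRecord], clusters_by_id: Mapping[int, LBDCluster]
) -> list:
    """Tabulate high-DPS clusters per LBD type.

    Compact clusters are attributed to their dominant label; mixed clusters
    are tabulated under ``"mixed"``. Returns rows with cluster count,
    sequence count and mean sequences per cluster (2 decimals in output).
    """
    agg: dict = {}
    for rec in high_records:
        cluster = clusters_by_id[rec.cluster_id]
        label = (
            cluster.dominant_label if cluster.classification == "compact" else "mixed"
        )
        n_clusters, n_seqs = agg.get(label, (0, 0))
        agg[label] = (n_clusters + 1, n_seqs + cluster.size)
    rows = []
    for label in sorted(agg, key=lambda k: (-agg[k][0], k)):
        n_clusters, n_seqs = agg[label]
        rows.append(
            {
                "label": label,
                "n_clusters": n_clusters,
                "n_sequences": n_seqs,
                "mean_sequences_per_cluster": mean_sequences_per_cluster(
                    n_seqs, n_clusters
                ),
            }
        )
    return rows


def mean_sequences_per_cluster(n_sequences: int, n_clusters: int) -> float:
    """Average cluster size of a type: sequences over clusters."""
    if n_clusters < 1:
        raise ValueError("need at least one cluster")
    return n_sequences / n_clusters


def type_concentration(n_sequences_high_dps: int, n_sequences_total: int) -> float:
    """Percentage of a type's sequences that sit in its high-DPS clusters."""
    if n_sequences_total < 1 or n_sequences_high_dps > n_sequences_total:
        raise ValueError("invalid sequence counts")
    return 100.0 * n_sequences_high_dps / n_sequences_total
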