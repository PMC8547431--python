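"""Homology clustering of LBD sequences.

A greedy centroid algorithm in the style of cascaded sequence-clustering
tools: sequences are processed longest-first, each unassigned sequence
founds a new cluster, and every remaining sequence joins it when the local
alignment against the centroid reaches the identity and query-coverage
thresholds (coverage is evaluated with the member as query, the analogue of
query-only coverage mode). Defaults are the relaxed remote-homology
thresholds used for LBD family inference: 20% identity, 50% coverage.

Clusters are classified ``compact`` when at least 90% of members share one
domain label (singletons trivially so), otherwise ``mixed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import biotite.sequence as bioseq
import biotite.sequence.align as bioalign

from .lbd_extract import LBDRecord

#: Fraction of members sharing one label for a cluster to be "compact".
COMPACT_FRACTION = 0.90

#: A label grouping into fewer than this many compact clusters is
#: "low-abundance".
LOW_ABUNDANCE_CLUSTERS = 12


@dataclass(frozen=True)
class AlignmentStats:
    """Identity, query coverage and score of one optimal local alignment.

    ``identity`` is identical residue pairs over alignment columns;
    ``query_coverage`` is aligned query residues over query length.
    """

    identity: float
    query_coverage: float
    score: float


#: Raw-score stand-in for the search stage's E-value cutoff. Karlin-Altschul
#: statistics are unstable on a desk-scale database, so the significance
#: filter is a fixed raw alignment score: for gapped BLOSUM62 statistics
#: (lambda ~ 0.267, K ~ 0.041) a raw score of 60 corresponds to E ~ 0.01
#: against a database of a few thousand LBD-sized sequences.
DEFAULT_MIN_SCORE = 60.0


@dataclass
class ClusterParams:
    min_identity: float = 0.20
    min_query_coverage: float = 0.50
    min_score: float = DEFAULT_MIN_SCORE
    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1

    def __post_init__(self) -> None:
        for f in (self.min_identity, self.min_query_coverage):
            if not 0 < f <= 1:
                raise ValueError("thresholds must be in (0, 1]")


@dataclass
class LBDCluster:
    """One homology cluster of LBD records."""

    cluster_id: int
    centroid_lbd_id: str
    member_lbd_ids: tuple
    member_species: frozenset
    classification: str = ""  # compact | mixed | singleton handled via is_singleton
    dominant_label: str = ""
    dominant_fraction: float = 0.0

    @property
    def size(self) -> int:
        return len(self.member_lbd_ids)

    @property
    def is_singleton(self) -> bool:
        return self.size == 1


_MATRICES: dict = {}


def _matrix(name: str) -> bioalign.SubstitutionMatrix:
    if name not in _MATRICES:
        alph = bioseq.ProteinSequence.alphabet
        _MATRICES[name] = bioalign.SubstitutionMatrix(alph, alph, name)
    return _MATRICES[name]


def _local_alignment_counts(
    query_seq: str, target_seq: str, matrix: str, gap_open: int, gap_extend: int
) -> tuple:
    """(score, matches, n_columns, q_aligned, t_aligned) of the optimal
    local alignment."""
    if not query_seq or not target_seq:
        raise ValueError("empty sequence")
    q = bioseq.ProteinSequence(query_seq)
    t = bioseq.ProteinSequence(target_seq)
    aln = bioalign.align_optimal(
        q, t, _matrix(matrix), gap_penalty=(-gap_open, -gap_extend), local=True,
        max_number=1,
    )[0]
    matches = q_aligned = t_aligned = 0
    qc, tc = q.code, t.code
    for qi, ti in aln.trace:
        if qi != -1:
            q_aligned += 1
        if ti != -1:
            t_aligned += 1
        if qi != -1 and ti != -1 and qc[qi] == tc[ti]:
            matches += 1
    return float(aln.score), matches, len(aln.trace), q_aligned, t_aligned


def align_local(
    query_seq: str,
    target_seq: str,
    matrix: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
) -> AlignmentStats:
    """Optimal local alignment (affine gaps) of *query_seq* vs *target_seq*.

    Ambiguous residues (X) score as their substitution-matrix entries, i.e.
    effectively as mismatches. The score is symmetric in the two sequences.
    """
    score, matches, n_cols, q_aligned, _ = _local_alignment_counts(
        query_seq, target_seq, matrix, gap_open, gap_extend
    )
    if n_cols == 0:
        return AlignmentStats(identity=0.0, query_coverage=0.0, score=score)
    return AlignmentStats(
        identity=matches / n_cols,
        query_coverage=q_aligned / len(query_seq),
        score=score,
    )


def align_local_pair(
    seq_a: str, seq_b: str, params: "ClusterParams | None" = None
) -> tuple:
    """Stats of one optimal local alignment read from both query sides.

    Returns ``(stats_a_as_query, stats_b_as_query)``; score and identity are
    shared, only the coverage changes with the query side.
    """
    params = params or ClusterParams()
    score, matches, n_cols, a_aligned, b_aligned = _local_alignment_counts(
        seq_a, seq_b, params.matrix, params.gap_open, params.gap_extend
    )
    identity = matches / n_cols if n_cols else 0.0
    return (
        AlignmentStats(identity, a_aligned / len(seq_a), score),
        AlignmentStats(identity, b_aligned / len(seq_b), score),
    )


def accepts_stats(stats: AlignmentStats, params: ClusterParams) -> bool:
    """The member-joins-centroid acceptance predicate on precomputed stats."""
    return (
        stats.score >= params.min_score
        and stats.identity >= params.min_identity
        and stats.query_coverage >= params.min_query_coverage
    )


def _accepts(member: LBDRecord, centroid: LBDRecord, params: ClusterParams) -> bool:
    stats = align_local(
        member.sequence,
        centroid.sequence,
        matrix=params.matrix,
        gap_open=params.gap_open,
        gap_extend=params.gap_extend,
    )
    return (
        stats.score >= params.min_score
        and stats.identity >= params.min_identity
        and stats.query_coverage >= params.min_query_coverage
    )


def seed_order(lbds: Sequence[LBDRecord]) -> list:
    """Processing order: length descending, ties by lbd_id."""
    return sorted(lbds, key=lambda l: (-l.length, l.lbd_id))


def greedy_cluster(
    lbds: Sequence[LBDRecord], params: ClusterParams | None = None
) -> list:
    """Greedy centroid clustering of *lbds* at the configured thresholds.

    Single pass, no reassignment: deterministic for fixed input, and
    independent of the input order (the processing order is recomputed).
    """
    if not lbds:
        raise ValueError("no LBD sequences to cluster")
    params = params or ClusterParams()
    ordered = seed_order(lbds)
    assigned = [False] * len(ordered)
    clusters: list = []
    for i, centroid in enumerate(ordered):
        if assigned[i]:
            continue
        assigned[i] = True
        members = [centroid]
        for j in range(i + 1, len(ordered)):
            if assigned[j]:
                continue
            if _accepts(ordered[j], centroid, params):
                assigned[j] = True
                members.append(ordered[j])
        clusters.append(
            LBDCluster(
                cluster_id=len(clusters),
                centroid_lbd_id=centroid.lbd_id,
                member_lbd_ids=tuple(m.lbd_id for m in members),
                member_species=frozenset(m.species_id for m in members),
            )
        )
    labels = {l.lbd_id: l.label for l in lbds}
    for c in clusters:
        classify_cluster(c, labels)
    return clusters


def classify_cluster(cluster: LBDCluster, lbd_labels: Mapping[str, str]) -> str:
    """Set and return the cluster's compact/mixed classification.

    ``compact`` iff >= 90% of members share one label (which may be
    ``"unknown"``); singletons are compact at fraction 1. Ties between
    labels break lexicographically.
    """
    tally: dict = {}
    for mid in cluster.member_lbd_ids:
        lab = lbd_labels[mid]
        tally[lab] = tally.get(lab, 0) + 1
    dominant = min(tally, key=lambda k: (-tally[k], k))
    frac = tally[dominant] / cluster.size
    cluster.dominant_label = dominant
    cluster.dominant_fraction = frac
    cluster.classification = "compact" if frac >= COMPACT_FRACTION else "mixed"
    return cluster.classification


def import_clusters(path, lbds: Sequence[LBDRecord]) -> list:
    """Rebuild clusters from a representative→member TSV (external tool output).

    The mapping must cover every LBD exactly once; the representative is
    taken as the centroid.
    """
    by_id = {l.lbd_id: l for l in lbds}
    mapping: dict = {}
    seen: set = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            rep, member = cols[0], cols[1]
            if member not in by_id:
                raise ValueError(f"{path}:{lineno}: unknown member {member}")
            if member in seen:
                raise ValueError(f"{path}:{lineno}: member {member} in two clusters")
            seen.add(member)
            mapping.setdefault(rep, []).append(member)
    missing = set(by_id) - seen
    if missing:
        raise ValueError(f"mapping omits {len(missing)} LBDs: {sorted(missing)[:5]}")
    labels = {l.lbd_id: l.label for l in lbds}
    clusters = []
    for rep in sorted(mapping):
        members = sorted(mapping[rep])
        c = LBDCluster(
            cluster_id=len(clusters),
            centroid_lbd_id=rep,
            member_lbd_ids=tuple(members),
            member_species=frozenset(by_id[m].species_id for m in members),
        )
        classify_cluster(c, labels)
        clusters.append(c)
    return clusters


def export_clusters(clusters: Sequence[LBDCluster], path) -> None:
    """Write clusters as a representative→member TSV (import round-trips)."""
    with open(path, "w") as fh:
        for c in sorted(clusters, key=lambda c: c.centroid_lbd_id):
            for member in sorted(c.member_lbd_ids):
                fh.write(f"{c.centroid_lbd_id}\t{member}\n")


def low_abundance_types(clusters: Sequence[LBDCluster]) -> set:
    """Labels whose compact-cluster count is below the low-abundance cutoff."""
    counts: dict = {}
    for c in clusters:
        if c.classification == "compact":
            counts[c.dominant_label] = counts.get(c.dominant_label, 0) + 1
    return {lab for lab, n in counts.items() if n < LOW_ABUNDANCE_CLUSTERS}


def non_singleton_count(cluster_sizes: Sequence[int]) -> int:
    """Number of clusters containing more than one sequence."""
    return sum(1 for s in cluster_sizes if s > 1)
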