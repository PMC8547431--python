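"""Chemoreceptor identification and the per-genome CR catalogue.

A protein is a chemoreceptor (CR) iff it carries at least one MCPsignal
domain hit scoring at or above the bit-score threshold — presence of the
highly conserved cytosolic signaling domain is the sole criterion. When a
protein has several qualifying MCPsignal hits, the highest-scoring one is
retained (ties: smaller ``ali_start``, then smaller ``ali_end``), so each
CR contributes exactly one record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import DomainHit, LifestyleDB, TMSegment

MCP_DOMAIN = "MCPsignal"
#: Domains never considered ligand-binding candidates: the signaling domain
#: itself and the HAMP membrane-proximal linker.
EXCLUDED_DOMAINS = frozenset({MCP_DOMAIN, "HAMP"})

#: Stand-in for the Pfam gathering threshold of the MCPsignal model (bits).
DEFAULT_SCORE_THRESHOLD = 25.0


@dataclass
class CRRecord:
    """One chemoreceptor protein with its retained MCPsignal hit."""

    protein_id: str
    species_id: str
    sequence: str
    mcp_hit: DomainHit
    tm_segments: tuple = ()
    other_hits: tuple = ()

    def __post_init__(self) -> None:
        if self.mcp_hit.domain_name != MCP_DOMAIN:
            raise ValueError(
                f"retained hit on {self.protein_id} is not {MCP_DOMAIN}"
            )
        if self.mcp_hit.ali_end > len(self.sequence):
            raise ValueError(
                f"{MCP_DOMAIN} hit beyond sequence end on {self.protein_id}"
            )
        for seg in self.tm_segments:
            if seg.tm_end > len(self.sequence):
                raise ValueError(
                    f"TM segment beyond sequence end on {self.protein_id}"
                )
        self.tm_segments = tuple(
            sorted(self.tm_segments, key=lambda s: (s.tm_start, s.tm_end))
        )


@dataclass
class GenomeCatalog:
    """``species_id → list of CRRecord``; zero-CR species are representable."""

    by_species: dict = field(default_factory=dict)

    @property
    def n_crs(self) -> int:
        return sum(len(v) for v in self.by_species.values())

    def counts(self) -> dict:
        return {sp: len(v) for sp, v in self.by_species.items()}

    def all_records(self) -> list:
        return [cr for sp in sorted(self.by_species) for cr in self.by_species[sp]]


def _best_mcp_hit(hits: Sequence[DomainHit]) -> DomainHit:
    # highest bit score; ties by smaller ali_start, then smaller ali_end
    return min(hits, key=lambda h: (-h.bit_score, h.ali_start, h.ali_end))


def identify_crs(
    hits: Iterable[DomainHit],
    sequences: Mapping[str, str],
    species_map: Mapping[str, str],
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    tm_segments: Iterable[TMSegment] = (),
) -> list:
    """Identify chemoreceptors among *hits* and build their records.

    Returns one :class:`CRRecord` per CR protein, sorted by protein id;
    the result is independent of the input row order. Proteins that
    qualify but lack a sequence or species mapping raise ``KeyError``.
    """
    by_protein: dict = {}
    for hit in hits:
        by_protein.setdefault(hit.protein_id, []).append(hit)
    tm_by_protein: dict = {}
    for seg in tm_segments:
        tm_by_protein.setdefault(seg.protein_id, []).append(seg)

    records = []
    for pid in sorted(by_protein):
        phits = by_protein[pid]
        mcp = [
            h
            for h in phits
            if h.domain_name == MCP_DOMAIN and h.bit_score >= score_threshold
        ]
        if not mcp:
            continue
        if pid not in sequences:
            raise KeyError(f"chemoreceptor {pid} has no sequence")
        if pid not in species_map:
            raise KeyError(f"chemoreceptor {pid} has no species mapping")
        best = _best_mcp_hit(mcp)
        others = tuple(
            sorted(h for h in phits if h.domain_name != MCP_DOMAIN)
        )
        records.append(
            CRRecord(
                protein_id=pid,
                species_id=species_map[pid],
                sequence=sequences[pid],
                mcp_hit=best,
                tm_segments=tuple(tm_by_protein.get(pid, ())),
                other_hits=others,
            )
        )
    return records


def build_catalog(
    records: Iterable[CRRecord], species_universe: Iterable[str] = ()
) -> GenomeCatalog:
    """Group CR records per genome; *species_universe* adds zero-CR species."""
    by_species: dict = {sp: [] for sp in species_universe}
    for rec in records:
        by_species.setdefault(rec.species_id, []).append(rec)
    return GenomeCatalog(by_species=by_species)


def per_genome_counts(catalog: GenomeCatalog) -> dict:
    """Per-species CR counts, including zero-count species."""
    return catalog.counts()


def group_means(counts: Mapping[str, int], partition: Mapping[str, Iterable[str]]) -> dict:
    """Mean CR count per species group for any partition of the universe.

    Groups with no species present in *counts* get ``None``.
    """
    means: dict = {}
    for name, members in partition.items():
        vals = [counts[sp] for sp in members if sp in counts]
        means[name] = sum(vals) / len(vals) if vals else None
    return means


def top_genomes(catalog: GenomeCatalog, db: LifestyleDB, n: int) -> list:
    """The *n* genomes with most CRs, with phytopathogen/symbiont flags.

    Descending by count, ties by species id; flags are ``"P"``/``"S"``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(catalog.counts().items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        {
            "species_id": sp,
            "n_crs": cnt,
            "phyto_flag": "P" if sp in db.phyto else "",
            "symb_flag": "S" if sp in db.symb else "",
        }
        for sp, cnt in ranked[:n]
    ]


def coverage_percentage(n_with_crs: int, n_total: int) -> float:
    """Percentage of genomes carrying at least one chemoreceptor."""
    if n_total <= 0 or n_with_crs < 0 or n_with_crs > n_total:
        raise ValueError("invalid genome counts")
    return 100.0 * n_with_crs / n_total
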