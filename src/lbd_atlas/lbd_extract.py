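"""Ligand-binding-domain (LBD) extraction from chemoreceptor architecture.

Putative LBD regions are inferred per CR by three strategies:

* ``inter_tm`` — the periplasmic region strictly between the first two
  transmembrane helices (the canonical two-TM receptor topology);
* ``n_terminal`` — for single-TM receptors, the region from the N terminus
  to the TM;
* ``domain_based`` — any non-MCPsignal, non-HAMP domain hit, catching
  cytosolic sensor domains and extracellular LBDs whose TMs were missed.

Regions shorter than 30 residues or overlapping the retained MCPsignal hit
are discarded. A domain hit covering at least half of the shorter of itself
and a topology region labels that region; topology regions with no such hit
are labeled ``"unknown"``; domain hits matching no topology region become
stand-alone LBDs at the hit coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .cr_catalog import CRRecord, EXCLUDED_DOMAINS

#: Minimum LBD length in residues, applied to all three strategies.
MIN_LBD_LEN = 30

UNKNOWN_LABEL = "unknown"

#: Length bands (aa, inclusive) of the three main LBD size groups.
DEFAULT_BANDS = ((60, 110), (130, 200), (220, 299))

#: LBDs at or above this length are reported but excluded from histograms.
LONG_LBD_CUTOFF = 500


@dataclass(frozen=True)
class LBDRecord:
    """One extracted ligand-binding region of a chemoreceptor."""

    protein_id: str
    species_id: str
    start: int
    end: int
    strategy: str  # inter_tm | n_terminal | domain_based
    label: str
    sequence: str

    @property
    def lbd_id(self) -> str:
        return f"{self.protein_id}/{self.start}-{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def topology_candidates(cr: CRRecord, min_len: int = MIN_LBD_LEN) -> list:
    """Candidate LBD intervals from the CR's TM topology.

    Returns ``(start, end, strategy)`` tuples. With two or more TMs the
    region between TM1 and TM2 is taken (the first periplasmic loop,
    upstream of the signaling domain in the canonical topology); with
    exactly one TM, the N-terminal region before it. Candidates shorter
    than *min_len* or overlapping the MCPsignal hit are dropped.
    """
    tms = cr.tm_segments
    for seg in tms:
        if seg.tm_end > len(cr.sequence):
            raise ValueError(f"TM beyond sequence end on {cr.protein_id}")
    if len(tms) >= 2:
        raw = [(tms[0].tm_end + 1, tms[1].tm_start - 1, "inter_tm")]
    elif len(tms) == 1:
        raw = [(1, tms[0].tm_start - 1, "n_terminal")]
    else:
        return []
    out = []
    for start, end, strategy in raw:
        if end - start + 1 < min_len:
            continue
        if _overlap(start, end, cr.mcp_hit.ali_start, cr.mcp_hit.ali_end):
            continue
        out.append((start, end, strategy))
    return out


def domain_candidates(cr: CRRecord, min_len: int = MIN_LBD_LEN) -> list:
    """Candidate LBDs from non-MCPsignal, non-HAMP domain hits.

    Mutually overlapping hits (sharing at least one residue) are resolved
    to the highest-scoring one; ties by coordinates then name. Returns
    ``(start, end, domain_name, bit_score)`` tuples sorted by start.
    """
    hits = [
        h
        for h in cr.other_hits
        if h.domain_name not in EXCLUDED_DOMAINS and h.length >= min_len
    ]
    hits.sort(key=lambda h: (-h.bit_score, h.ali_start, h.ali_end, h.domain_name))
    kept: list = []
    for hit in hits:
        if any(_overlap(hit.ali_start, hit.ali_end, k.ali_start, k.ali_end) for k in kept):
            continue
        kept.append(hit)
    kept.sort(key=lambda h: (h.ali_start, h.ali_end))
    return [(h.ali_start, h.ali_end, h.domain_name, h.bit_score) for h in kept]


def extract_lbds(cr: CRRecord, min_len: int = MIN_LBD_LEN) -> list:
    """All LBD records of one chemoreceptor.

    Topology regions are labeled by the best-scoring domain candidate
    covering >= 50% of the shorter of the two intervals (coordinates stay
    topological), or ``"unknown"``; domain candidates consumed by no
    topology region become stand-alone ``domain_based`` records unless they
    touch the MCPsignal hit. Output is deduplicated by coordinates and
    sorted by start.
    """
    topo = topology_candidates(cr, min_len)
    doms = domain_candidates(cr, min_len)

    consumed = [False] * len(doms)
    records: dict = {}
    for start, end, strategy in topo:
        best_label = UNKNOWN_LABEL
        best_score = float("-inf")
        for i, (dstart, dend, dname, dscore) in enumerate(doms):
            shorter = min(end - start + 1, dend - dstart + 1)
            if _overlap(start, end, dstart, dend) * 2 >= shorter:
                consumed[i] = True
                if dscore > best_score:
                    best_score = dscore
                    best_label = dname
        records[(start, end)] = LBDRecord(
            protein_id=cr.protein_id,
            species_id=cr.species_id,
            start=start,
            end=end,
            strategy=strategy,
            label=best_label,
            sequence=cr.sequence[start - 1 : end],
        )
    for i, (dstart, dend, dname, _) in enumerate(doms):
        if consumed[i] or (dstart, dend) in records:
            continue
        if _overlap(dstart, dend, cr.mcp_hit.ali_start, cr.mcp_hit.ali_end):
            continue
        records[(dstart, dend)] = LBDRecord(
            protein_id=cr.protein_id,
            species_id=cr.species_id,
            start=dstart,
            end=dend,
            strategy="domain_based",
            label=dname,
            sequence=cr.sequence[dstart - 1 : dend],
        )
    return [records[k] for k in sorted(records)]


def extract_all(crs: Iterable[CRRecord], min_len: int = MIN_LBD_LEN) -> list:
    """Extract LBDs for every CR, sorted by (protein_id, start)."""
    out: list = []
    for cr in sorted(crs, key=lambda c: c.protein_id):
        out.extend(extract_lbds(cr, min_len))
    return out


@dataclass
class LengthBands:
    """Binned length distribution of the extracted LBDs."""

    bands: tuple
    counts: tuple
    fractions: tuple
    dominant_labels: tuple
    n_total: int
    n_out_of_band: int
    n_long: int  # >= LONG_LBD_CUTOFF, excluded from histogram rendering


def length_bands(
    lbds: Sequence[LBDRecord], bands: tuple = DEFAULT_BANDS
) -> LengthBands:
    """Count LBDs per length band, with the modal label of each band."""
    n_total = len(lbds)
    counts = []
    dominant = []
    in_band_ids: set = set()
    for lo, hi in bands:
        members = [l for l in lbds if lo <= l.length <= hi]
        in_band_ids.update(id(l) for l in members)
        counts.append(len(members))
        if members:
            tally: dict = {}
            for l in members:
                tally[l.label] = tally.get(l.label, 0) + 1
            dominant.append(min(tally, key=lambda k: (-tally[k], k)))
        else:
            dominant.append("")
    fractions = tuple(c / n_total if n_total else 0.0 for c in counts)
    return LengthBands(
        bands=tuple(bands),
        counts=tuple(counts),
        fractions=fractions,
        dominant_labels=tuple(dominant),
        n_total=n_total,
        n_out_of_band=n_total - len(in_band_ids),
        n_long=sum(1 for l in lbds if l.length >= LONG_LBD_CUTOFF),
    )
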