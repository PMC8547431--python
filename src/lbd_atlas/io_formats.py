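"""Readers and writers for the external formats the pipeline touches.

All coordinates are 1-based inclusive residue positions (the HMMER/TMHMM
convention); any conversion happens at parse time only. Canonical internal
tables are TSV; HMMER ``domtblout`` and TMHMM short format are accepted as
dialects so real tool output can be plugged in unchanged. Writers are
byte-deterministic: rows are sorted by primary key, scores are formatted
``%.4f`` and percentages ``%.2f``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "DomainHit",
    "TMSegment",
    "LifestyleDB",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_domtblout",
    "read_tm_segments",
    "read_species_map",
    "read_newick",
    "read_lifestyle_lists",
    "write_table",
    "read_table",
]


class FormatError(ValueError):
    """Malformed or invariant-violating input file content."""


@dataclass(frozen=True, order=True)
class DomainHit:
    """One domain-model match on a protein (e.g. a Pfam hit).

    Coordinates are alignment coordinates, 1-based inclusive.
    """

    protein_id: str
    domain_name: str
    ali_start: int
    ali_end: int
    bit_score: float
    e_value: float

    def __post_init__(self) -> None:
        if self.ali_start < 1 or self.ali_start > self.ali_end:
            raise FormatError(
                f"invalid coordinates {self.ali_start}-{self.ali_end} for "
                f"{self.domain_name} on {self.protein_id}"
            )
        if self.e_value < 0:
            raise FormatError(f"negative E-value on {self.protein_id}")

    @property
    def length(self) -> int:
        return self.ali_end - self.ali_start + 1

    def overlaps(self, other: "DomainHit") -> bool:
        return (
            self.protein_id == other.protein_id
            and self.ali_start <= other.ali_end
            and other.ali_start <= self.ali_end
        )


@dataclass(frozen=True, order=True)
class TMSegment:
    """One predicted transmembrane helix, 1-based inclusive."""

    protein_id: str
    tm_start: int
    tm_end: int

    def __post_init__(self) -> None:
        if self.tm_start < 1 or self.tm_start > self.tm_end:
            raise FormatError(
                f"invalid TM segment {self.tm_start}-{self.tm_end} on "
                f"{self.protein_id}"
            )


@dataclass
class LifestyleDB:
    """Reference lists of plant-associated species (PAB).

    ``phyto`` (phytopathogens) and ``symb`` (plant symbionts) are subsets of
    ``broad``, mirroring the nested reference databases.
    """

    broad: set = field(default_factory=set)
    phyto: set = field(default_factory=set)
    symb: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.phyto <= self.broad:
            raise FormatError("phytopathogen list is not a subset of the broad PAB list")
        if not self.symb <= self.broad:
            raise FormatError("symbiont list is not a subset of the broad PAB list")

    def sets(self) -> dict:
        return {"broad": self.broad, "phyto": self.phyto, "symb": self.symb}


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict:
    """Read a protein FASTA into ``{protein_id: sequence}``.

    Raises :class:`FormatError` on duplicate ids or an empty file.
    """
    seqs: dict = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate id {rec.id} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise FormatError(f"no FASTA records in {path}")
    return seqs


def write_fasta(seqs: Mapping[str, str], path) -> None:
    """Write ``{id: sequence}`` as FASTA, sorted by id."""
    records = [
        SeqRecord(Seq(seqs[pid]), id=pid, description="") for pid in sorted(seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Domain hits

# domtblout column indices (hmmscan orientation: target = domain model,
# query = protein): i-Evalue (12), dom bit score (13), ali from/to (17, 18).
_DOMTBL_MIN_COLS = 19


def read_domtblout(path, dialect: str = "tsv") -> list:
    """Read per-protein domain hits.

    ``dialect='domtblout'`` parses HMMER's whitespace-separated per-domain
    table (hmmscan orientation; alignment coordinates, per-domain i-Evalue
    and bit score). ``dialect='tsv'`` parses the canonical 6-column table
    ``protein_id  domain_name  ali_start  ali_end  bit_score  e_value``.
    """
    if dialect not in {"domtblout", "tsv"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    hits: list = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if dialect == "domtblout":
                cols = line.split()
                if len(cols) < _DOMTBL_MIN_COLS:
                    raise FormatError(f"{path}:{lineno}: truncated domtblout row")
                raw = (cols[3], cols[0], cols[17], cols[18], cols[13], cols[12])
            else:
                cols = line.split("\t")
                if len(cols) < 6:
                    raise FormatError(f"{path}:{lineno}: expected 6 TSV columns")
                raw = tuple(cols[:6])
            try:
                hit = DomainHit(
                    protein_id=raw[0],
                    domain_name=raw[1],
                    ali_start=int(raw[2]),
                    ali_end=int(raw[3]),
                    bit_score=float(raw[4]),
                    e_value=float(raw[5]),
                )
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric coordinate or score"
                ) from None
            hits.append(hit)
    return hits


# ---------------------------------------------------------------------------
# Transmembrane segments

_TOPOLOGY_RE = re.compile(r"Topology=(\S+)")
_SEGMENT_RE = re.compile(r"([io])(?:(\d+)-(\d+))?")


def _parse_topology(protein_id: str, topo: str) -> list:
    """Expand a TMHMM ``Topology=`` string like ``i5-25o190-210i``."""
    segments = []
    pos = 0
    for m in _SEGMENT_RE.finditer(topo):
        if m.start() != pos:
            raise FormatError(f"malformed topology string {topo!r}")
        pos = m.end()
        if m.group(2) is not None:
            segments.append(TMSegment(protein_id, int(m.group(2)), int(m.group(3))))
    if pos != len(topo):
        raise FormatError(f"malformed topology string {topo!r}")
    return segments


def read_tm_segments(path, dialect: str = "tsv") -> list:
    """Read predicted TM helices.

    ``dialect='tmhmm_short'`` parses TMHMM short-format lines (one protein
    per line, ``Topology=i5-25o190-210i``); the i/o markers only order the
    segments and are not retained. ``dialect='tsv'`` parses
    ``protein_id  tm_start  tm_end`` rows. Output is sorted per protein and
    checked for overlap.
    """
    if dialect not in {"tmhmm_short", "tsv"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    segments: list = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if dialect == "tmhmm_short":
                protein_id = line.split()[0]
                m = _TOPOLOGY_RE.search(line)
                if m is None:
                    raise FormatError(f"{path}:{lineno}: no Topology= field")
                segments.extend(_parse_topology(protein_id, m.group(1)))
            else:
                cols = line.split("\t")
                if len(cols) < 3:
                    raise FormatError(f"{path}:{lineno}: expected 3 TSV columns")
                try:
                    segments.append(TMSegment(cols[0], int(cols[1]), int(cols[2])))
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: non-numeric coordinate") from None
    segments.sort()
    by_protein: dict = {}
    for seg in segments:
        prev = by_protein.get(seg.protein_id)
        if prev is not None and seg.tm_start <= prev.tm_end:
            raise FormatError(
                f"overlapping TM segments on {seg.protein_id}: "
                f"{prev.tm_start}-{prev.tm_end} and {seg.tm_start}-{seg.tm_end}"
            )
        by_protein[seg.protein_id] = seg
    return segments


# ---------------------------------------------------------------------------
# Species map, tree, lifestyle lists

def read_species_map(path) -> dict:
    """Read the two-column ``protein_id → species_id`` TSV."""
    mapping: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 TSV columns")
            if cols[0] in mapping and mapping[cols[0]] != cols[1]:
                raise FormatError(
                    f"{path}:{lineno}: protein {cols[0]} mapped to two species"
                )
            mapping[cols[0]] = cols[1]
    return mapping


def read_newick(path) -> dendropy.Tree:
    """Read a Newick species tree; leaf labels are species ids."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise FormatError(f"duplicate leaf names in {path}: {exc}") from None
    tree.is_rooted = True
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        raise FormatError(f"duplicate leaf names in {path}: {sorted(dupes)}")
    return tree


def read_lifestyle_lists(
    broad_path, phyto_path, symb_path, tree: dendropy.Tree | None = None
) -> LifestyleDB:
    """Read the three one-column species-id lists into a :class:`LifestyleDB`.

    Species listed but absent from *tree* (when given) trigger a warning and
    are retained: the species universe legitimately includes genomes without
    chemoreceptors.
    """

    def _read(path) -> set:
        out = set()
        with open(path) as fh:
            for line in fh:
                sp = line.strip().split("\t")[0]
                if sp and not sp.startswith("#"):
                    out.add(sp)
        return out

    db = LifestyleDB(broad=_read(broad_path), phyto=_read(phyto_path), symb=_read(symb_path))
    if tree is not None:
        leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        missing = db.broad - leaves
        if missing:
            warnings.warn(
                f"{len(missing)} lifestyle species absent from the tree "
                f"(retained): {sorted(missing)[:5]}...",
                stacklevel=2,
            )
    return db


# ---------------------------------------------------------------------------
# Generic deterministic tables

def _format_cell(value) -> str:
    if isinstance(value, float):
        return f"{value:.4f}"
    return str(value)


def write_table(
    rows: Iterable[Mapping], path, columns: Sequence[str], sort_by: Sequence[str] | None = None
) -> None:
    """Write dict rows as a headered TSV, deterministically.

    Rows are sorted by *sort_by* (defaults to the first column); floats are
    written ``%.4f`` unless the row already carries a formatted string.
    """
    rows = list(rows)
    keys = list(sort_by) if sort_by else [columns[0]]
    rows.sort(key=lambda r: tuple(r[k] for k in keys))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(_format_cell(row[c]) for c in columns) + "\n")


def read_table(path) -> list:
    """Read a headered TSV written by :func:`write_table` into dict rows."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        return [
            dict(zip(header, line.rstrip("\n").split("\t")))
            for line in fh
            if line.strip()
        ]
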