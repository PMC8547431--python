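"""Seeded synthetic datasets with the statistical structure the pipeline assumes.

Emulates, at desk scale, the inputs of a proGenomes-style chemoreceptor
survey: a Yule species tree; nested plant-associated lifestyle sets (broad /
phytopathogen / symbiont) placed on a clade or scattered; per-genome CR
counts whose class means echo the survey (plant-associated genomes carry
roughly twice as many chemoreceptors, phytopathogens the most); and planted
LBD families with controlled within-family divergence, controlled
lifestyle enrichment (an intended DPS hit exactly where feasible) and a
controlled taxonomic placement (clade-confined families carry phylogenetic
signal, scattered ones do not). Every planted property is recorded in a
ground-truth manifest so recovery can be asserted end to end.

Receptor architectures follow the canonical topology
``N-term – TM1 – LBD – TM2 – HAMP – MCPsignal``; variant templates plant
N-terminal (single-TM) and cytosolic (TM-less, domain-hit-only) LBDs.
Families flagged "unknown" emit no domain hit, so their LBDs are
recoverable only through TM topology. Filler receptors (canonical topology
with a sub-minimum periplasmic loop) pad genomes to their CR-count draw
without adding extractable LBDs, and sub-threshold decoy MCPsignal hits
exercise the identification threshold.
"""

from __future__ import annotations

import json
import random as _pyrandom
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .io_formats import DomainHit, LifestyleDB, TMSegment, write_fasta
from .cr_catalog import MCP_DOMAIN
from .clustering import ClusterParams, accepts_stats, align_local_pair

AA = "ACDEFGHIKLMNPQRSTVWY"

#: Length of the mock signaling-domain segment appended to every CR.
MCP_LEN = 180
HAMP_LEN = 50
TM_LEN = 21


@dataclass(frozen=True)
class FamilySpec:
    """One planted LBD family."""

    name: str
    label: str  # domain name, or "unknown" (no hit emitted)
    n_members: int
    prototype_length: int
    divergence: float  # substitutions/site within the family
    dps_broad: float  # intended fraction of members in PAB-broad
    placement: str  # "clade" (phylogenetic signal) | "scattered" (none)
    strategy: str = "inter_tm"  # inter_tm | n_terminal | domain_based

    def __post_init__(self) -> None:
        if not 0 <= self.dps_broad <= 1:
            raise ValueError("intended DPS must be in [0, 1]")
        if self.divergence < 0:
            raise ValueError("divergence must be >= 0")
        if self.strategy == "domain_based" and self.label == "unknown":
            raise ValueError(
                "a TM-less family needs a domain label to be recoverable"
            )


def default_families() -> tuple:
    """The default family panel.

    Ten high-specificity families (intended DPS 1.0 or 0.8) split evenly
    between clade-confined and scattered placements, plus two families with
    no plant enrichment; five of twelve are "unknown" types (no domain
    hit), echoing the large unknown fraction seen in real LBD surveys.
    Within-family divergence 0.2 substitutions/site keeps families
    recoverable at the default clustering thresholds while prototypes are
    mutually unrelated.
    """
    specs = []
    panel = [
        # (label, dps, placement, strategy, length)
        ("dCache_1", 1.0, "clade", "inter_tm", 250),
        ("4HB_MCP_1", 1.0, "clade", "inter_tm", 160),
        ("unknown", 1.0, "clade", "inter_tm", 140),
        ("TarH", 1.0, "clade", "inter_tm", 170),
        ("unknown", 1.0, "clade", "n_terminal", 120),
        ("PAS_3", 1.0, "scattered", "domain_based", 100),
        ("HBM", 1.0, "scattered", "inter_tm", 190),
        ("unknown", 1.0, "scattered", "inter_tm", 150),
        ("sCache_2", 0.8, "scattered", "inter_tm", 130),
        ("unknown", 0.8, "scattered", "inter_tm", 110),
        ("PilZ", 0.0, "scattered", "domain_based", 100),
        ("unknown", 0.0, "scattered", "inter_tm", 180),
    ]
    for i, (label, dps, placement, strategy, length) in enumerate(panel):
        specs.append(
            FamilySpec(
                name=f"FAM{i:02d}",
                label=label,
                n_members=10,
                prototype_length=length,
                divergence=0.2,
                dps_broad=dps,
                placement=placement,
                strategy=strategy,
            )
        )
    return tuple(specs)


@dataclass
class SynthConfig:
    """Generator settings; the defaults define the reference study conditions."""

    n_species: int = 96
    seed: int = 0
    broad_fraction: float = 0.30
    phyto_fraction: float = 0.125  # of broad
    symb_fraction: float = 0.20  # of broad
    lifestyle_placement: str = "clade"  # clade | scattered
    cr_mean_pab: float = 23.0
    cr_mean_non_pab: float = 13.0
    cr_mean_phyto: float = 27.0
    families: tuple = field(default_factory=default_families)
    decoy_rate: float = 0.15  # sub-threshold MCPsignal decoys per species
    score_threshold: float = 25.0

    def __post_init__(self) -> None:
        for f in (self.broad_fraction, self.phyto_fraction, self.symb_fraction):
            if not 0 <= f <= 1:
                raise ValueError("lifestyle fractions must be in [0, 1]")
        if min(self.cr_mean_pab, self.cr_mean_non_pab, self.cr_mean_phyto) <= 0:
            raise ValueError("CR-count means must be positive")


@dataclass
class SynthDataset:
    """In-memory synthetic dataset plus its ground-truth manifest."""

    tree: dendropy.Tree
    lifestyle_db: LifestyleDB
    sequences: dict  # protein_id -> sequence
    hits: list  # DomainHit
    tm_segments: list  # TMSegment
    species_map: dict  # protein_id -> species_id
    truth: dict  # the manifest (JSON-serializable)


# ---------------------------------------------------------------------------
# Stage generators — all randomness flows from the config seed through one
# named child generator per stage, so stages reproduce independently.

_STAGES = ("tree", "lifestyles", "families", "counts", "sequences", "decoys")


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STAGES.index(stage)])


def simulate_tree(n_species: int, seed: int) -> dendropy.Tree:
    """Pure-birth (Yule) species tree with unit-mean branch lengths."""
    if n_species < 4:
        raise ValueError("need at least 4 species")
    rng = _pyrandom.Random(int(_stage_rng(seed, "tree").integers(2**31)))
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_species, rng=rng
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"S{i:04d}"
    lengths = [e.length for e in tree.preorder_edge_iter() if e.length]
    mean = sum(lengths) / len(lengths)
    for e in tree.preorder_edge_iter():
        if e.length:
            e.length /= mean
    return tree


def _clade_nodes(tree: dendropy.Tree) -> list:
    return [n for n in tree.preorder_node_iter() if not n.is_leaf()]


def _leaves_of(node: dendropy.Node) -> list:
    return [l.taxon.label for l in node.leaf_iter()]


def _best_clade(tree: dendropy.Tree, target: int, within: set | None = None):
    """Internal node whose leaf set (optionally within a label set) has the
    size closest to *target*; ties by smallest leaf label."""
    best = None
    best_key = None
    for node in _clade_nodes(tree):
        leaves = _leaves_of(node)
        if within is not None and not set(leaves) <= within:
            continue
        key = (abs(len(leaves) - target), min(leaves))
        if best_key is None or key < best_key:
            best, best_key = node, key
    return best


def assign_lifestyles(tree: dendropy.Tree, config: SynthConfig) -> LifestyleDB:
    """Place the nested lifestyle sets on the tree.

    Clade placement labels the clade whose leaf count best matches the
    broad target; scattered placement samples leaves uniformly. The
    phytopathogen and symbiont subsets are drawn disjointly within broad.
    """
    rng = _stage_rng(config.seed, "lifestyles")
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    n_broad = round(config.broad_fraction * len(leaves))
    if n_broad < 1:
        raise ValueError("broad fraction selects no species")
    if config.lifestyle_placement == "clade":
        node = _best_clade(tree, n_broad)
        broad = sorted(_leaves_of(node))
    elif config.lifestyle_placement == "scattered":
        broad = sorted(rng.choice(leaves, size=n_broad, replace=False))
    else:
        raise ValueError(f"unknown placement {config.lifestyle_placement!r}")
    n_phyto = round(config.phyto_fraction * len(broad))
    n_symb = round(config.symb_fraction * len(broad))
    if n_phyto + n_symb > len(broad):
        raise ValueError("phyto and symb fractions overfill the broad set")
    shuffled = list(broad)
    rng.shuffle(shuffled)
    phyto = set(shuffled[:n_phyto])
    symb = set(shuffled[n_phyto : n_phyto + n_symb])
    return LifestyleDB(broad=set(broad), phyto=phyto, symb=symb)


def _choose_family_species(
    spec: FamilySpec,
    tree: dendropy.Tree,
    db: LifestyleDB,
    rng: np.random.Generator,
) -> list:
    """Member species of one family, hitting the intended DPS exactly.

    ``round(dps * n_members)`` members come from the broad set, the rest
    from outside; clade placement takes a broad subclade (plus one broad
    straggler to keep the trait's MRCA subtree informative), scattered
    placement samples uniformly.
    """
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    broad = sorted(db.broad)
    non_broad = sorted(set(leaves) - db.broad)
    n_b = round(spec.dps_broad * spec.n_members)
    n_nb = spec.n_members - n_b
    if n_b > len(broad) or n_nb > len(non_broad):
        raise ValueError(
            f"family {spec.name}: intended DPS {spec.dps_broad} needs more "
            "species than the lifestyle sets provide"
        )
    if spec.placement == "scattered" or n_b == 0:
        chosen_b = list(rng.choice(broad, size=n_b, replace=False)) if n_b else []
    elif spec.placement == "clade":
        clade = _best_clade(tree, max(2, n_b - 1), within=set(broad))
        if clade is None:
            raise ValueError(f"family {spec.name}: no clade inside the broad set")
        clade_leaves = sorted(_leaves_of(clade))[: n_b]
        rest = sorted(set(broad) - set(clade_leaves))
        if not rest:
            raise ValueError(
                f"family {spec.name}: broad set too small for clade placement"
            )
        n_extra = n_b - len(clade_leaves)
        if n_extra == 0:
            # make room for at least one straggler outside the subclade: it
            # pulls the trait's MRCA subtree above the family clade, keeping
            # the trait testable and phylogenetically informative
            clade_leaves = clade_leaves[:-1]
            n_extra = 1
        if n_extra > len(rest):
            raise ValueError(
                f"family {spec.name}: broad set too small for clade placement"
            )
        # first straggler: the broad species whose MRCA with the family
        # clade subtends the most leaves (ties broken at random)
        sizes = np.array(
            [
                len(tree.mrca(taxon_labels=clade_leaves + [x]).leaf_nodes())
                for x in rest
            ]
        )
        argmax = np.flatnonzero(sizes == sizes.max())
        first = rest.pop(int(rng.choice(argmax)))
        extra = [first] + (
            list(rng.choice(rest, size=n_extra - 1, replace=False))
            if n_extra > 1
            else []
        )
        chosen_b = clade_leaves + extra
    else:
        raise ValueError(f"unknown placement {spec.placement!r}")
    chosen_nb = list(rng.choice(non_broad, size=n_nb, replace=False)) if n_nb else []
    return sorted(chosen_b + chosen_nb)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


def _mutate(rng: np.random.Generator, prototype: str, divergence: float) -> str:
    out = []
    for ch in prototype:
        if rng.random() < divergence:
            alt = AA.replace(ch, "") if ch in AA else AA
            out.append(alt[int(rng.integers(len(alt)))])
        else:
            out.append(ch)
    return "".join(out)


def _bit_score(rng: np.random.Generator) -> float:
    # comfortably above threshold, with spread so thresholding is exercised
    return 30.0 + float(rng.exponential(20.0))


_MAX_FAMILY_ATTEMPTS = 25


def _family_sequences(
    spec: FamilySpec, seed: int, fam_index: int, attempt: int
) -> list:
    """Member LBD sequences of one family: a random prototype mutated at the
    configured divergence, from a family-specific generator stream."""
    rng = np.random.default_rng(
        [seed, _STAGES.index("sequences"), fam_index, attempt]
    )
    prototype = _random_seq(rng, spec.prototype_length)
    return [_mutate(rng, prototype, spec.divergence) for _ in range(spec.n_members)]


def _families_conflict(seqs_a: Sequence[str], seqs_b: Sequence[str]) -> bool:
    """Would any cross-family member pair satisfy the clustering acceptance
    predicate (either query direction) at default thresholds?"""
    params = ClusterParams()
    for a in seqs_a:
        for b in seqs_b:
            st_a, st_b = align_local_pair(a, b, params)
            if accepts_stats(st_a, params) or accepts_stats(st_b, params):
                return True
    return False


def _separated_family_sequences(config: SynthConfig) -> dict:
    """Member sequences per family, oracle-checked to be mutually separated.

    Families are drawn independently; whenever a cross-family member pair
    would pass the clustering thresholds, the later family is redrawn from
    a fresh stream. This makes the planted partition the unique clustering
    outcome at default parameters.
    """
    fam_seqs: dict = {}
    done: list = []
    for i, spec in enumerate(config.families):
        for attempt in range(_MAX_FAMILY_ATTEMPTS):
            candidate = _family_sequences(spec, config.seed, i, attempt)
            if not any(_families_conflict(candidate, fam_seqs[d]) for d in done):
                fam_seqs[spec.name] = candidate
                done.append(spec.name)
                break
        else:
            raise RuntimeError(
                f"family {spec.name}: could not draw sequences separated from "
                "earlier families; lower the divergence or lengthen prototypes"
            )
    return fam_seqs


def _build_cr(
    pid: str,
    species: str,
    lbd_seq: str | None,
    strategy: str,
    label: str | None,
    rng: np.random.Generator,
    filler: bool = False,
):
    """Assemble one CR protein; returns (sequence, tms, hits, planted_lbd)."""
    hits = []
    tms = []
    parts = []
    pos = 1

    def _emit(segment: str):
        nonlocal pos
        start = pos
        parts.append(segment)
        pos += len(segment)
        return start, pos - 1

    planted = None
    if filler:
        _emit(_random_seq(rng, 7))
        s, e = _emit(_random_seq(rng, TM_LEN))
        tms.append((s, e))
        _emit(_random_seq(rng, 10))  # sub-minimum periplasmic loop
        s, e = _emit(_random_seq(rng, TM_LEN))
        tms.append((s, e))
    elif strategy == "inter_tm":
        _emit(_random_seq(rng, 7))
        s, e = _emit(_random_seq(rng, TM_LEN))
        tms.append((s, e))
        ls, le = _emit(lbd_seq)
        planted = (ls, le)
        s, e = _emit(_random_seq(rng, TM_LEN))
        tms.append((s, e))
    elif strategy == "n_terminal":
        ls, le = _emit(lbd_seq)
        planted = (ls, le)
        s, e = _emit(_random_seq(rng, TM_LEN))
        tms.append((s, e))
    elif strategy == "domain_based":
        _emit(_random_seq(rng, 10))
        ls, le = _emit(lbd_seq)
        planted = (ls, le)
        _emit(_random_seq(rng, 10))
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    if strategy != "domain_based" or filler:
        _emit(_random_seq(rng, 5))
        hs, he = _emit(_random_seq(rng, HAMP_LEN))
        hits.append(DomainHit(pid, "HAMP", hs, he, _bit_score(rng), 1e-10))
    _emit(_random_seq(rng, 5))
    ms, me = _emit(_random_seq(rng, MCP_LEN))
    hits.append(DomainHit(pid, MCP_DOMAIN, ms, me, _bit_score(rng), 1e-30))
    if planted is not None and label is not None and label != "unknown":
        hits.append(
            DomainHit(pid, label, planted[0], planted[1], _bit_score(rng), 1e-15)
        )
    sequence = "".join(parts)
    tm_segments = [TMSegment(pid, s, e) for s, e in tms]
    return sequence, tm_segments, hits, planted, (ms, me)


def generate(config: SynthConfig) -> SynthDataset:
    """Generate the full dataset and its truth manifest for one seed."""
    tree = simulate_tree(config.n_species, config.seed)
    db = assign_lifestyles(tree, config)
    fam_rng = _stage_rng(config.seed, "families")
    seq_rng = _stage_rng(config.seed, "sequences")
    count_rng = _stage_rng(config.seed, "counts")
    decoy_rng = _stage_rng(config.seed, "decoys")

    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())

    # plant families: species per the intended DPS/placement, sequences from
    # per-family streams checked for mutual separation
    fam_members: dict = {}
    for spec in config.families:
        fam_members[spec.name] = _choose_family_species(spec, tree, db, fam_rng)
    fam_seqs = _separated_family_sequences(config)

    sequences: dict = {}
    species_map: dict = {}
    all_hits: list = []
    all_tms: list = []
    truth_proteins: dict = {}
    truth_families: dict = {
        spec.name: {
            "label": spec.label,
            "strategy": spec.strategy,
            "intended_dps_broad": spec.dps_broad,
            "signal_class": spec.placement,
            "species": fam_members[spec.name],
            "member_lbd_ids": [],
        }
        for spec in config.families
    }

    cr_counter: dict = {sp: 0 for sp in leaves}

    def _new_pid(sp: str) -> str:
        cr_counter[sp] += 1
        return f"{sp}.p{cr_counter[sp]:03d}"

    # family member proteins
    for spec in config.families:
        for member_idx, sp in enumerate(fam_members[spec.name]):
            pid = _new_pid(sp)
            lbd_seq = fam_seqs[spec.name][member_idx]
            seq, tms, hits, planted, mcp = _build_cr(
                pid, sp, lbd_seq, spec.strategy, spec.label, seq_rng
            )
            sequences[pid] = seq
            species_map[pid] = sp
            all_tms.extend(tms)
            all_hits.extend(hits)
            lbd_id = f"{pid}/{planted[0]}-{planted[1]}"
            truth_families[spec.name]["member_lbd_ids"].append(lbd_id)
            truth_proteins[pid] = {
                "species": sp,
                "tms": [[t.tm_start, t.tm_end] for t in tms],
                "mcp": list(mcp),
                "lbds": [
                    {
                        "start": planted[0],
                        "end": planted[1],
                        "label": spec.label,
                        "strategy": spec.strategy,
                        "family": spec.name,
                    }
                ],
            }

    # filler CRs up to the per-class Poisson draw
    truth_species: dict = {}
    for sp in leaves:
        if sp in db.phyto:
            mean, cls = config.cr_mean_phyto, "phyto"
        elif sp in db.symb:
            mean, cls = config.cr_mean_pab, "symb"
        elif sp in db.broad:
            mean, cls = config.cr_mean_pab, "other_pab"
        else:
            mean, cls = config.cr_mean_non_pab, "non_pab"
        target = int(count_rng.poisson(mean))
        n_fill = max(0, target - cr_counter[sp])
        for _ in range(n_fill):
            pid = _new_pid(sp)
            seq, tms, hits, _, mcp = _build_cr(
                pid, sp, None, "inter_tm", None, seq_rng, filler=True
            )
            sequences[pid] = seq
            species_map[pid] = sp
            all_tms.extend(tms)
            all_hits.extend(hits)
            truth_proteins[pid] = {
                "species": sp,
                "tms": [[t.tm_start, t.tm_end] for t in tms],
                "mcp": list(mcp),
                "lbds": [],
            }
        truth_species[sp] = {
            "lifestyle_class": cls,
            "n_crs": cr_counter[sp],
        }

    # sub-threshold decoys: proteins that must NOT be identified as CRs
    for sp in leaves:
        if decoy_rng.random() < config.decoy_rate:
            pid = f"{sp}.decoy"
            seq = _random_seq(decoy_rng, 300)
            sequences[pid] = seq
            species_map[pid] = sp
            score = float(decoy_rng.uniform(5.0, config.score_threshold - 1.0))
            all_hits.append(DomainHit(pid, MCP_DOMAIN, 100, 280, score, 0.5))
            truth_proteins[pid] = {
                "species": sp,
                "tms": [],
                "mcp": None,
                "lbds": [],
                "decoy": True,
            }

    truth = {
        "config": {
            "n_species": config.n_species,
            "seed": config.seed,
            "broad_fraction": config.broad_fraction,
            "lifestyle_placement": config.lifestyle_placement,
            "families": [asdict(s) for s in config.families],
        },
        "species": truth_species,
        "proteins": truth_proteins,
        "families": truth_families,
        "lifestyles": {
            "broad": sorted(db.broad),
            "phyto": sorted(db.phyto),
            "symb": sorted(db.symb),
        },
    }
    return SynthDataset(
        tree=tree,
        lifestyle_db=db,
        sequences=sequences,
        hits=sorted(all_hits),
        tm_segments=sorted(all_tms),
        species_map=species_map,
        truth=truth,
    )


def emit_dataset(config: SynthConfig, out_dir) -> SynthDataset:
    """Generate and write the canonical input files plus ``truth.json``."""
    ds = generate(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(ds.sequences, out / "proteins.fasta")
    with open(out / "hits.tsv", "w") as fh:
        for h in ds.hits:
            fh.write(
                f"{h.protein_id}\t{h.domain_name}\t{h.ali_start}\t{h.ali_end}"
                f"\t{h.bit_score:.4f}\t{h.e_value:.3g}\n"
            )
    with open(out / "tm.tsv", "w") as fh:
        for t in ds.tm_segments:
            fh.write(f"{t.protein_id}\t{t.tm_start}\t{t.tm_end}\n")
    with open(out / "species_map.tsv", "w") as fh:
        for pid in sorted(ds.species_map):
            fh.write(f"{pid}\t{ds.species_map[pid]}\n")
    ds.tree.write(path=str(out / "tree.nwk"), schema="newick")
    for name, members in ds.lifestyle_db.sets().items():
        with open(out / f"lifestyle_{name}.tsv", "w") as fh:
            for sp in sorted(members):
                fh.write(sp + "\n")
    with open(out / "truth.json", "w") as fh:
        json.dump(ds.truth, fh, indent=1, sort_keys=True)
    return ds
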