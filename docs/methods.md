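# Methods

## Scope and data model

The pipeline operates on four inputs: per-protein domain hits (HMMER
`domtblout` or a canonical 6-column TSV), predicted transmembrane segments
(TMHMM short format or TSV), protein sequences (FASTA) with a protein→
species map, and a species tree (Newick) plus three nested lifestyle lists
(plant-associated broad set, phytopathogen subset, symbiont subset). All
coordinates are 1-based inclusive residue positions, the convention of the
upstream tools; conversions happen only at parse time. For `domtblout` the
hmmscan orientation is assumed (target = domain model, query = protein) and
the *alignment* coordinate columns are used for domain placement — envelope
coordinates are systematically wider and would inflate overlap resolution.

## Chemoreceptor identification

Presence of an MCPsignal hit with bit score ≥ threshold is the sole
criterion. The canonical threshold is the Pfam gathering threshold of the
MCPsignal model, which is a property of the model file and not
reproducible without it; the threshold is therefore an explicit parameter
(default 25 bits, matched by the synthetic generator's score
distributions). A protein with several qualifying hits yields one record
keeping the highest-scoring hit; exact score ties resolve to the smaller
alignment start, then the smaller end, making identification deterministic
and input-order independent.

## LBD extraction

Three strategies, mirroring canonical receptor topology
(N-term–TM1–LBD–TM2–HAMP–MCPsignal):

* **inter_tm** — the region strictly between the first two TM helices. For
  receptors with more than two TMs only this first periplasmic loop is
  taken positionally (assumed N-in topology; the i/o orientation labels are
  not re-derived); further sensory regions remain reachable through domain
  hits.
* **n_terminal** — for single-TM receptors, positions 1..(tm_start − 1).
* **domain_based** — any hit of a domain other than MCPsignal and HAMP.
  Mutually overlapping hits (≥ 1 shared residue) resolve to the highest bit
  score.

All three strategies share the 30-aa minimum (`--min-lbd-len`), applied
uniformly for symmetry, and no emitted region may overlap the retained
MCPsignal hit. A domain candidate covering ≥ 50% of the shorter of itself
and a topology region *labels* that region (coordinates stay topological);
topology regions with no such hit are labeled `unknown`; unconsumed domain
candidates become stand-alone LBDs. The two overlap rules (≥ 1 residue
among hits, ≥ 50%-of-shorter for labeling) are deliberate, testable
readings of the informal "domains mapping to the same region".

Length summaries use the three empirical LBD size bands 60–110, 130–200
and 220–299 aa, with out-of-band and ≥ 500-aa tails reported separately.

## Clustering

Greedy centroid clustering in the style of cascaded tools: sequences sorted
by length descending (ties by id); each unassigned sequence founds a
cluster; a remaining sequence joins when its optimal local alignment
against the centroid (BLOSUM62, gap open 11 / extend 1; identity = matches
over alignment columns; coverage = aligned member residues over member
length, i.e. query-only coverage with the member as query) satisfies
identity ≥ 0.20 and coverage ≥ 0.50. Single pass, no reassignment:
deterministic and order-independent.

The search stage of real clustering tools additionally imposes an E-value
cutoff. Karlin–Altschul statistics are unstable on a desk-scale database,
so the significance filter is a fixed raw-score floor (`min_score`, default
60): under standard gapped BLOSUM62 statistics (λ ≈ 0.267, K ≈ 0.041) a raw
score of 60 corresponds to E ≈ 0.01 against a database of a few thousand
LBD-sized sequences. Without this floor, short high-identity gappy local
alignments between unrelated sequences occasionally clear the identity and
coverage thresholds — exactly the accidental hits an E-value cutoff
removes.

A cluster is *compact* when ≥ 90% of members share one label (`unknown`
counts as a label; singletons are trivially compact), else *mixed*; labels
forming fewer than 12 compact clusters are *low-abundance*. External
clustering output imports via a representative→member TSV that must cover
every LBD exactly once.

## Degree of plant specificity

DPS_R = 100 · |distinct member species ∩ R| / |distinct member species| for
R ∈ {broad, phyto, symb}. The statistic is species-level — duplicating
sequences from an already-present species changes nothing; a
sequence-weighted variant exists behind `--dps-weighting sequences` for
sensitivity analysis. Because the reference sets are nested, DPS_phyto ≤
DPS_broad and DPS_symb ≤ DPS_broad hold for every cluster and are asserted
in the tests. Values are compared unrounded and printed half-up to two
decimals. High-DPS selections use inclusive thresholds (50%, 80%) and
exclude singletons by default: the specificity of a one-sequence cluster
carries no grouping information.

## Phylogenetic signal

The trait for a cluster is presence/absence over the leaves of the MRCA
subtree of its member species. Subtrees under 20 leaves are skipped (the
statistic has poor sensitivity there), as are invariant traits. Polytomies
are resolved arbitrarily with epsilon branches (1e-8), which leaves
likelihoods unchanged to numerical tolerance while the pruning machinery
requires binary nodes.

Evolution is modeled as the symmetric two-state Mk process; the stay
probability along a branch of length t is (1 + e^(−2qt))/2. The rate q is
fitted by maximum likelihood (Felsenstein pruning, flat root prior) over
[1e-8, 1e3]. The log-likelihood is nearly flat in q over most of that
interval (a saturation plateau at ln(1/2)·n), so a local search from an
arbitrary start can stall on the plateau; the implemented search is an
iteratively refined log-spaced grid (33 points per pass, pruning vectorized
over the grid) zoomed until the bracket is below 1e-6 in log10(q) —
deterministic and verified against a 10,000-point grid scan.

Marginal posterior state probabilities at internal nodes come from the
standard two-pass (up/down) algorithm; each node's Shannon entropy Hᵢ
(natural log, floored at h_min = 1e-6) measures reconstruction
uncertainty. The signal statistic is the entropy ratio

    δ = m · ln 2 / Σᵢ max(Hᵢ, h_min)

over the m internal nodes: δ = 1 under maximal uncertainty, capped at
ln2/h_min as reconstructions sharpen. This deterministic statistic stands
in for the Bayesian entropy-based formulation of the δ-approach; the
permutation p-value — the decision-relevant quantity — depends on the
statistic only through its ordering, a rank-invariance the tests assert
directly by re-running the permutation test with −ΣHᵢ.

Significance: tip states are shuffled without replacement (preserving
prevalence), q is re-fitted and δ recomputed per permutation (default 100),
and p = (1 + #{δ_r ≥ δ_obs}) / (1 + n_perm) — the add-one estimator keeps
p > 0 — with signal declared at p < 0.05. Shuffles are drawn over tips
sorted by label, so isomorphic trees reproduce identical results. Type-I
error at the 0.05 level, measured over 200 null simulations on a 32-leaf
tree, stays within [0.02, 0.09] (slightly conservative, as ties and the
add-one correction predict). An alternative reference tree restricted to
chemoreceptor-bearing species is available (`--tree-variant chemotactic`).

## Per-genome profiles

An LBD is *highly plant-specific* when its cluster's DPS-broad is at or
above the threshold (default 80%). Genomes are assigned one lifestyle class
with priority symbiont > phytopathogen > other plant-associated >
non-plant-associated, making the classes disjoint for plotting and
summaries. Histogram defaults: decile bins for proportions, width-5 bins
for counts, half-open with the final bin closed (numpy convention; exactly
0.5 falls in the upper bin of [0, 0.5, 1]).

## Synthetic data

The generator emulates the survey conditions at desk scale and records
every planted property in `truth.json`:

* **Tree** — pure-birth (Yule) tree, branch lengths rescaled to unit mean;
  default 96 species (large enough that clade-confined traits subtend ≥ 20
  leaves while the full pipeline, including the permutation screen, runs in
  seconds to minutes).
* **Lifestyles** — broad fraction 0.30 placed on the best-matching clade by
  default (scattered placement available); phytopathogens (12.5% of broad)
  and symbionts (20% of broad) drawn disjointly within broad. The paper's
  survey proportions are far smaller (960/11,806 broad); at 96 species that
  would leave too few plant-associated genomes to plant enrichment
  structure on, so the fractions are scaled up while keeping the nesting.
* **CR counts** — per-genome Poisson draws with class means 23
  (plant-associated), 13 (other), 27 (phytopathogens), echoing the
  reported survey means (22.86 / 12.94 / 27.29).
* **Families** — twelve planted LBD families (default), sizes 10,
  within-family divergence 0.2 substitutions/site from a random prototype;
  five "unknown" (no domain hit emitted, recoverable only via TM topology —
  echoing the large unknown fraction in the real survey); intended
  DPS-broad hit exactly by construction (members drawn from broad vs
  non-broad species in the target proportion); placement either
  clade-confined (a broad subclade plus one straggler chosen to maximize
  the MRCA subtree, so the trait is testable) or scattered. Family
  sequences are *oracle-checked for separation*: any cross-family member
  pair passing the clustering acceptance predicate triggers a redraw of the
  later family, making the planted partition the unique clustering outcome
  at default thresholds.
* **Architectures** — canonical TM1–LBD–TM2–HAMP–MCPsignal; single-TM
  (N-terminal LBD) and TM-less (cytosolic, domain-hit-only) templates;
  filler receptors with a sub-minimum periplasmic loop pad genomes to their
  CR-count draw without adding LBDs; sub-threshold MCPsignal decoys (rate
  0.15/species) exercise the identification threshold. Mock bit scores are
  30 + Exp(mean 20).
* **Randomness** — one seed, one named child generator per stage, so
  stages reproduce independently.

What the generator does **not** emulate: realistic substitution processes
(no rate heterogeneity, no indels), pseudogenes and fragments, correlated
domain architectures, annotation noise in coordinates, or horizontal
transfer dynamics. Passing recovery tests therefore demonstrates the
pipeline's correctness on clean planted structure — not robustness to the
annotation noise of real genome surveys.

## Numerical and policy choices

* Branch lengths ≤ 0 or missing → 1e-8; root prior (1/2, 1/2).
* Identity/coverage computed from the single optimal local alignment
  biotite reports; exact score ties between co-optimal alignments are
  resolved by the aligner deterministically.
* Writers sort rows by primary key and format scores `%.4f`, percentages
  `%.2f` half-up, so outputs are byte-deterministic.
* Known limitations: the greedy single-pass clustering is order-dependent
  on the length ranking by design and does not reassign members; the
  δ engine is the deterministic ML entropy ratio described above (a
  Bayesian MCMC engine could be added without changing any contract); the
  E-value criterion of the original search stage is approximated by a raw
  score floor.
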