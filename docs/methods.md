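# Methods

This note documents the models, rules and numerical choices behind
`t6sscope`, and what the synthetic cohorts do and do not establish.

## Coordinate system and cluster detection

Gene order is the coordinate system throughout: each gene on a replicon
carries a 0-based ordinal, spans are half-open, and all distance rules count
*genes*, not base pairs (physical lengths in bp are carried only for
megaplasmid bookkeeping). This matches how cluster detectors driven by
profile searches operate: the relevant quantity is the number of intervening
genes between hits.

Two T6SS hits belong to the same cluster when at most
`max_intervening_genes` (default **20**) non-T6SS genes lie strictly between
them, strand ignored. Chains with fewer than `min_distinct_genes`
(default **2**) distinct components are discarded and their members demoted
to isolated-gene candidates rather than dropped. A cluster is **complete**
with ≥ `complete_min_distinct` (default **8**) *distinct* components —
distinct, not total hits, because multi-copy components (extra *vgrG*
paralogs, say) do not add structural modules; duplicated members are kept in
the member list but counted once. Clusters whose distinct-component set is
exactly one of {hcp,vgrG}, {hcp,PAAR}, {vgrG,PAAR}, {hcp,vgrG,PAAR} are
**orphan islands**; anything else below the completeness threshold is
incomplete. A stricter `phylo_min_distinct` (default **10**) marks the
clusters suitable for phylogenetic work, where missing components would
translate into missing alignment data.

Homotypic islands (*hcp-hcp*, *vgrG-vgrG*) cannot be emitted by the scan —
it requires two *distinct* components — so they are assembled afterwards
from pairs of isolated same-component genes within the same intervening-gene
threshold, greedily left-to-right. Replicons are treated as linear by
default (annotation tables present linear orders); an optional circular flag
allows a cluster or scan window to wrap across the origin.

Because the per-type denominator for island prevalence is genuinely
ambiguous (count islands, or count replicons carrying the type?), the
inventory reports both tallies.

The diagnostic markers separating subtypes i/ii/iii are deliberately not
hard-coded: no canonical public marker list exists at the label level this
package consumes, so `assign_subtype` takes a user-supplied
label → subtype table whose insertion order is the priority order.

## Replicon traits

* **Megaplasmid**: length / family-median-genome ≥ 0.05, boundary inclusive.
  The family median is metadata supplied with the replicon (a real analysis
  would take it from a curated taxonomy resource); a missing median yields
  status *unknown*, excluded from tallies rather than defaulted.
* **Transmissibility**: conjugative = relaxase + MPF; mobilizable = relaxase
  only; everything else non-transmissible. The MPF-without-relaxase corner
  is not named by the usual trichotomy; it is classified non-transmissible
  (no relaxase, no transfer initiation) and logged, since it usually
  indicates an annotation artifact or a decayed conjugation module.
* **GC divergence** is the signed difference in percentage points,
  100·(plasmid − host chromosome); hosts with several chromosomes use the
  length-weighted mean GC. Cohort summaries report medians of these signed
  differences.
* **Group precedence**: a plasmid carrying both a complete system and
  islands belongs to the complete-system group; the island-only group is
  genuinely island-only. Proportions of an empty group are undefined
  (`None`), never zero.

## MGE context

The neighbourhood screen takes 20 genes on *each side* of the locus span —
the symmetric reading of "around" — excluding the locus itself; MGE genes
inside the span are reported separately and do not set the adjacency flag,
since the question is whether mobile machinery sits next to the locus. The
choice to exclude locus-internal genes is recorded in the output metadata.
Windows truncate at replicon ends and wrap when the replicon is circular.
Per-family association between complete systems and orphan islands uses
two-sided Fisher tests, BH-corrected across families; families absent
everywhere are skipped.

## Networks

Louvain modularity on a bipartite graph is ill-posed, so community detection
runs on the **weighted replicon projection** (edge weight = number of shared
HPCs) of the replicon–HPC graph, with a fixed resolution of 1.0 and a
required seed (`networkx`'s Louvain implementation is stochastic).
Singleton replicons are their own communities. Host-range grades walk the
taxonomy from species to class and report the shallowest rank at which all
community members agree (I–V); disagreement at class rank is flagged
`beyond V` rather than silently graded. Core proteomes use an inclusive
≥ 80 % membership threshold; ANI edges require the aligned fraction of the
shorter replicon to reach 50 % (inclusive), with ANI as edge weight.
Protein clustering itself (at 99 %/100 % for transfer networks, 80 %/80 %
for PTU proteomes) is consumed as input.

## Ancestral reconstruction

The compartment of each sequence (plasmid/chromosome) is a binary character
on a fixed rooted tree under F81:

    P(i→j, t) = π_j + (δ_ij − π_j) · exp(−t/ν),   ν = 1 − Σ_s π_s²,

ν rescaling branch lengths so the expected substitution rate is 1.
Equilibrium frequencies default to observed tip-state proportions (clamped
to (1/(n+1), 1 − 1/(n+1)) so a one-state tree stays numerically benign) and
are configurable — in particular to 0.5/0.5 when the process is known to be
symmetric, as in the simulation experiments below. Marginal posteriors come
from one post-order pruning pass and one pre-order pass; trees are used as
rooted, never re-rooted.

MPPA state selection minimises a Brier-style prediction error over prefixes
of the posterior-sorted state list: predicting set S uniformly scores
Σ_s (1[s∈S]/|S| − p_s)²; for two states this keeps the runner-up whenever
its posterior is ≥ 1/4. Error ties (including exactly tied posteriors) keep
the larger set — conservative for transition counting. A branch contributes
one switch event iff the parent and child MPPA sets are disjoint, direction
parent → child; ambiguous branches contribute none. All-zero branch lengths
with conflicting tips are rejected as unidentifiable.

The closest-homolog analysis assigns distance zero between tips that share
an identity cluster (near-identical protein at 99 % identity / 100 %
coverage) but occupy different genomic contexts; without an identity-cluster
table the rule is inactive and logged. ECDFs are right-continuous and reach
1 at the maximum. The co-resident comparison tests, one-sided, whether
co-resident chromosome–plasmid homolog distances stochastically exceed each
chromosomal sequence's globally closest plasmid homolog distance: equality
is what local duplication would produce, an excess indicates independent
acquisition.

## Statistics

Fisher tests, the Mann–Whitney U and BH adjustment delegate to
`scipy.stats`/`numpy` behind a thin layer that fixes conventions: two-sided
Fisher p-values use the point-probability rule (tables as extreme or more
extreme than observed, with the usual ~1e-7 relative tolerance in mass
comparison); odds ratios are the sample ad/bc with infinity on a zero
denominator; Mann–Whitney switches from exact enumeration to the tie- and
continuity-corrected normal approximation when n_x·n_y > 400 or ties are
present (the switch point is an implementation choice, recorded in the
result flag). The gene-presence association is labelled **naive GWAS**: per
gene a two-sided Fisher test with BH control, no correction for population
structure (the pairwise-comparison machinery of lineage-aware tools is out
of scope); constant genes get p = 1 by convention and are flagged. COG
enrichment requires adjusted p < .05 *and* OR > 1, so depletion never
qualifies.

The headline transmissibility comparison between island-only and
complete-system plasmid groups is computed **one-sided** (enrichment of
transmissible plasmids among island-only carriers); the virulence and
megaplasmid tables two-sided. One caveat surfaced while validating against
published reference values: BH *adjusted p-values* are not a fixed point of
the step-up procedure, so the test suite asserts monotonicity and
order-preservation rather than literal idempotence.

## Synthetic cohorts: what they emulate and what they don't

The generator emulates the *outputs* of upstream annotation: ordered gene
tables with planted complete clusters (8–14 distinct components, intra-
cluster gaps of 0–2 genes), orphan islands drawn from configurable type
weights, isolated tube/spike genes, IS neighbours near planted loci,
per-plasmid mobility/maintenance/accessory traits, protein-cluster tables
with planted transfer communities (noise adds only private singleton
clusters), and trees whose compartment character evolves by a symmetric
two-state Markov jump process with every realised jump recorded.

Default cohort conditions: 120 plasmids + 40 chromosomes; log-normal gene
counts (log-mean 5.0/6.2, so plasmids ≈ 150 genes, chromosomes ≈ 500 —
deliberately compact stand-ins); ~1 kb per gene; plasmid GC offset
−3.5 ± 1.0 points from the host; completeness/island/isolated plant
probabilities 0.45/0.35/0.25; an adjacent MGE at probability 0.5;
relaxase/MPF/partition/TA/AMR/VF trait rates 0.45/0.35/0.8/0.7/0.1/0.2,
chosen to echo the observed prevalence ordering (partition and TA nearly
ubiquitous on T6SS plasmids, AMR rare). Replicon size distributions are
free parameters, not calibrated claims — no public per-family plasmid size
distribution exists at the needed granularity. Each replicon has its own
RNG stream keyed by (seed, kind, within-kind index), so growing a cohort
never perturbs existing replicons; identical configurations are
byte-identical.

Planted features are separated by more than the intervening-gene threshold,
so noise-free recovery is exact by construction *given a correct detector* —
that is the point of the recovery suite: it checks the detector, not the
difficulty of real data. Real annotation noise (missed components, split
hits, mislabelled paralogs, nested loci) is not modelled; passing recovery
therefore shows rule-faithfulness, not robustness to annotation error.

## Experiment sizes and seeds

Problem sizes used by the test suite and the acceptance script, chosen as
comfortable desk-scale versions of each question: oracle equivalence on
1000 random gene tables (≤ 500 genes), every 2×2 table with N ≤ 30, and 200
random trees with ≤ 10 tips (relative tolerance 1e-10); exact recovery on a
1000-replicon noise-free cohort; community recovery over 20 seeds at noise
0 and 0.3; transition recovery over 100 trees of 100 tips at switch rate
0.1 per unit length on branches of mean length 0.1 (≈ 2 events per tree —
the low-switching regime where individual events remain identifiable), with
the reconstruction run at the generating process's symmetric equilibrium
frequencies; GWAS null calibration over 200 permuted datasets of 100 genes
× 40 plasmids. Recovered transition counts sit a few percent below planted
counts by construction: back-and-forth jumps on one branch are invisible to
any reconstruction, and ambiguous (MPPA-tied) branches deliberately count
nothing.

## Known limitations

* Subtype assignment is only as good as the supplied marker table.
* The naive GWAS inflates associations under strong population structure.
* MPPA-based transition counts are conservative (ambiguous branches count
  zero) and cannot see multiple hits per branch.
* The bipartite→projection route discards HPC identity during community
  detection; two communities sharing no HPCs but bridged by a third can
  merge at coarse resolution.
* Tip-proportion equilibrium frequencies are biased at low switch rates
  (tips over-represent the root state); prefer 0.5/0.5 when symmetry is
  defensible.
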