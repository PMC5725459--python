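# Methods

## Variant screen

Input SNP calls are biallelic multi-sample VCF records; multiallelic
and non-SNP records are rejected (and counted), never coerced.  An
individual is a *carrier* at a site when its genotype contains at
least one alternative allele — carrier status, not allele frequency or
dosage, is the unit of all population comparisons, being the weakest
condition consistent with an allele being "present only" in one
population.

Hard filtering follows the GATK convention: a variant is removed iff
QD < 5.0, MQ < 40.0, FS > 200.0 or QUAL < 30.0, all inequalities
strict, with a missing INFO statistic never firing its clause.  The
per-clause removal tally is reported with every run.

Coding effects are classified by direct codon substitution in the
spliced CDS (standard genetic code; minus-strand alleles complemented
first).  The classifier intentionally covers only the categories the
accounting needs — synonymous/non-synonymous, splice site (within 2 bp
of an exon/intron boundary, the SnpEff convention), UTR, intron,
intergenic — and is cross-checked against the generator's annotations
in the tests.  Severity (impact) follows the usual mapping (stop
gain/loss and splice HIGH, other missense MODERATE, synonymous LOW,
non-coding MODIFIER) but an externally supplied impact table (as an
annotation tool would emit) overrides it, which is how a LOW-impact
missense enters the system.  When a site overlaps several gene
annotations the most severe label wins (exonic > splice > UTR >
intron > intergenic).  Ti/Tv is the ratio of transitions (A↔G, C↔T)
to transversions over ref→alt pairs without strand folding.

A variant is **focal-unique** iff (a) non-synonymous with HIGH or
MODERATE impact, (b) carried by ≥ 1 focal individual, (c) its alt
allele is absent from every comparison-breed call set at the same
chrom:pos (any called alt disqualifies — comparison call lists, not
genotype frequencies), and (d) no related species shows the
alternative residue at the orthologous alignment column.  The
cross-species check runs at aligned-residue level because no genomic
lift-over between species is assumed: the focal protein position maps
to its alignment column, and a species' residue set there is its
aligned residue plus any recorded within-species alternatives; a gap
makes the species non-informative (condition (d) vacuously true for
it).  A gene with candidate variants but no alignment is flagged
unevaluable and excluded rather than silently passed.

Genes are partitioned by the subpopulations of the carriers of their
focal-unique variants: only tail (long- or short-tail) carriers →
tail-specific; only non-tail → non-tail-specific; both → common.  The
three sets provably partition the carrier-bearing focal-specific genes
(asserted on every run).  Term over-representation uses the one-sided
hypergeometric upper tail per term with Bonferroni adjustment
(adj = min(1, raw × #terms), enriched iff adj < 0.05); the flat
term→gene map is deliberate — no ontology DAG propagation.

## Network propagation

RWR solves r = c·e + (1−c)·W·r by power iteration (L1 stopping
tolerance 1e-12, well below the reported 1e-8 oracle agreement), with
c = 0.95 by default, e uniform over the seeds and W the
column-normalized, score-weighted adjacency (a flag switches to binary
adjacency).  Columns of isolated nodes redirect to e, keeping W
stochastic; consequently the scores sum to exactly one at every
iteration and nodes unreachable from the seeds score exactly zero.
The propagation network is *not* pre-thresholded at 0.7 — the
credibility threshold belongs to the interaction-evolution analysis —
but a config flag can apply it to propagation too.

The extended protein set is the top 5% of nodes with nonzero score
(ceiling of fraction × count), ranked by score descending with
lexicographic protein id as the deterministic tie-break; seeds rank
like any node.  The denominator is the set of nonzero-scoring nodes,
which makes the extended-set size depend on the seed set's reach — the
definition is configurable because reasonable alternatives (all nodes;
non-seed nodes) exist.  Subnetwork extraction keeps edges with both
endpoints in the set and score ≥ 0.7 (inclusive).  The within/between
test compares interacting pair counts inside the two disjoint extended
sets against pairs bridging them, with a one-sided hypergeometric
upper-tail p (equivalent to one-sided Fisher on the 2×2 table).

## Interaction transfer and ancestral reconstruction

A dog pair's state in another species is decided by a strict majority
rule over ortholog groups: with m and k members, present iff
(interacting cross pairs) / (m×k) > 1/2 using edges with score ≥ 0.7;
exactly half is absent.  Self-pairs arising when both dog proteins
share one group are excluded from the count; an empty group or an
unmapped dog protein yields unknown.  The dog state itself is read
from the dog network and is never unknown.

Ancestral states are reconstructed by Fitch parsimony on the rooted
tree ((dog,cat),(horse,(pig,cow))).  Unknown tips contribute the
unconstrained set {0,1} — treating absence of evidence as evidence of
absence would bias gains onto the dog branch, the direction of the
headline result, so the conservative choice is deliberate.  The
bottom-up pass counts union events (the parsimony score); the
top-down pass resolves ambiguous nodes to the parent's resolved state,
which concentrates changes away from the root (DELTRAN-like) and
provably realizes the minimum change count (tested).  A per-node
"accelerated" alternative was considered and dropped: a greedy
away-from-parent choice over Fitch preliminary sets is not guaranteed
to yield a minimum-change labeling, which would break the conservation
identity below.  Root ambiguity is resolved by the outgroup (mouse)
state — taken from the profiles, since mouse is not a tree tip — and
falls back to absent when the outgroup is unknown.

Branch accounting reports, per branch parent→child, the gains (0→1),
losses (1→0), the at-risk denominators (pairs absent/present at the
parent) and the corresponding fractions; a zero denominator reports
not-applicable rather than zero.  Total gains+losses over branches
equals the summed parsimony scores (asserted).  The randomization test
draws, 10,000 times, as many pairs as observed uniformly without
replacement from the profiled universe (all dog pairs with computable
profiles) and recomputes each branch's gain fraction from the cached
reconstructions — valid because a pair's reconstruction does not
depend on which other pairs were sampled — giving the one-sided
add-one-smoothed empirical p.

## Synthetic data: what it emulates, what it does not

The cohort generator reproduces the study design: 7 long-tail, 5
short-tail and 10 non-tail focal individuals, a 12-breed comparison
panel with sizes (10, 10, 10, 10, 10, 10, 3, 1, 1, 2, 2, 1), six
related species, and a background substitution process targeting
Ti/Tv = 2.05.  Genes (default 60) are single- to three-exon models on
one chromosome with random non-stop CDS, flanking UTRs and both
strands.  Planted genes (default 10, the tail/non-tail/common split
following the 39:20:98 proportions of the motivating study) receive
focal-unique missense SNPs; every remaining gene is a decoy violating
exactly one uniqueness condition — synonymous effect, LOW-impact
annotation, the same allele carried in a comparison breed, or the
alternative residue present in a related species (alternating between
the aligned row and the within-species residue table).  Related-species
variation is represented directly as residues at alignment columns
because the pipeline consumes it at that level.  A handful of
low-quality background sites (two per filter clause) exercises the
hard filter.

The interaction-history generator evolves each pair as a two-state
Markov chain from the root (present with probability 0.25) with gain
rate 0.04 and loss rate 0.02 per branch, branch lengths ignored.  A
planted subset (default 25% of pairs) uses gain_rate × excess_factor
on one designated branch; that subset is the "observed" set of the
randomization test, the full pair universe its null.  Tip states are
materialized as per-species networks through ortholog groups of 1–3
members, with the number of interacting cross pairs drawn strictly
above or at-most half so the majority rule recovers the evolved state
exactly.  Scores sit in [0.75, 0.99], above the 0.7 credibility
threshold.

What passing tests therefore show: the screening logic, the
propagation fixed point, the transfer rule and the reconstruction
machinery are correct against independent oracles and recover planted
truth exactly under noise-free conditions.  What they do not show:
behavior under real linkage disequilibrium, shared demography between
breeds, alignment error, incomplete ortholog databases or STRING score
noise — none of which the generator models.  Problem sizes (60 genes,
2,000 pairs, 10,000 randomizations, 500 oracle characters, 100 oracle
graphs) are the package's test conditions, chosen to exercise every
code path at high statistical resolution.

## Known limitations and edge cases

- Parsimony can reconstruct losses that never happened when a pair
  gained convergently on sibling lineages (an ancestral gain plus one
  loss is cheaper than two independent gains); this is a property of
  maximum parsimony itself, confirmed against the brute-force oracle,
  and bounds what "loss-free history in, loss-free reconstruction out"
  can promise.
- Multiallelic sites are rejected rather than split; splitting is an
  upstream normalization concern.
- Ti/Tv of a full synthetic cohort sits below the background target
  because planted missense variants are constrained by the codon
  structure; the target governs the background substitution sampler.
- The hypergeometric within/between p is conservative (discrete), so
  its null distribution is super-uniform rather than exactly uniform.
- No probabilistic (ML/Bayesian) ancestral reconstruction and no
  branch-length-aware models; divergence times are decorative.
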