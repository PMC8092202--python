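# Methods

This note documents the models, algorithms and design choices behind
`panerosion`, in the spirit of the methods documentation of simulation and
statistics packages: what each stage assumes, which knobs matter, and what
the synthetic validation does and does not demonstrate.

## The synthetic pangenome generator

The generator (`panerosion.simulate`) emulates a clade of related
bacterial genomes undergoing convergent genome reduction. It is the
package's validation substrate: every downstream stage can be checked
against the planted truth it records.

**Species tree.** A pure-birth (Yule) tree with birth rate 1.0 per unit
time. After the topology and waiting times are drawn, every branch length
is multiplied by an independent Gamma(shape 2, mean 1) variate — a relaxed
clock. This matters: a strictly clock-like Yule tree makes every leaf
equidistant from the root, so every genome would face the *same* expected
gene loss and the genome-size gradient that the erosion statistics detect
would arise only from sampling noise. Real reduced-genome clades contain
strains at visibly different stages of reduction; the relaxed clock is the
minimal way to encode that heterogeneity. With the default 20 taxa,
root-to-leaf path lengths typically span a 2–4× range.

**Gene content.** Each of the 1000 ancestral families belongs to one COG
category; the default panel mirrors the canonical erosion story:

| category | loss rate (events / unit branch) | pseudogenization rate |
|---|---|---|
| K (transcription) | 0.8 | 0.3 |
| L (replication/recombination/repair) | 0.5 | 0.8 |
| N (cell motility) | 0.3 | 0.4 |
| E (amino-acid metabolism) | 0.1 | 0.05 |
| J (translation) | 0.0 | 0.02 |

Loss is an irreversible Poisson process on branches: a family lost on a
branch is absent from the entire descendant subtree, and the per-leaf
retention probability for rate r and root-to-leaf depth d is exp(−r·d).
Families are assigned to categories round-robin (200 each by default).

**Sequences.** Each family starts from a random CDS (ATG, stop-free sense
codons, terminal stop; 200 codons by default) and evolves along the tree
under a K80-like substitution scheme (transition:transversion 2:1, default
0.02 substitutions per site per unit branch length). The process is
*nonsense-free*: substitutions that would create an in-frame internal stop
or touch the start/terminal codon are reverted. This is deliberate — it
guarantees that planted lesions are the only source of pseudogenization,
so the classifier's precision can be measured exactly. Real sequences do
acquire spontaneous nonsense mutations; the generator trades that realism
for an unambiguous ground truth.

**Lesions.** A retained gene pseudogenizes with probability
1 − exp(−ψ·d); the mechanism is drawn from `mech_probs` (defaults:
internal_stop 0.2, frameshift 0.2, stop_frameshift 0.3, gap_decay 0.3):

* `internal_stop` — one sense codon (not the start, strictly before the
  last sense codon) replaced by TAA/TAG/TGA;
* `frameshift` — a 1–2 bp insertion at an interior position;
* `stop_frameshift` — a nonsense codon followed by an indel planted 3′ of
  it. The ordering models post-nonsense decay (downstream sequence is
  released from selection) and makes the stop visible in the annotated
  reading frame regardless of how the alignment places the indel. This
  combined lesion exists because the conjunctive classification rule can
  only ever detect genes carrying *both* kinds of damage;
* `gap_decay` — a contiguous codon-aligned deletion removing strictly
  more than 30% and at most 60% of the CDS. Codon alignment keeps the
  junction stop-free, so these genes exercise *only* the gap criterion.

Two identifiability constraints apply. Pseudogenes are planted only in
families present in at least two genomes, and every family retains at
least one intact member (a reverted copy if the draws would degrade all).
The classification rule is comparative: stops, frameshifts and gaps are
all defined relative to an alignment with intact homologs, so lesions in
singleton or fully degraded families would be undetectable *in principle*
and would contaminate recall measurements with a floor that says nothing
about the classifier.

**Emission.** Assemblies are single contigs: genes in family order,
separated by uniform 50–500 bp random spacers, plus GFF3 (1-based
inclusive, `ID=` and `product=` attributes), CDS/protein FASTA, a
metadata table (genome size = contig length; phenotype `motile` iff ≥50%
of N-category families are retained), the gene→COG map, the true tree and
ground-truth tables. All output is byte-deterministic for a fixed config;
independent RNG substreams per stage mean the content-only mode
(`with_sequences=False`, used for statistics over many replicates)
reproduces exactly the tree/content/status draws of a full run.

## Orthology

All-vs-all protein comparison uses Smith–Waterman local alignment
(BLOSUM62, gap open −11 / extend −1) with a score floor of 50; best hits
per (query, target-genome) break ties by higher identity, then smaller
subject id. RBH edges require mutual best hits and raw groups are the
connected components of the RBH graph — a deliberately simple stand-in
for Markov-clustering orthology engines, with a TSV hook for ingesting
externally computed groups. The refinement step partitions every raw
group by exact annotation equality (whitespace-trimmed, case-sensitive;
genes with no annotation become logged singletons). Case sensitivity is a
convention choice; automated annotation pipelines emit product strings
with stable casing, so exact matching is the conservative reading.
Presence/absence collapses paralogs: a genome is present in a group if it
contributes at least one member, intact or degraded.

## Pseudogene classification

Per family: frame-consistent members (ungapped CDS, terminal stop
stripped, exactly 3× the protein length) enter a center-star progressive
protein MSA, which is back-translated to a codon alignment (protein gaps
→ `---`). Internal stops are counted on codon rows (bacterial table 11;
gap codons skipped, N-containing codons ignored, the final non-gap codon
excluded). The gap fraction is the share of gap characters in the row of
the *nucleotide* alignment. Frameshifts are counted against a reference —
the longest frame-consistent, stop-free member — as maximal indel runs
with length ≢ 0 (mod 3) in a global nucleotide alignment (match +2 /
mismatch −3, gap open −5 / extend −2), terminal overhangs excluded.

Three robustness choices deserve explanation:

* **Center selection.** The center-star center is the longest member
  maximizing the summed pairwise score *among the longest members*. If a
  truncated member is used as the scaffold, the full-length members'
  "insertions" (the scaffold's missing block) land in slightly different
  scaffold slots and the merge fragments the alignment, inflating
  everyone's gap fraction past the 30% threshold.
* **Frame-inconsistent members** (CDS length ≠ 3× protein length) are
  kept out of the MSA — their translation is off-frame downstream of the
  lesion — and scored directly against the reference. Their frameshift
  count has a floor of 1: the length inconsistency is itself frameshift
  evidence, and an indel within ~3 bp of the CDS end can otherwise merge
  into the excluded terminal overhang. Their stop count is the maximum
  over the frame-corrected sequence (insertions removed, deletions padded
  with N) and the raw annotated frame: near a frameshift the optimal
  alignment can trade a stop codon's three mismatches for a pair of gaps,
  hiding the stop from the corrected frame, while upstream of the first
  indel the annotated frame is exact.
* **Decision modes.** The default `literal` mode is the conjunctive rule
  ((stops ≥ 1 AND frameshifts ≥ 1) OR gap > 0.30); `any` ORs all three
  criteria. Both are first-class because the conjunction leaves genuinely
  broken genes (a lone nonsense mutation) unclassified; the calls table
  records all three evidence values and the fired criteria either way.
  The gap threshold is strictly greater-than: exactly 30% does not fire.

## ANI

Orthologous-fragment ANI: contigs are cut into consecutive 1020-bp
windows (trailing remainders discarded); fragments are matched across
genomes by shared 15-mers on both strands (non-overlapping seed stride),
the best candidate is globally aligned with edlib, and pairs must keep
≥70% matched columns. The genome-pair ANI is the mean identity over
*reciprocal best* fragment pairs (symmetric by construction; NaN when no
pair passes, and NaN never merges in clustering). Threshold clustering is
single-linkage with an inclusive boundary: genomes merge iff ANI ≥
cutoff. Single linkage is the reading most consistent with "clustered at
a cutoff": a chain of near-identical genomes is one species even if its
endpoints fall below the cutoff.

## Erosion statistics

Gene proportions p(g,c) divide by the genome's total gene count
(COG-unmapped genes included by default; a flag excludes them) and
multi-letter genes count once in every carried category. Pseudogene
profiles q(g,c) divide by the genome's pseudogene count and are NaN when
there are none. The trend test is Spearman correlation of p(·,c) against
genome size — exact permutation p for n ≤ 9 genomes (all n!
permutations, vectorized), the t-approximation otherwise — with OLS
slope/intercept reported alongside; the verdict (`eroded` if p < 0.05 and
rho > 0, `preserved` if p < 0.05 and rho < 0) follows the Spearman test.
No multiple-testing correction is applied across categories, matching the
per-category reporting convention of erosion studies. State matrices
encode gene=2 / pseudogene=1 / absent=0, with pseudogene taking
precedence over intact paralogs so that any erosion evidence is surfaced;
rows are clustered with complete-linkage Euclidean agglomeration (rows
pre-sorted by label for deterministic ties). The Wilcoxon rank-sum test
enumerates the exact permutation null (conditional on observed mid-ranks)
when the combined sample is ≤ 12 and otherwise uses the normal
approximation with continuity and tie corrections.

## Phylogenetics and ordination

Core genes are single-copy, universal, pseudogene-free groups, processed
in group-id order; concatenation emits a 1-based inclusive partition
table. When no externally inferred tree is supplied, a neighbor-joining
tree on p-distances of the concatenated alignment serves as a
self-contained fallback (negative branch lengths clamped to zero) —
it is not a substitute for model-based inference and is labelled as a
fallback in the interfaces. PCoA is classical metric scaling: Gower
double-centering of the squared distances, eigendecomposition, axes
scaled by √λ for positive eigenvalues, each axis oriented so its first
nonzero loading is positive. Negative eigenvalues (possible for
non-Euclidean metrics such as Jaccard) are reported but excluded from the
explained-variance denominator. The default presence/absence metric is
Euclidean distance on 0/1 genome columns, under which classical scaling
is exact. Robinson–Foulds distances are computed on the bipartitions of
the subtrees induced on the shared leaf set (trivial bipartitions
excluded); tanglegram pairing uses each tree's ladderized leaf order and
lists unmatched leaves per side. Rooting helpers provide midpoint rooting
and root-on-outgroup-then-prune.

## Problem sizes and validation scope

The default study conditions — 20 genomes × 1000 families × 200 codons —
keep a full pipeline run around 1–2 minutes on one CPU while leaving
~2400 planted lesions and ~100 core genes per run; the erosion-verdict
rates are measured over 50 content-only replicates (seconds each). The
acceptance script reports quantities at these sizes.

Passing the synthetic validation shows that the implementation applies
its stated rules exactly and recovers planted signal under the
generator's assumptions. It does *not* show robustness to features the
generator omits: annotation errors and missing product strings,
assembly fragmentation and contig-edge gene truncation, horizontal
transfer and paralog expansions, spontaneous nonsense substitutions,
rearrangements, or compositional heterogeneity between lineages. On real
data the literal/any mode choice, the COG mapping quality and the MSA
quality are the dominant sources of disagreement.
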