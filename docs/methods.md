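# Methods

This note documents the models, rules and numerical choices behind each
stage, what the synthetic data does and does not emulate, and the design
decisions taken where more than one reasonable option existed.

## The problem

A single individual carries two circular mitochondrial genomes: a major
molecule M1 (18,078 bp here) and a minor molecule M2 at ~10.4% nucleotide
divergence, present at roughly one seventh the concentration. The analysis
must (i) separate mixed sequencing reads between the molecules, (ii) verify
both are genuine mitochondrial molecules rather than nuclear copies,
(iii) date their split and the split of the carrier populations, (iv) test
the phylogenetic placement of the second molecule and the concerted
evolution of triplicated non-coding (Control-Region-like) blocks, and
(v) describe the genome rearrangement. Every step is implemented as a
library function; the drivers and the acceptance script only compose them.

## Read binning

A read is aligned (edlib, edit-distance alignment) against each reference,
in both orientations, with circular references doubled so origin-spanning
reads align contiguously. Alignments beyond a 35% edit fraction are not
pursued and count as identity 0. Identity is **gap-compressed** —
matches / (matches + mismatches + gap openings), each contiguous gap
counting once — because long single-molecule reads carry many short
unread-base gaps that would otherwise dominate the denominator.

**Decision rule.** The stated cutoff is a 5% difference between molecules;
the comparison arithmetic is a design choice here: a read is called for the
molecule with the higher identity when the identity difference is at least
`delta_rel = 0.5 × delta` (2.5 identity points at the 5% setting). A read
from one molecule is expected to lose the full inter-molecule divergence
against the wrong reference while noise is symmetric, so half the cutoff is
a balanced margin. Exact ties and sub-margin differences are left
unassigned, never broken arbitrarily; raw identities are always emitted so
any alternative rule can be applied post hoc. Reads aligning to only one
molecule's non-homologous region receive identity 0 on the other side and
are called from the single finite identity. Paired-end mates are assigned
independently.

The minor-molecule share is the minor count over assignable (M1 + M2)
reads, with a 95% Wilson score interval. Coverage breadth/depth are
computed from aligned spans with circular wrap-around. The majority-vote
consensus re-projects read bases through the alignment path; the reference
base breaks per-position ties, and zero-depth positions keep the reference
base and are flagged. The k-mer repeat scan (default k = 71, canonical
k-mers) takes the modal draft-genome k-mer count as single-copy depth and
flags k-mers at ≥ 1.6× that depth, merging their draft positions into
regions — this is how a collapsed tandem repeat or a triplicated block
reveals itself against a draft assembly.

## Mitogenome QC

- **Composition**: exact base counts on the heavy strand (defined as the
  strand given in the FASTA), N excluded from the denominator. Vertebrate
  heavy strands are strongly G-poor, so the guanine percentage is the
  headline number.
- **Translation**: NCBI translation table 2 (TGA = Trp, ATA = Met,
  AGA/AGG = stop). Light-strand genes are reverse-complemented first.
  Incomplete terminal stops (T or TA completed by polyadenylation) pass
  with a flag; the criterion for a real mt-genome is the absence of
  internal stops.
- **tRNA folding** is a constrained combinatorial search over cloverleaf
  layouts — acceptor 6–8 bp, D arm 3–4 bp + 4–12 nt loop *or* a D-arm
  replacement loop, anticodon stem 5 bp with a 7 nt loop, variable region
  3–23 nt, T arm 4–5 bp + 5–9 nt loop, with at most one G·U or mismatch
  per stem — rather than free-energy minimization: the claim being tested
  is structural plausibility (arms present, anticodon recoverable), which
  constraint satisfaction answers deterministically. Scoring prefers a
  true D stem over a replacement loop and penalizes defects, so the
  replacement loop is reported only when no D stem fits. Random 70-mers
  fold in under 5% of trials.
- **Stem-loop scan**: maximal hairpins (stem ≥ 5 bp of WC/G·T pairs,
  loop 3–20 nt, perfect pairing by default) in the tRNA-Asn–tRNA-Cys
  window, reporting overlaps into the flanking tRNAs and the presence of
  the 5'-GGC-3' heavy-strand elongation triplet at the stem base.

## Divergence and dating

p-distance with pairwise deletion of gaps and N, and optional exclusion
masks (e.g. the unalignable tail of the third non-coding block). No
multiple-hit correction is applied because the clock rate used — 1.3%
pairwise divergence per million years, from the well-dated ND1–COI section
of amphibian and reptile mtDNA — is itself an uncorrected-percent rate;
correcting the distance but not the rate would bias the dates. Time is
reported to one decimal (t = 100·d / r). A model-corrected distance is not
used anywhere in the analysis.

The progressive aligner (for small sequence sets such as NC blocks or
tRNAs) uses Gotoh affine-gap pairwise/profile alignment (match 1,
mismatch −1, open −4, extend −1) over a UPGMA guide tree from k-mer
distances; it is deterministic and intended for ≤ 20 sequences. Externally
produced alignments can always be loaded instead. Genome-scale alignment
of the simulated molecules is trivial because the generator introduces no
indels.

## Parsimony machinery

Fitch (unordered, unit-cost) optimization with gaps and N as missing data;
site patterns are collapsed with weights and the Fitch pass is vectorized
over patterns. Branch-and-bound stepwise addition is exact: partial-tree
length never decreases as taxa are added, so partial trees longer than the
best complete tree are pruned; taxa are added in decreasing distance to the
first taxon for tight early bounds. The search collects **all**
minimum-length trees and is guarded to ≤ 16 taxa (everything in this
analysis uses ≤ 9).

Bootstrap resamples sites with replacement and credits a split when it
appears in the strict consensus of that replicate's shortest trees (ties
collapse rather than being broken by discovery order). Decay (Bremer)
indices are computed by reverse-constraint search — the shortest tree
*incompatible* with the clade, minus the global shortest — which is the
same quantity as suboptimal-tree sweeps but exact by construction. The
whole-tree collapse value is the minimum decay over consensus splits.

The Templeton test compares per-site Fitch steps of two trees: zero
differences dropped, midranks on |difference|, two-tailed. With ≤ 20
differing sites the exact sign-permutation distribution of the rank sum is
computed by dynamic programming; above that, the normal approximation with
tie-corrected variance is used. Swapping the trees negates z and preserves
p.

Concatenation rules follow the published protocol for this system: ND5
excluded (absent from earlier datasets), bicistronic overlaps dropped
(last 96 nt of ATP8, last 7 nt of ND4L), and stated gap insertions applied
to rows shorter than a gene's longest row (the 15 + 6 nt Cytb insertions).

## Gene orders

Orders are signed circular permutations canonicalized by rotating to
tRNA-Phe and reflecting when the anchor reads on the light strand.
Breakpoints are counted on the shared single-copy gene set — duplicates,
non-coding blocks and pseudogenes (the second tRNA-Lys copy) are removed
first and reported separately, since breakpoint distance is defined on
single-copy permutations. A gene is "moved" when its signed
(predecessor, successor) context differs, so immediate neighbours of a
relocated segment are included; the report is therefore a superset of a
curated moved-gene list. Rearrangement-scenario inference (which events
produced the order) is out of scope; no simple duplication-loss model
explains this rearrangement.

## The synthetic data

The generator's defaults are the study conditions: 18,078 bp genomes,
10.4% target divergence, three NC blocks homogenized to ≥ 99% within-genome
identity, a 14.5% minor read share, 100 bp paired-end reads at 180 bp
inserts with 0.1% substitution error, and long reads with lognormal lengths
moment-matched to mean 2504.5 / sd 2409.2, truncated to [514, 16978], at
3% substitution and 2.5% each insertion/deletion error, with a 1%
probability of a full-molecule two-strand read (genome + reverse
complement, emulating an end-connected native duplex).

Divergence is introduced as a fixed number of substitutions
(`round(d·L)`) at disjoint random positions split between the two lineages,
with a transition:transversion bias of κ = 4 (mitochondrial sequences are
transition-rich; the value is configurable and the system names no model).
Constraints: CDS start/stop codons are never touched, substitutions that
would create internal stops are rejected per codon, and tRNA stem
positions are held fixed — real mt-tRNA stems evolve by compensatory
pairing, which holding them fixed approximates without modelling
covariation. Heavy-strand base frequencies are drawn G-poor
(A/C/G/T = 0.33/0.28/0.14/0.25) so the composition QC is meaningful.
Concerted evolution is simulated by copying each genome's first NC block
over the others with independent noise at 1 − within-identity; the noise
stream is keyed on the master-block content so a zero-divergence pair stays
bit-identical. The realized pairwise divergence therefore lands within
±0.005 of target by construction (the NC noise adds ≈ 0.002).

For population-level analyses, island samples are placed by *reverting*
nested random subsets of M1's derived sites back to the ancestral state
(creating internal points of the M1 lineage where the second molecule and
the southern group attach) and then evolving tips forward. Depths used:
northern ancestor at 0.004, population root at 0.008, southern ancestor
+0.008, tips +0.002 — giving ≈ 1.6% north–south divergence (≈ 1.2 My at
the clock rate) with the LAI M1 genome inside the northern clade. The
third sample for the NC analysis splits half its 2% divergence back along
the M1 lineage and keeps homogenizing its own NC blocks.

**What the simulation does not emulate**: indels between the genomes (so
whole-genome alignment is trivial and the NC3-tail exclusion mask, though
implemented, is not exercised by default), base-quality profiles, chimeric
reads, nuclear mitochondrial insertions, and within-read error
autocorrelation. Passing tests therefore demonstrate the correctness of
the decision rules and statistics under a clean two-molecule mixture, not
robustness to assembly artifacts or NUMT contamination.

## Problem sizes

The drivers and checks run at desk scale by choice: long-read mixtures of
~100–300 reads (enough for the Wilson interval to be informative at a
14.5% minor share), 6–9-taxon exact searches, and 100-replicate bootstraps
(1000 available via the CLI). The binning calibration check runs 100
seeded mixtures of ~74 reads each.

## Numerical choices and degenerate inputs

- Identities and divergences are exact rational counts formatted late.
- Assignment ties → unassigned; consensus ties → reference base; bootstrap
  ties → strict consensus per replicate.
- Zero assignable reads, zero comparable sites, all-N sequences, empty
  alignments and leaf/alignment mismatches raise named validation errors
  rather than returning zeros.
- Coverage with no assigned reads reports breadth 0 and null depth
  statistics (not 0).
- All randomness flows from explicit seeds; each generator operation draws
  from its own seeded stream so stages can be re-run independently.
- Annotation text files are 1-based inclusive (GFF convention); internal
  coordinates are 0-based half-open; origin-spanning circular features are
  stored unwrapped with `end` beyond the genome length. Positions quoted
  in the source material are assumed 1-based inclusive (standard GenBank
  convention).

## Known limitations

- The exact searches do not scale beyond ~16 taxa; no heuristic mode is
  provided.
- The Templeton normal approximation is used above 20 differing sites;
  its tie correction matches the standard Wilcoxon procedure but no
  continuity correction is applied.
- The aligner is a small-set progressive aligner, not a MUSCLE
  re-implementation; for large or indel-rich sets an external alignment
  should be supplied.
- Two reported whole-genome divergences (10.4% vs 10.1%) plausibly
  reflect different masks or gene subsets; both masks are supported and
  the acceptance script reports the synthetic realized value, which tracks
  the 10.4% generator target.
- Site-level selection analyses are out of scope; only summary fractions
  over an externally supplied site-classification table are computed.
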