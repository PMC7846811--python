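# mitotwin

Tools for discovering and characterizing **two deeply divergent, co-existing
mitochondrial genomes in a single individual** from mixed sequencing reads —
the situation found in the Tuatara (*Sphenodon punctatus*), where an 18.1 kb
molecule (M1) and an 18.3 kb molecule (M2) differ by ~10% nucleotide
divergence and are carried together at roughly a 1:7 minor:major ratio.

The package is organised as an analysis project: a library under
`src/mitotwin/` implements every step, and numbered drivers under
`analysis/` run the study end to end on synthetic data that emulates the
two-molecule system with known truth labels.

## What it does

1. **Read binning** (`partition`): each read is aligned to both candidate
   molecules (both orientations; circular references are doubled so reads
   wrap the origin) and called for the molecule with the higher
   gap-compressed identity when the margin clears a divergence cutoff
   (default 5%, reads < 500 bp set aside). The minor-molecule share of
   assignable reads is estimated with a 95% Wilson interval; per-molecule
   breadth/depth of coverage, majority-vote consensus, k-mer repeat
   detection, and contaminant purging are also provided.
2. **Mitogenome QC** (`qc`): heavy-strand composition bias (vertebrate
   mtDNA is G-poor), translation of all 13 protein-coding genes under the
   vertebrate mitochondrial code (NCBI table 2; incomplete T/TA stops are
   flagged, not failed), constrained cloverleaf folding of tRNAs (including
   D-arm replacement loops), and detection of O_L-like stem-loops between
   tRNA-Asn and tRNA-Cys.
3. **Clock dating** (`divergence`): uncorrected p-distances (pairwise
   deletion of gaps/N, optional exclusion masks for unalignable regions)
   converted to time as `t = 100·d / r` at the empirical rate
   r = 1.3% divergence per million years.
4. **Parsimony phylogenetics** (`parsimony`): exact branch-and-bound
   searches with Fitch optimization, nonparametric bootstrap, Bremer decay
   indices via reverse-constraint searches, Templeton (Wilcoxon
   signed-ranks) comparisons of trees with tie correction (exact for ≤ 20
   differing sites), strict consensus, and concatenated-alignment
   construction with bicistronic-overlap exclusions and stated gap
   insertions.
5. **Gene-order comparison** (`gene_order`): signed circular permutations
   canonicalized by rotation/reflection; breakpoint counts and moved-gene
   reports on the shared single-copy gene set, with duplications and extra
   non-coding (Control-Region-like) blocks reported separately.
6. **Synthetic data** (`simulate`): an ancestor with the standard
   vertebrate gene order evolved into two molecules under a K2P process
   with coding and tRNA-stem constraints, concerted-evolution
   homogenization of the non-coding blocks, and short paired-end plus
   indel-rich long-read mixtures with per-read truth labels.

## Worked example

```bash
cd analysis
python 02_partition_reads.py --seed 0
```

prints

```
302 of 303 reads called (100.0% agree with truth labels); minor share 14.2%
(95% CI 10.7-18.6%, simulated 14.5%).
M1 breadth 100.0% at 33.3x; M2 breadth 100.0% at 5.8x.
```

i.e. on a simulated long-read mixture at the study conditions the
divergence-cutoff rule bins essentially every read correctly, and the Wilson
interval of the estimated minor-molecule share covers the simulated 14.5%.
Continuing,

```bash
python 04_divergence_dating.py --seed 0
```

prints

```
M1 vs M2: 10.5% -> 8.1 My separation (study system: 10.1% -> 7.8 My).
North vs south groups: 1.6% -> 1.2 My (study system: 1.6% -> 1.2 My).
```

and `python 06_nc_concerted_evolution.py --seed 0` shows the three
non-coding blocks clustering by genome (concerted evolution), with
monophyly of each block class rejected at 84–88 extra steps.

The `mitotwin` console command exposes the same stages
(`simulate`, `assign`, `qc`, `diverge`, `mp`, `order`, `run`, `demo`).

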