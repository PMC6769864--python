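# mitolineage

Matrilineal diversity analysis of cattle mitochondrial genomes.

Complete-mitogenome surveys of composite cattle breeds ask a recurring set of
questions: how many maternal haplotypes does a herd carry, how diverse are
they, which taurine (*Bos taurus*) and indicine (*Bos indicus*) haplogroups do
they belong to, and do any animals represent divergent, previously undescribed
matrilines? `mitolineage` implements that entire analysis as a tested Python
library plus thin drivers: haplotype collapsing, Nei diversity statistics,
sliding-window diversity scans, diagnostic-motif haplogroup classification,
neighbor-joining trees with bootstrap supports, and median-joining haplotype
networks — together with a synthetic cohort generator so the whole pipeline is
reproducible without any sequence download.

## The statistics at the core

For `n` aligned mitogenomes restricted to the usable sites `L` (complete
deletion: any column with a gap or `N` is dropped):

* haplotype (gene) diversity, with haplotype frequencies `p_i`:
  `Hd = n(1 − Σ p_i²)/(n − 1)`, with Nei's sampling variance (Nei 1987,
  eq. 8.12) reported as `± SD`;
* mean pairwise differences `k = Σ_{i<j} d_ij / C(n,2)` and nucleotide
  diversity `Pi = k/L`, with Nei's eq. 10.7 total variance as `± SD`;
* segregating sites `S`, split into singletons and parsimony-informative
  sites (a variable column is informative iff ≥2 bases each occur in ≥2
  sequences);
* haplogroup assignment by diagnostic-mutation motifs: 1-based reference
  positions ("np", V00654-style frame) whose derived alleles jointly diagnose
  a clade (T vs I), a haplogroup (T1–T6, I1, I2) and sub-haplogroups (T1a,
  I1a — the I1a motif comprises the five published sites 1495, 3051, 8646,
  12622, 14027; the T6 motif the twelve published sites 106, 169, 2536, 7931,
  9682, 11899, 12923, 13310, 13374, 14063, 16109, 16255);
* Saitou–Nei neighbor joining over haplotype Hamming distances, with supports
  from resampling alignment columns;
* Bandelt-style median joining: the ε-relaxed minimum spanning network over
  haplotypes, augmented with majority-consensus median vectors until closure.

## Worked example

```bash
python analysis/01_simulate_cohorts.py   # synthetic cohorts (fixtures under scratch/)
python analysis/02_diversity_statistics.py
python analysis/04_tree_and_network.py
```

The second step prints the per-breed summary (written to
`results/table1.tsv`):

```
  breed   n  T1  T2  T3  T4  T6  I1  I2   S  H     Hd    Hd_sd       Pi    Pi_sd     k
Brahman  31  11   0   8   0   0   7   5 308 20 0.9656  0.01668 0.007787 0.003819 127.2
Yunling 129  19   5  37   7   2  54   5 397 47 0.9646 0.007502  0.00796 0.003804   130
  Total 160  30   5  45   7   2  61  10 448 64 0.9714 0.005645 0.007922  0.00378 129.4

composite cohort: H=47, Hd=0.965±0.008, k=130.046, Pi=0.00796, S=397 (51 singletons, 346 informative)
```

Each row gives the haplogroup composition (counts of animals per haplogroup),
the number of segregating sites S, haplotype count H, haplotype diversity Hd,
nucleotide diversity Pi and mean pairwise differences k; the Total row is
computed on the pooled alignment, not by summing rows. The third step reports
the deep split between the two maternal lineages:

```
160 animals collapse to 64 haplotypes
taurine/indicine clusters separated by 233 mutations in the network
NJ bootstrap support for the taurine/indicine split: 100% (1000 replicates)
```

The same stages are available as a CLI (`mitolineage simulate | stats | scan |
classify | tree | network | run | validate`); `mitolineage run` executes the
whole pipeline on any aligned FASTA + breed TSV and writes a manifest with
input checksums alongside the artifacts.

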