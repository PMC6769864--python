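# Methods

## Coordinate frame and site filtering

All positions are 1-based nucleotide positions ("np") in a fixed reference
frame, the convention in which cattle mtDNA diagnostic sites are published
(bovine reference V00654). Alignments are treated as linear; mitogenome
circularity is ignored because every printed diagnostic position is a linear
np value. When a reference row with gap characters is supplied, inserted
columns carry no np and are excluded from motif matching; otherwise column
`i` (0-based) is np `i+1`.

The default site policy is **complete deletion**: any column containing `-`
or `N` in any sequence is excluded before haplotype collapsing and all
statistics, matching the behaviour of the classic diversity software for
which these statistics were defined. Pairwise deletion is available but not
default. Whether real published counts of segregating sites included indel
columns is generally not reported by studies; our convention excludes them.

## Diversity statistics

* `Hd = n(1 − Σ p_i²)/(n − 1)` with variance
  `V(Hd) = 2/(n(n−1)) · [2(n−2)(Σp_i³ − (Σp_i²)²) + Σp_i² − (Σp_i²)²]`
  (Nei 1987, eq. 8.12). `Hd = 0` iff the sample is monomorphic.
* `k` is computed from the haplotype table with pair weights
  `n_i n_j` — an exact, order-invariant equivalent of the double loop over
  all sequence pairs (tested against that brute force). `Pi = k / L`.
* `Pi ± SD` uses Nei (1987) eq. 10.7, the total (stochastic + sampling)
  variance `V(Pi) = (n+1)Pi/(3(n−1)L) + 2(n²+n+3)Pi²/(9n(n−1))`. This is a
  documented convention: published tables rarely state which variance their
  software reported, and the choice does not affect any other quantity.
* Site classification is column-level: a variable column is
  parsimony-informative iff at least two bases each occur in at least two
  sequences, a singleton otherwise; hence a tri-allelic column with one
  singleton allele and two common alleles counts as informative, and
  `S = singletons + informative` holds by construction.
* The sliding-window scan (default window 200 np, step 25 np — window
  parameters are rarely published, so both are configurable) computes window
  Pi from per-column pair-difference counts
  `C(n,2) − Σ_b C(c_b,2)` in O(L); windows with zero usable sites are
  reported as undefined (NaN), not zero.

## Motif classification

A motif is a set of (np, ref, alt) substitutions. Assignment is top-down:

1. **Clade.** The taurine/indicine split is represented by a clade motif of
   sites fixed between the lineages; a sequence is scored by the fraction of
   those sites carrying the derived (indicine) vs ancestral (taurine)
   allele, and the higher fraction decides the clade.
2. **Haplogroup.** Within the clade, each haplogroup is scored by the
   fraction of its own diagnostic alt alleles present. T3 is modelled as the
   *backbone*: the reference sequence itself is a T3 mitogenome, so T3 has
   no derived motif and is scored by the fraction of reference alleles at
   its siblings' diagnostic sites (this makes the reference score 1 for T3,
   as it must). The best score is accepted at a threshold of 0.8 of
   assessable sites; below threshold the call is `<clade>-novel`. Ties are
   broken by number of assessable sites, then label order, and recorded.
3. **Sub-haplogroup.** A child motif (I1a, T1a) is assigned only when every
   assessable diagnostic allele is present.

Sites where the query has `N`/`-` are dropped from numerator and denominator
and listed as unassessed. The 0.8 threshold operationalizes "unambiguous
motif match with tolerance for occasional back-mutation or missing data";
published analyses typically combine tree placement with motif inspection
and state no numeric rule.

**Novel-lineage detection.** Because a backbone matches any same-clade
sequence at the diagnostic sites, motif scoring alone can never flag a
divergent taurine matriline — precisely the situation in which new
haplogroups are discovered. `detect_novel` therefore also reports samples
whose substitutions relative to the reference, excluding the motifs they
were assigned, number at least 10 (default). The threshold sits well above
the private-mutation load of ordinary animals (~3) and below the 12
diagnostic mutations that characterized the most recently named taurine
haplogroup, T6.

**Packaged motif table.** Only the T6 (12 sites) and I1a (5 sites) positions
are published values. All other positions (clade motif of 233 sites,
T1/T2/T4/T5/T1a/I1/I2) and every ref/alt allele are synthetic stand-ins
generated once for the synthetic reference frame: published sources print
positions only for the new motifs and no alleles at all. Alt alleles default
to transitions of the reference base, since bovine mtDNA diagnostic sites
are predominantly transitions. The `source` column flags provenance
(`published` vs `synthetic`; T5 and T1a are included for completeness from
the broader haplogroup nomenclature). Applying the table to real V00654-
aligned data requires regenerating ref/alt alleles against V00654 — it is
deliberately not silently assumed to transfer.

## Trees and networks

* **NJ**: standard Saitou–Nei agglomeration on the Q-criterion over
  haplotype Hamming distances (raw differences; no substitution-model
  correction, as is usual for within-species mitogenome trees). Q-ties are
  broken toward the first index pair in the current node ordering, making
  the topology deterministic. Negative branch lengths are reported as
  computed. Optional outgroup rooting splits the outgroup's pendant edge at
  its midpoint.
* **Bootstrap**: columns are resampled with replacement (all columns, with
  only variable columns materialized — constant columns cannot change any
  distance), the tree is rebuilt per replicate, and supports are the
  percentage of replicates containing each original bipartition. 1000
  replicates by default, seeded.
* **Median joining**: the ε-relaxed minimum spanning network is defined via
  bottleneck (minimax-path) distances — edge (u,v) is kept iff
  `d(u,v) ≤ minimax(u,v) + ε` — which at ε = 0 equals the union of all
  minimum spanning trees and grows monotonically with ε. Median vectors are
  proposed for every connected triplet as the column-wise majority
  consensus (ties resolved toward the first node in label order); per pass,
  candidates within ε of the cheapest connection cost are added, until
  closure; median vectors of final degree < 3 are pruned. Edges carry the
  np positions at which their endpoints differ.
* **Cluster separation** between two haplotype groups is the largest
  single-edge mutation count on the minimum-weight path between the closest
  cross-group pair — the long boundary branch a network figure shows
  between deeply divergent clusters.

## Synthetic cohorts

The generator emulates a composite tropical beef breed cohort in a 16,338 bp
reference frame. Each animal is: reference + clade motif (indicine animals)
+ haplogroup motif + optional sub-haplogroup motif + private substitutions.

Default study composition (129 animals):

* haplogroup counts {T1:19, T2:5, T3:37, T4:7, T6:2, I1:54, I2:5} — the
  published composition of the cohort this pipeline targets;
* 47 haplotype templates with counts {17, 12, 4×5, 3×20, 1×20}: the top two
  counts and the number of singleton haplotypes are published facts; the
  remaining 25 templates split the remaining 80 animals near-equally (five
  4s, twenty 3s), a deliberately uninformative completion. Templates are
  partitioned across haplogroups so that both marginals hold exactly;
* the I1a star: 28 of the 54 I1 animals (the 17-animal core template plus
  the 11 singleton satellites) carry the five-site I1a motif, giving the
  star-like pattern typical of a past expansion;
* private mutations: each non-core template carries `1 + Poisson(2)`
  private substitutions (mean 3), drawn with a 20× rate multiplier inside
  the control-region hotspot (np 15909–16315) and a 10:1
  transition:transversion ratio; haplogroup cores carry none (star
  topology). Private sites avoid diagnostic positions by default so
  classification ground truth is exact; a collision-allowed mode exists for
  robustness testing. At private rate 0, templates merge into their motif
  classes. Per-sample extra noise is available (`sample_mutation_rate`,
  default 0);
* the clade motif has 233 sites — the published mutational separation of
  the taurine and indicine network clusters — drawn with the same hotspot
  weighting, emulating the control-region enrichment of between-lineage
  divergence;
* an optional indel mode plants 1–2 gap columns inside the hotspot,
  mimicking the few bp of length variation real mitogenomes show; off by
  default since all core statistics exclude such columns anyway.

Under these defaults the cohort reproduces the published headline numbers
closely — Hd 0.965 (published 0.964 ± 0.007), k ≈ 130 (128.074),
Pi ≈ 0.0080 (0.00784), S ≈ 400 (405), 47 haplotypes exactly, 233-mutation
cluster separation exactly — because Hd and H depend only on the planted
frequency skeleton, and k, Pi and S are dominated by the planted clade
divergence and composition. Quantities driven by the fine placement of real
mutations (the exact singleton/informative split, the absolute height of
the D-loop diversity peak) are *not* calibrated and differ from the
published values; tests on them assert structural properties (peak location
inside the hotspot; exact agreement with brute-force oracles) rather than
published numbers.

What the generator does **not** emulate: coalescent genealogy within
haplogroups (no time calibration), recurrent/back mutation, rate variation
beyond the single hotspot, indels beyond the optional gap columns, and
sequencing error. Passing tests therefore demonstrate correctness of the
estimators and algorithms under known truth, not robustness to real-data
artifacts.

## Numerical and degenerate-input choices

* Haplotype labels H1…Hk are assigned by descending count, then first
  occurrence; published haplotype names follow unstated schemes and are not
  reproduced.
* Percentages in frequency tables use half-up rounding to 2 decimals, the
  convention of printed breed tables.
* `Hd` requires n ≥ 2; zero usable sites is an error; a breed with n < 2 in
  the summary table gets NaN statistics rather than a crash.
* Bootstrap on an invariant alignment yields a single haplotype and is
  rejected upstream (one haplotype cannot form a tree); a 3-haplotype star
  has no internal bipartitions and an empty support set.
* Problem sizes used by the shipped drivers and acceptance script: n = 129
  (+31 control), L = 16,338, 1000 bootstrap replicates, 100 scan
  replicates, window 200/step 25. These complete in seconds on a laptop.
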