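# Methods

## Model

A conceptus genome is a per-chromosome multiset of homologs, each tagged
with its parental origin and the gamete that contributed it. Array
observables follow the standard intensity model: at a locus with copy
number *n* and *k* B alleles, the ideal B-allele frequency (BAF) is *k/n*
and the ideal log R ratio (LRR) is *a*·log₂(*n*/2), where *a* ∈ (0, 1] is a
platform attenuation factor (real platforms compress LRR toward 0).
Observed values add independent Gaussian noise; BAF is clipped to [0, 1].
Genotype calls (GType) derive from the true allele multiset — all-A → AA,
all-B → BB, mixed → AB — with a small no-call rate.

The origin test rests on one structural fact: restricted to loci where the
mother is AA, a chromosome carrying a maternal homolog has true BAF at most
(*n*−1)/*n* < 1, while an all-paternal chromosome can reach BAF 1 wherever
all its homologs carry B. Loss of the top BAF band among these "selected"
loci is therefore a deterministic signature of maternal contribution, not a
statistical tendency; noise only blurs the band edges.

## Synthetic-data generator

* **Panel** — exome-array-like: 20,000 autosomal loci apportioned to
  chromosomes by physical length, 800 on X, 100 on Y, 208 mitochondrial.
  Population B-allele frequencies are Uniform(0.05, 0.95); real arrays have
  a skewed frequency spectrum, but band geometry and the selection fraction
  depend only weakly on the spectrum's shape.
* **Parents** — each haplotype allele is an independent Bernoulli draw at
  the locus frequency (no linkage disequilibrium).
* **Meiosis** — crossover count per chromosome ~ Poisson(genetic length),
  crossover positions uniform on the genetic map, starting homolog uniform;
  genetic lengths run 1.0–2.8 Morgans, scaled linearly by physical size,
  with no crossover interference and no obligate chiasma. Y and MT do not
  recombine. STR loci ride on the SNP meiosis: each STR allele follows the
  parental haplotype transmitted at the STR's physical position, so the
  segmental structure of a dispermic mole is consistent across the SNP and
  STR views.
* **Constitutions** — monospermic CHM (one sperm duplicated), dispermic
  CHM (two independent sperm of the same father), biparental diploid,
  diandric and digynic triploids; sex constitutions XX, XY, XYY (a 24,XY
  plus a 23,Y sperm) and XXYY (a duplicated 24,XY sperm). Extra chromosomes
  are injected per autosome as an additional maternal or paternal meiotic
  product; a biparental disomy replaces one paternal homolog with a
  maternal one. The mitochondrial haplotype is always the mother's.
* **Noise defaults** — BAF sd 0.03, LRR sd 0.15, attenuation 1.0, no-call
  rate 0.005: typical of modern genotyping arrays. Y loci in a conceptus
  without a Y render as no-calls with LRR near −3 (hemizygous-absent
  behaviour).
* **Reference cohort** — `data/default_cohort.yaml` ships 31 dispermic-CHM
  constitutions (22 euploid; 8 autosomal-trisomy cases of which one is a
  double trisomy; one XYY; 7 maternal and 3 paternal extra chromosomes;
  3 biparental disomies) with SR/GTN outcomes, the composition the cohort
  statistics are exercised against.

What the generator does **not** emulate: linkage disequilibrium, GC-wave
LRR artifacts, locus-specific noise, mosaicism, segmental (sub-chromosomal)
aneuploidy, STR stutter/mutation and peak heights, crossover interference.
Passing tests therefore demonstrate correctness of the calling logic under
the stated noise model, not robustness to every artifact of real arrays.

## Calling thresholds

| parameter | default | rationale |
|---|---|---|
| band tolerance | ±0.08 BAF | < half the minimal inter-band gap for every copy hypothesis up to 4; ≈2.7σ at BAF sd 0.03 |
| band presence | ≥2% of chromosome loci and ≥10 loci | suppresses noise-tail "bands" on dense chromosomes and tiny-count flukes on sparse ones |
| LRR gain threshold | 0.5·*a*·log₂(1.5) ≈ 0.29 | midpoint between the disomic (0) and trisomic (0.585·*a*) expectations |
| LRR ambiguity margin | 0.05 | two copy hypotheses closer than this in median-LRR distance → ambiguous, never forced |
| minimum called loci | 50 per chromosome | below this, band occupancies are unstable |
| top-band cut | BAF ≥ 0.85 | separates the BB band from ABB at 2/3 by 5σ at sd 0.03 |
| loss threshold | retention statistic < 0.25 | a true maternal homolog drives the statistic to ≈0; all-paternal chromosomes sit at ≥1 |
| minimum selected loci | 30 per chromosome | selection keeps ~⅓ of loci; smaller chromosomes are reported undetermined rather than guessed |

The copy caller demands agreement between the band pattern and the median
LRR: intermediate bands at 1/3 and 2/3 plus an LRR shift call copy 3;
a 0.5 band with LRR near 0 calls copy 2; a chromosome showing only the
homozygous bands {0, 1} (monospermic genomes; identical-homolog trisomies)
is decided by LRR proximity alone, with the ambiguity margin guarding the
borderline. Disagreement yields "ambiguous", which propagates to a
non-confident karyotype rather than a wrong one. Balanced tetraploidy
against diploidy is resolvable only through LRR and is otherwise flagged,
since both show the same BAF bands.

The retention statistic divides the observed fraction of selected loci with
BAF ≥ 0.85 by the all-paternal expectation, computed analytically as the
mean over selected loci of *f*ⁿ (probability all *n* homologs carry B at
population frequency *f*). This treats homologs as independent; the two
sperm of a dispermic mole share a paternal haplotype over half the genome,
which raises true retention above the expectation (statistic ≈ 1.3). The
bias is deliberately conservative: it moves all-paternal chromosomes away
from the loss threshold and cannot create a false maternal call. The CLI's
`origin` command instead uses an empirical expectation (median top-band
fraction over confidently disomic chromosomes) because final-report files
carry no population frequencies. A mirrored diagnostic — maternal-BB loci
and the BAF≈0 band — is available as a cross-check and is never the
decider.

The sex caller uses the Y-locus call rate for Y presence (an absent Y
renders as no-calls), the Y median LRR for one versus two Y copies, and
the X band/LRR logic for the X count.

## Statistics

GTN incidence is stratified by maternal contribution, defined as ≥1
chromosome carrying a maternal homolog (extra maternal chromosome or
biparental disomy). The association test is Fisher's exact test, two-sided
under the probability-ordering convention (sum over tables with the same
margins whose hypergeometric probability does not exceed the observed
one), computed with exact integer arithmetic so probability ties are
handled exactly. A table with an empty margin returns p = 1 and is
flagged.

## Design choices where the procedure was open

* The visual read-outs of the source procedure (band counting on BAF
  plots, LRR histogram inspection, "loss of plots near 1.0") are replaced
  by the numeric thresholds above; values were fixed from the noise model's
  geometry before cohort-level evaluation.
* STR triploidy detection uses allele counts only (≥3 distinct alleles at
  a locus); peak-height dosage is unreliable in electropherograms and is
  not modelled, so diandric versus digynic triploids are deliberately not
  subclassified from STR data.
* A classification attempt requires ≥8 loci typed in both STR profiles;
  below that the result is "indeterminate" with a reason.
* Mitochondrial identity reports alongside the origin caller but never
  overrides it.
* Undetermined beats wrong throughout: sparse chromosomes and
  band/LRR conflicts surface as undetermined/ambiguous flags.

## Problem sizes and determinism

Unit and property tests run on a reduced panel (5,000 autosomal loci, full
chromosome complement) — far above every caller's minimum-locus guard while
keeping whole-cohort simulations fast; whole-cohort recovery checks use the
full default panel across 30 seeds. All randomness flows from one root
seed through hierarchical `SeedSequence` splitting (per case, then per
stage), so cohorts are reproducible byte for byte and cases are
independent.

## Known limitations

* No mosaicism or segmental CNV calling; calls are whole-chromosome.
* Pseudoautosomal regions are not modelled; X in males is exempt from the
  autosomal disomy baseline but PAR loci would leak heterozygosity on real
  data.
* The analytic retention expectation assumes the panel's population
  frequencies apply to the parents at hand; strong ancestry mismatch would
  shift the statistic's baseline (the empirical mode is the fallback).
* Real-platform LRR attenuation must be supplied by the user (`lrr_attenuation`);
  the callers' LRR thresholds scale with it, and heavily compressed
  platforms lose the power to separate balanced tetraploidy from diploidy.
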