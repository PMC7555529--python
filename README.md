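# molekaryo

Molecular karyotyping of androgenetic complete hydatidiform moles (CHMs)
from SNP-array duos and STR profiles.

## The problem

A complete hydatidiform mole is an abnormal conception whose nuclear genome
derives entirely from sperm: either one sperm endoreduplicated (monospermic,
fully homozygous) or two distinct sperm (dispermic, segmentally homozygous).
Dispermic moles are not always clean diploids — some chromosomes turn up in
three copies, and some disomic chromosomes turn out to carry one maternal
homolog inside an otherwise androgenetic genome. Whether such maternal
contribution exists matters clinically: it is a candidate stratifier for the
risk of gestational trophoblastic neoplasia (GTN).

`molekaryo` implements the desk analysis of a mole/mother duo for labs and
methodologists working on molar genetics:

* **STR classification** — forensic-style allele-sharing rules over a
  16-locus panel: a villous sample that shares no allele with the mother at
  ≥1 locus is androgenetic; ≥1 two-allele locus makes it dispermic; a
  three-allele locus raises a triploidy suspicion.
* **Copy-number calling** — per chromosome, from B-allele-frequency (BAF)
  band structure plus the log-R-ratio (LRR) shift. At copy number *n* a
  locus with *k* B alleles clusters at BAF *k/n*, so trisomic chromosomes
  show four bands (0, 1/3, 2/3, 1) and heterozygous disomic ones three
  (0, 0.5, 1); the median LRR (ideally log₂(n/2)) confirms the call.
* **Selected-BAF origin calling** — restrict the mole's BAF to loci where
  the mother's genotype is AA. There the mother can only have transmitted
  an A allele, so any chromosome carrying a maternal homolog cannot reach
  BAF 1: loss of the BAF≈1 band marks a maternal extra homolog on a
  trisomic chromosome, or a biparental disomy on a disomic one.
* **Mitochondrial identity** — mole and mother must match at every
  informative MT locus; a mismatch flags a sample swap.
* **Cohort statistics** — karyotype table, GTN incidence stratified by
  maternal contribution, and an exact two-sided Fisher test
  (probability-ordering convention, integer arithmetic).
* **Synthetic data** — a seeded generator that simulates parents from
  population allele frequencies, gametes through a Poisson crossover model,
  and conceptuses of any supported constitution (monospermic/dispermic CHM,
  biparental diploid, diandric/digynic triploid; XX/XY/XYY/XXYY; injected
  trisomies and biparental disomies), rendered into
  GenomeStudio-final-report-like tables and STR CSVs with configurable
  array noise. Every caller is tested end to end against this generator's
  ground truth.

## Worked example

Simulate the packaged 31-case dispermic-CHM reference cohort and run the
full caller chain:

```python
from molekaryo import (analyze_case, default_cohort_specs, default_panel,
                       simulate_cohort, summarize_cohort)

panel = default_panel()
cases = simulate_cohort(default_cohort_specs(), seed=1, panel=panel)
calls = [analyze_case(case, panel)[0] for case in cases]
report = summarize_cohort(calls)

print(f"cases: {report.n_cases}  euploid: {report.n_euploid}  "
      f"aneuploid: {report.n_aneuploid} ({report.aneuploidy_percent:.0f}%)")
```

prints

```
cases: 31  euploid: 22  aneuploid: 9 (29%)
```

and the per-case calls recover the generating constitutions, e.g. case
HM11 comes back as `47,XY,+13` with a maternal extra chromosome 13 and a
biparental disomic chromosome 6; the GTN stratification is 0/6 in the
maternal-contribution stratum versus 7/25 without.

The same run is available from the shell:

```sh
molekaryo run-all --seed 1 --out out/
```

which writes one duo TSV, one STR CSV and one call JSON per case plus
`report.json`/`report.tsv`, all deterministically for a given seed. The
other subcommands (`simulate`, `classify-str`, `karyotype`, `origin`,
`report`) expose the individual stages.

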