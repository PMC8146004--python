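# ddfetal

Noninvasive fetal blood-group genotyping from duplex droplet digital PCR
(ddPCR) of cell-free DNA in maternal plasma.

## The problem

Hemolytic disease of the fetus and newborn (HDFN) arises when a mother
carries alloantibodies against a red-cell antigen the fetus inherited from
the father — most importantly RhD, and in Central European populations
also RhC/c, RhE/e and Kell (K/k). Because a few percent of the cell-free
DNA in maternal plasma is fetal, the fetal genotype at these loci can be
read noninvasively: partition the plasma DNA into ~10⁴ nanoliter droplets,
amplify a duplex TaqMan assay in each, and count droplets positive per
fluorescence channel (FAM/blue, HEX/green).

The key design constraint is that the mother must be **homozygous** at the
assay locus. Every droplet positive for the allele she lacks (a
*fetus-specific positive*, FSP) can then only come from fetal DNA — or
from the false-positive background, which is why a no-template control
(NTC) gates every run. For RhD-negative mothers, who almost always carry a
whole-gene *RHD* deletion, the assay pairs *RHD* exon 7 (FAM) with a
β-globin total-DNA control (HEX).

`ddfetal` implements the full analysis: amplitude thresholding, Poisson
quantification, the cffDNA-fraction statistic, and droplet-count decision
rules — plus a partitioning simulator used to validate all of it.

## The statistic and the decision rules

With a homozygous mother, a detectable fetus is necessarily heterozygous,
so the mother contributes 2 copies of her allele per genome and the fetus
1 copy per channel. Writing MSP for maternal-specific positives, the
fetal fraction (fetal/maternal genome-equivalent ratio) is

```
FF = FSP / ((MSP − FSP) / 2)
```

under the one-molecule-per-droplet reading valid at low occupancy. Above
~5% positive droplets the pipeline switches to Poisson-corrected molecule
numbers, n·λ with λ = −ln(1 − k/n); for the RHD assay the β-globin
denominator additionally subtracts the fetal genomes it contains
(maternal genomes = (MSP − 2·FSP)/2). A seeded parametric bootstrap
(Gamma(count + ½) resampling of the two Poisson means) gives a 95%
interval on FF.

Calls are gated by three empirical droplet-count limits:

* **NTC QC** — at most 4 positive droplets per channel in the NTC;
* **calling limit** — the paternal allele is called present only at
  FSP ≥ 5 (below that, with adequate maternal signal, the fetal genotype
  equals the maternal one);
* **repeat zone** — any FSP in [3, 7] flags the well `REPEAT_RECOMMENDED`.

## Worked example

The two wells below are the published per-sample droplet counts of the
maternal *RHcc* group (mother homozygous c/c on the *RHCE* rs676785
assay; FAM counts the maternal c allele, HEX the paternal C):

```python
from ddfetal import ClassifiedCounts, MaternalContext, builtin_registry
from ddfetal.model import FetalGenotypeModel

ctx = MaternalContext(builtin_registry()["RHCE_rs676785"], "c/c")
sample = ClassifiedCounts("maternal_cc_1", 14_000, 379, 44, 0, 13_577)
ntc = ClassifiedCounts("ntc", 15_646, 1, 0, 0, 15_645)

res = FetalGenotypeModel(sample, ntc, ctx).fit()
print(res.summary())
```

```
      Fetal blood-group genotype call (duplex ddPCR)
==========================================================
Well:                   maternal_cc_1
Assay:                  RHCE_rs676785
Maternal genotype:      c/c
Fetus-specific channel: HEX (C)
----------------------------------------------------------
Droplets (total):       14000
FSP:                    44
MSP:                    379
NTC positives:          FAM 1, HEX 0 (limit 4)
----------------------------------------------------------
Fetal genotype call:    C/c
Status:                 CONCLUSIVE
Fetal fraction:         26%  (95% CI 18.7%-37.3%)
QC flags:               none
Thresholds:             NTC<=4, FSP>=5, repeat [3, 7], MSP>=200
==========================================================
```

44 fetus-specific C droplets against 379 maternal c droplets give
FF = 44/((379 − 44)/2) = 26%: a heterozygous *RHCc* fetus in a plasma
sample whose cfDNA is about one-quarter fetal. The same counts yield the
maternal-allele occupancy λ = 0.0274 molecules/droplet, i.e. 32.3
copies/µL via `res.concentration("MSP")`. The second published well
(FSP 54, MSP 517) gives 23%.

The same pipeline runs from raw per-droplet amplitude exports
(`FetalGenotypeModel.from_amplitudes`, automatic two-cluster thresholds
with manual override) and from the shell:

```
ddfetal ff --fsp 44 --msp 379
ddfetal simulate --assay KEL_rs8176058 --maternal KEL2/KEL2 \
    --fetal KEL1/KEL2 --fetal-fraction 0.12 --seed 5 --out well.csv
ddfetal call --assay KEL_rs8176058 --maternal KEL2/KEL2 \
    --sample well.csv --ntc ntc.csv
ddfetal replay-study
```

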