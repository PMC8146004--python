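# Methods

This note documents the statistical models, defaults and design choices
behind `ddfetal`, and what the simulation-based validation does and does
not demonstrate.

## Analysis model

A duplex ddPCR well partitions plasma cfDNA into `n` droplets
(typically 11,000–18,000) read on two channels, FAM and HEX. The
analysis assumes:

1. **Homozygous mother.** The maternal genotype at the assay locus is
   homozygous; a detectable fetus is therefore heterozygous. Violations
   are rejected at context construction, not downstream.
2. **Channel→allele map.** For SNP assays each channel detects one
   allele; for the RHD presence/absence assay FAM detects *RHD* exon 7
   and HEX carries a β-globin total-DNA control. The registry flags the
   control channel so quantification can treat it as counting total
   (maternal + fetal) genomes.
3. **Poisson partitioning.** Molecules land in droplets independently;
   the count of channel-c molecules per droplet is Poisson(λ_c). The
   fraction of positive droplets p_c estimates λ_c = −ln(1 − p_c),
   and concentration is λ over droplet volume (default 0.85 nL,
   configurable; instrument convention, not a measured value).

## Fetal fraction

Let FSP be fetus-specific positives and MSP maternal-specific positives.
The fetal/maternal genome-equivalent ratio is estimated as

    FF = FSP / ((MSP − FSP) / 2)

because the mother contributes 2 copies of her allele per genome while
the heterozygous fetus contributes 1 copy to each channel. Reported
percent follows the house style: whole percent at ≥10%, one decimal
below.

Three refinements, all exposed as explicit options:

* **Occupancy correction.** The raw-count form assumes one molecule per
  positive droplet, accurate while occupancies are small (the raw and
  Poisson-corrected estimates agree within ~2% below 5% positive
  droplets). The pipeline default (`ff_method="auto"`) therefore uses
  raw counts below 5% occupancy on both channels and Poisson-corrected
  molecule numbers n·λ(count) above, where raw counts understate
  molecules by ~λ/2 relative. `quantify.fetal_fraction` itself defaults
  to the raw form so published count tables replay to the same numbers.
* **Total-DNA reference (RHD).** The β-globin channel counts two copies
  from *every* genome, fetal included, so maternal genomes are
  (MSP − 2·FSP)/2 rather than (MSP − FSP)/2. The caller applies this
  automatically for assays flagged `reference_channel_is_total_dna`;
  without it FF is biased low by a factor 1/(1 + f/2). The plain ratio
  2·FSP/MSP (fetal per *total* genomes, a smaller quantity) is available
  as `reference="total-dna-ratio"` for comparison with reports that
  normalise to total cfDNA.
* **Uncertainty.** FSP and MSP are treated as independent Poisson
  observations; their means are resampled from Gamma(count + ½) — the
  Jeffreys posterior, proper at FSP = 0 — the FF formula is applied to
  each of 4,000 draws, and the 2.5/97.5 percentiles form the 95%
  interval (widened to include the point estimate if needed; lower bound
  pinned to 0 at FSP = 0). The bootstrap is deterministic, seeded from
  the counts unless a `random_state` is given. Count-level simulations
  at the published well's expectations give ~95% coverage; end-to-end
  coverage is reported below.

## Decision rules

Defaults (all configurable per run, always echoed in reports):

| limit | default | meaning |
|---|---|---|
| `ntc_max_false_pos` | 4 | max NTC positives per channel (QC gate) |
| `min_fetal_pos` | 5 | minimum FSP for a paternal-allele call |
| `repeat_halfwidth` | 2 | repeat zone [3, 7] around the calling limit |
| `min_msp` | 200 | minimum maternal-channel positives for any call |

Sequence: NTC QC (per channel — failure voids the well, no call) →
saturation check → maternal-signal adequacy (a *negative* call is only
evidence of absence when enough cfDNA was interrogated; 200 sits just
below the smallest observed maternal-channel count, 239) → FSP versus
the calling limit. FSP ≥ 5 calls the heterozygous genotype and computes
FF; FSP ≤ 4 calls the maternal genotype back. Any FSP in the repeat zone
downgrades the status to `REPEAT_RECOMMENDED` whichever side of the
limit it falls on — the rules never hard-fail a well for being near the
limit, they flag it for repetition. If a user configures a gap between
the NTC ceiling and the calling limit, counts inside the gap are
`INCONCLUSIVE`: no silent calls from an undefined region. Called
genotypes are asserted to share an allele with the mother.

## Classification

Per channel, an exact 1-D two-means split (all ordered split points via
prefix sums) finds the best two-cluster partition of the amplitudes. The
channel is declared bimodal when the split reduces total sum-of-squares
by ≥ 4× (configurable); the cutoff is then the midpoint of the cluster
means. Otherwise — clean NTCs, fetus-specific channels with a handful of
positives — the fallback cutoff is trimmed mean + 7 × trimmed SD (5%
trimming per side), which sits above every droplet of a ~15k-droplet
negative cloud yet far below the positive cloud, so sparse positives are
still counted. Positivity is strictly-greater-than (ties negative —
conservative for fetal calls); manual cutoffs always override and their
provenance is recorded. Double-positive droplets count in both channel
tallies and separately, giving the conservation identity
`n_ch1 + n_ch2 − n_double + n_neg = n_total`.

## Simulator

`simulate_well` draws per-droplet molecule counts Poisson(λ_c)
independently per channel, with

    λ_c = λ_m · (maternal copies on c + f · fetal copies on c)

(β-globin: 2·λ_m·(1 + f)), where λ_m is maternal genome-equivalents per
droplet and f the true fetal/maternal ratio. A droplet is latently
positive if ≥1 molecule survives the per-molecule `detection_dropout`
(default 0), or spuriously with `false_positive_rate` (default 2e-5 per
droplet per channel, bracketing observed NTC rates of ~0.2–0.6 positives
per 15,646 droplets). Amplitudes come from Gaussian clouds (negative
1000 ± 150, positive 8000 ± 400 arbitrary units) with probability 0.01
of uniform "rain" between the cloud means. Published data include no
amplitude statistics, so the clouds are morphology-plausible
placeholders, not fits. Closed-form expected positives per channel
(`expected_counts`) serve as the simulator's analytic oracle.

Defaults emulate the validation-study conditions: 14,000 droplets,
λ_m = 0.035 (≈950 maternal-channel positives), f = 0.10, within the
observed 3.5–26% range. Scenario helpers solve λ_m exactly from a target
maternal-channel count.

**What the simulator does not model:** droplet volume variability,
inter-well drift, amplitude-dependent rain structure, carry-over
contamination, cfDNA fragment-length effects, and any systematic (non-
Poisson) partitioning bias. Passing the recovery tests therefore shows
the *analysis* is correct under the stated stochastic model, not that
the instrument obeys it.

## Validation study sizes and observed behaviour

Sizes were chosen to give tight Monte-Carlo error at interactive
runtimes:

* **Simulator fidelity:** 10 replicate wells of 200,000 droplets per
  occupancy (λ ∈ {0.005, 0.05, 0.2}); per-channel latent positives must
  fall in the 99% binomial band of the closed form in ≥8/10 replicates
  (a single realization misses ~1% of the time by construction).
* **Decision rules:** exhaustive FSP 0–12 against an independent
  enumeration of the post-conditions.
* **End-to-end recovery:** 200 wells per scenario (5 assay/genotype
  configurations, f ~ U(0.035, 0.26), maternal-channel targets spanning
  each group's observed range, fetus positive/negative at random),
  full amplitude pipeline. Observed: 100% call accuracy in the
  adequate-signal regime (f ≥ 0.05, MSP ≥ 300) and ~96% CI coverage of
  the true f among positive calls (the suite accepts 92–98%).
* **Occupancy estimator:** Wilson-based λ interval covers λ = 0.05 at
  14,000 droplets in ≥90/100 seeded replicates.

False-negative risk is concentrated exactly where the repeat zone sits:
with ~300 maternal positives and f = 0.05 the expected FSP is ~7.5, so
single wells can fall below the calling limit by Poisson chance; the
repeat-zone flag, not the point estimate, is the guard there.

## Known limitations

* Group-level summaries of the original cohort (per-group mean fetal
  fractions, overall concordance) cannot be recomputed here because
  per-sample counts were published for only one group; the replay
  command marks group-mean rows as representative wells.
* The automatic threshold is a stand-in for instrument software whose
  algorithm is unpublished; its diagnostics (cluster means, variance
  ratio, bimodality) are exposed so users can audit every cutoff, and
  manual override is first-class.
* The repeat-zone halfwidth (2) is a policy default; the underlying
  guidance is only that results "around" the limit be repeated.
* Fetal-fraction CIs assume independent Poisson counts; they ignore
  threshold placement uncertainty, which is negligible for clean clouds
  but not for assays needing manual cutoffs.
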