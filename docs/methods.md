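# Methods

## The measurement problem

A mosaic somatic variant present in a few percent of brain cells yields a
variant allele frequency (VAF) of 0–7% in bulk DNA — and far less on an
individual SEEG electrode, where only nanogram traces of tissue are
recovered and the electrode tract crosses regions of unequal mutation load.
Both assays in this package are therefore calibrated decision rules against
technical noise, not mere quantifiers: droplet digital PCR (ddPCR) against
spurious mutant-channel droplets, amplicon sequencing against a background
alt-read fraction.

## ddPCR quantification model

A well partitions template into D droplets (default 20,000). Template
molecules are assumed independently and uniformly assigned to droplets, so
per-droplet occupancy on each channel is Poisson. If a fraction f of
droplets is negative on a channel, the maximum-likelihood mean copies per
droplet is λ = −ln f. The estimator is exercised against a brute-force
grid-search maximization of the binomial likelihood in the tests.

Processing rules:

- wells with fewer than 10,000 accepted droplets are discarded
  (`min_accepted`, default 10,000, boundary inclusive);
- the two 2.5 ng split wells of each duplicate are merged by summing
  droplet-class counts (a merged well is a single larger partition
  experiment, so merge-then-estimate equals pooled-count estimation by
  construction);
- the reported VAF is the *mean fractional abundance over duplicates*
  (`scheme="per-duplicate-mean"`, the default); a `pooled` scheme (merge
  everything, estimate once) is provided and agrees within Monte Carlo
  error on balanced duplicates;
- the FAM+ droplet count used for classification is summed over **all**
  retained wells of a sample (up to 4 wells ≈ 10 ng). This choice matters:
  an electrode at VAF 0.4% carries ≈ 12 expected mutant droplets on 10 ng
  but only ≈ 6 per 5 ng duplicate, and only the summed count is reliably
  separable from a limit of detection of 8;
- a channel with zero negative droplets raises a saturation error rather
  than being capped: saturation cannot occur at mosaic VAFs on 2.5 ng and
  always indicates a bad input.

Fractional abundance λ_mut/(λ_mut+λ_wt) is undefined when both channels are
empty; it is returned as NaN with a flag, never silently zeroed.

## Limit of blank / limit of detection

With Λ_FP the mean FAM+ count over negative controls processed exactly like
the samples (the scheme tag on both tables enforces this):

    LOB = Λ_FP + 1.645·√Λ_FP + 0.8
    LOD = (1.645 + √(1.645² + 4·LOB))² / 4,  rounded up to an integer

1.645 is the one-sided 95% normal quantile; 0.8 is a low-count continuity
correction. The LOB approximates the 95th percentile of the blank count
distribution; the LOD is the smallest mean count whose distribution exceeds
the LOB with 95% probability (solving LOD − 1.645·√LOD = LOB for √LOD).
Numerical choices, each switchable:

- the ceiling is applied to the LOD only. Rounding the LOB first would give
  LOD 9 instead of 8 at Λ_FP ≈ 0.8, inconsistent with the operating point
  this framework is designed to reproduce;
- "above the LOD" is read as strictly greater (`strict=True`);
- for Λ_FP ≤ 0.05 the construction is out of its validity regime; calls are
  returned as `not-evaluable` instead of being made silently.

At the default generator operating point (per-droplet false-positive
probability 10⁻⁵, 4 × 20,000 droplets per control) Λ_FP is Poisson-mean 0.8,
and the modal integer LOD over replicate control panels is 8, with 7 and 9
as neighboring outcomes when the 20-control mean lands below ≈ 0.72 or
above ≈ 0.95. The implied control-sample false-positive VAF (≈ 0.8 spurious
droplets against ≈ 3,000 occupied droplets ≈ 0.03%) sits inside the 0–0.06%
range the framework is meant for.

## Amplicon positivity test

Negative controls (default 10) give per-control VAFs at the target site;
their mean m_c, standard deviation s_c and range form the noise model. A
sample with a single observed VAF v is tested with the single-observation
prediction-interval t-statistic

    t = (v − m_c) / (s_c · √(1 + 1/n_c)),   df = n_c − 1,

two-sided p, and called positive only if **both** v > m_c and p < α
(default 0.05): a significantly *low* VAF is not a variant call. A
two-sample pooled-variance t-test (`vaf_t_test`) is available when
replicate measurements exist. If the controls are degenerate (s_c = 0) the
call falls back to strict exceedance of the maximum control VAF, flagged.

Known limitation: at ~4000× coverage and 0.19% error VAF the null alt
count has mean ≈ 7.6 and is right-skewed, so the normal-theory prediction
interval is mildly anticonservative — the realized null positive rate is
≈ 3.5% rather than the nominal α/2 = 2.5% (a matched-Gaussian simulation
recovers 2.4%, isolating skewness as the cause). The property tests
therefore measure the rate with a Monte Carlo standard error computed at
the control-panel level, which is the correct clustering for nulls sharing
a panel. An exact count-based test (e.g. binomial against a pooled error
rate) would remove the skew effect but would no longer be the
prediction-interval construction implemented here.

## Synthetic data generator

The generator is the package's study model, not a test convenience. What it
emulates, with defaults chosen as the study conditions:

| parameter | default | meaning |
|---|---|---|
| `copies_per_ng` | 303 | haploid genome copies per ng (3.3 pg/haploid genome) |
| `droplets_per_well` | 20,000 | accepted droplets per well |
| `dna_ng_per_well` | 2.5 ng | 5 ng per measurement split over two wells |
| `duplicates` × `wells_per_measurement` | 2 × 2 | the duplicate/split layout, 4 wells ≈ 10 ng per sample |
| `droplet_fp_prob` | 10⁻⁵ | per-droplet spurious FAM+ probability (Bernoulli per droplet, since the observable is a droplet count); yields Λ_FP ≈ 0.8 per 80,000-droplet control and hence LOD 8 |
| `amplicon_coverage` | 4000 | Poisson mean site coverage |
| `amplicon_error_vaf` | 0.0019 | technical alt-read fraction (mean 0.19%, range ≈ 0.11–0.28% across controls) |
| `n_negative_controls_ddpcr` / `_amplicon` | 20 / 10 | blood-DNA control panel sizes |

Droplets are generated pre-classified into the four FAM/HEX classes; no
fluorescence amplitudes, droplet rain or thresholding are simulated, and no
read-level amplicon data (site-level allele counts only). Amplicon noise
and signal combine as max(true_vaf, error_vaf) by default — the fixture's
true VAFs are *observed* values that already contain background — with an
additive mode behind `amplicon_additive_noise` for sensitivity analyses.
Per-well template is the deterministic rounding of ng × copies/ng with a
binomial draw of mutant copies; coverage is Poisson because only a mean
coverage is meaningful for the emulated protocol.

The built-in fixture encodes the three-patient electrode layout: per
electrode the zone (EZN/PZN/NIN), MRI-lesion status, thermocoagulation
status, DNA yield and true VAF (detected VAFs for the three positive SE1
electrodes, 1.1/0.8/0.4%, and the SE3 CA electrode, 0.39%; zero for
non-detections). SE2's electrodes are simulated mutation-free: its tissue
variant sat at 0.25% VAF, below the per-electrode detection floor, and the
true per-electrode mosaicism is unknowable. The low-DNA electrodes excluded
from testing (4 of 13 for SE1, 2 of 14 for SE2) have no published
per-electrode values; their metadata rows are synthetic stand-ins
consistent with the exclusion rule and are labelled as such in the source.
The four SE1 tissue blocks carry the 7% → 5% → 2% → 0.5% VAF gradient.

What passing tests consequently do *not* show about real data: real droplet
classification error (rain/threshold misassignment), PCR efficiency
differences between alleles, UMI-less sequencing error clustering, and
between-electrode DNA quality variation are all outside the generator; the
pipeline's operating characteristics on real electrodes depend on those.

## Electrode integration

Eligibility: ddPCR electrodes with < 20 ng total DNA are excluded (exactly
20 ng is eligible); amplicon electrodes are retained regardless of yield
(inputs down to ~1 ng were sequenced in the emulated protocol) with a
`low-input` flag below 10 ng. Excluded electrodes carry no call by
contract. Thermocoagulation status is carried as metadata and affects no
computation — an invariance asserted by toggling the flag and diffing
outputs. Zone is a single label per electrode even though real electrodes
traverse several zones; this mirrors the tabular data model and is the main
data-model simplification (the "dilution effect" across contacts is not
modelled). Zone positivity is summarized descriptively; no enrichment
statistic is computed because none is part of the emulated analysis.

The tissue gradient report sorts blocks by VAF, flags strict monotonicity
(ties break it, stable label order) and reports the max/min ratio (omitted
when the minimum is zero).

## Problem sizes and determinism

All stochastic tests are seeded (hypothesis runs derandomized) and sized to
keep the full suite around a minute on one CPU: operating-characteristic
estimates use 2,000 null samples (ddPCR and amplicon), parameter-recovery
grids 300–500 replicates per VAF, and the headline reproductions 200
replicates each, at which size the modal outcomes (LOD 8; 3 of 9 SE1
electrodes positive; 1 of 11 SE3 electrodes positive) are stable across
seeds. Recovery/bias tests run with technical false positives switched off
so they measure the estimator, not the noise floor — the noise floor is
the LOB/LOD machinery's job. `scripts/acceptance.py` recomputes the modal
LOD and the modal SE1 positive count from scratch with the same replicate
count, deriving all randomness from `--seed`.
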