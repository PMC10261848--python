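# seegmosaic

Detection of low-level mosaic mTOR-pathway variants from trace brain tissue
on individual stereo-EEG (SEEG) electrodes.

In focal cortical dysplasia type II (FCDII), drug-resistant epilepsy is
frequently caused by postzygotic (somatic) variants in mTOR-pathway genes
(*AKT3*, *DEPDC5*, *MTOR*, ...) present in only a few percent of brain
cells. Genetic diagnosis normally requires resected brain tissue. During
presurgical SEEG evaluation, however, trace tissue adheres to the explanted
depth electrodes — enough DNA to test each electrode individually for a
known somatic variant and relate the mutation load to the
electrophysiologically defined networks (epileptogenic zone network EZN,
propagation zone network PZN, non-involved network NIN).

`seegmosaic` is a tested reusable pipeline for that analysis, aimed at
epilepsy-genetics labs and methods developers. It implements:

- **ddPCR Poisson quantification** — droplet digital PCR partitions ~5 ng
  of DNA over two 20,000-droplet wells, run in duplicate. With the mutant
  (FAM) and wild-type (HEX) channel concentrations estimated from the
  channel-negative droplet fractions, λ = −ln(n_neg/n_total), the variant
  allele frequency (VAF) is the fractional abundance
  λ_mut / (λ_mut + λ_wt), reported as the mean over duplicates. Wells with
  < 10,000 accepted droplets are discarded; split wells are merged by
  summing droplet-class counts.
- **Limit-of-blank / limit-of-detection calling** — from the mean
  false-positive FAM+ droplet count Λ_FP of mutation-negative controls,
  LOB = Λ_FP + 1.645·√Λ_FP + 0.8 and
  LOD = ⌈(1.645 + √(1.645² + 4·LOB))² / 4⌉. A sample is mutation-positive
  when its FAM+ droplet count, summed over all retained wells, is strictly
  above the LOD. The rule applies for Λ_FP > 0.05; below that, calls are
  suppressed as not-evaluable.
- **Amplicon positivity test** — for variants without a ddPCR assay, deep
  targeted amplicon sequencing (~4000× at the known site) gives per-site
  allele counts. A sample VAF is called positive when it exceeds the mean
  technical false-positive VAF of negative controls and a single-observation
  prediction-interval t-test, t = (v − m_c) / (s_c·√(1 + 1/n_c)) with
  df = n_c − 1, is significant at α = 0.05.
- **Electrode integration** — joins calls to electrode metadata, applies
  the < 20 ng DNA-yield eligibility rule (ddPCR only; low-input amplicon
  samples are flagged, not dropped), summarizes positivity per zone and
  MRI-lesion status, and reports the tissue-block mutation gradient.
- **Synthetic data generation** — a seeded generator producing
  droplet-level ddPCR tables, amplicon allele counts and electrode metadata
  with the study's statistical structure, including a built-in fixture of
  the three-patient electrode layout, so the entire pipeline is testable
  without any external data.

## Worked example

Simulate the first and third patients, call both assays, and build the
integrated report:

```sh
seegmosaic simulate --seed 1 --patients SE1,SE3 --outdir sim
seegmosaic ddpcr-call --wells sim/ddpcr_wells.tsv \
    --controls sim/negative_controls_ddpcr.tsv --outdir ddpcr
seegmosaic amplicon-call --counts sim/amplicon_counts.tsv \
    --controls sim/negative_controls_amplicon.tsv --outdir amp
seegmosaic report --electrodes sim/electrodes.tsv --calls ddpcr/calls.tsv \
    --amplicon-calls amp/amplicon_calls.tsv \
    --thresholds ddpcr/thresholds.json --outdir report
```

which prints

```
wrote study tables for SE1,SE3 to sim
LOD=9 (Lambda_FP=1.000); 3 positive sample(s)
noise mean VAF 0.2094% (range 0.1281%-0.2719%); 1 positive sample(s)
4 positive electrode(s) of 20 eligible; report in report
```

The 20 simulated negative controls averaged Λ_FP = 1.0 false-positive
droplets, giving LOB = 3.445 and LOD = 9 for this run. `ddpcr/calls.tsv`
then shows the three epileptogenic-zone electrodes of patient SE1 clearing
that threshold (FAM+ counts 43, 23 and 13 against LOD 9, recovered VAFs
1.42%, 0.76% and 0.43% for true mosaic fractions 1.1%, 0.8% and 0.4%),
while all propagation-zone and non-involved electrodes stay negative and
are rendered `ns` in the Table-2-shaped output:

```
sample_id  fam_pos_count  lod  call      vaf        p_vs_controls
SE1-PI     43             9    positive  0.0141945  7.844e-20
SE1-PS     23             9    positive  0.0075763  1.343e-14
SE1-FA     13             9    positive  0.0042759  5.949e-10
SE1-AS     1              9    negative             0.9994
```

For patient SE3 the amplicon caller estimates a technical false-positive
VAF of 0.21% (range 0.13–0.27%) from 10 negative controls and calls exactly
one electrode — CA, in the propagation zone at the border of the dysplasia —
positive at VAF 0.44% (t = 5.08, p = 0.0007); `report/report.json` totals
4 positive electrodes of 20 eligible, with 3/4 positives in the EZN.

The same analyses are available as library functions
(`seegmosaic.quantify_sample`, `DetectionThresholds.from_controls`,
`classify_sample`, `call_amplicon_variant`, ...); see `docs/methods.md` for
the statistical details and design choices.

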