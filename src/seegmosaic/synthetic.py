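"""Seeded generators for droplet-level ddPCR data, amplicon allele counts and
electrode metadata with the statistical structure the analysis assumes.

The forward model is deliberately simple and matches the assumptions of the
downstream Poisson estimator:

* ddPCR wells: each template molecule lands in a uniformly random droplet
  (per-droplet occupancy is then Poisson with mean copies/droplets); a
  droplet is HEX+ iff it holds >= 1 wild-type copy and FAM+ iff it holds
  >= 1 mutant copy or a spurious false-positive event fires (independent
  Bernoulli per droplet). Droplets come back pre-classified into the four
  FAM/HEX classes; no fluorescence amplitudes are simulated.
* amplicon samples: site coverage is Poisson around the mean coverage; alt
  reads are binomial. In the default mode the success probability is
  max(true_vaf, error_vaf), emulating *observed* VAFs that already contain
  the technical background; an additive mode (true_vaf + error_vaf) is
  available behind a config switch.
* the study fixture encodes the three-patient electrode layout (ids, zones,
  MRI-lesion and thermocoagulation status, DNA yields, per-electrode true
  VAFs) and the four-block tissue VAF gradient of the first patient.

All generators take a ``numpy.random.Generator``; identical seed + config
give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .amplicon import Locus, SiteAlleleCounts
from .ddpcr import DropletWellCounts

__all__ = [
    "GeneratorConfig",
    "ElectrodeSpec",
    "StudyFixture",
    "AKT3_E17K",
    "DEPDC5_R843X",
    "simulate_ddpcr_well",
    "simulate_electrode_sample",
    "simulate_negative_control_ddpcr",
    "simulate_amplicon_sample",
    "make_study_fixture",
]

#: AKT3 p.E17K as a transcript-relative site (c.49G>A)
AKT3_E17K = Locus("AKT3", 49, "G", "A")
#: DEPDC5 p.R843* as a transcript-relative site (c.2527C>T)
DEPDC5_R843X = Locus("DEPDC5", 2527, "C", "T")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-level simulation constants.

    ``copies_per_ng`` converts DNA mass to haploid genome copies (3.3 pg
    per haploid genome -> 303 copies/ng). ``droplet_fp_prob`` is the
    per-droplet probability of a spurious FAM+ event; the default 1e-5
    gives a 4-well (80,000-droplet) negative control a mean false-positive
    count of 0.8, which puts the integer limit of detection at 8 droplets.
    """

    copies_per_ng: float = 303.0
    droplets_per_well: int = 20_000
    droplet_fp_prob: float = 1e-5
    dna_ng_per_well: float = 2.5
    wells_per_measurement: int = 2
    duplicates: int = 2
    amplicon_coverage: float = 4000.0
    amplicon_error_vaf: float = 0.0019
    amplicon_additive_noise: bool = False
    n_negative_controls_ddpcr: int = 20
    n_negative_controls_amplicon: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("droplets_per_well", "wells_per_measurement", "duplicates",
                     "n_negative_controls_ddpcr", "n_negative_controls_amplicon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.copies_per_ng <= 0 or self.amplicon_coverage <= 0:
            raise ValueError("copies_per_ng and amplicon_coverage must be > 0")
        if self.dna_ng_per_well < 0:
            raise ValueError("dna_ng_per_well must be >= 0")
        for name in ("droplet_fp_prob", "amplicon_error_vaf"):
            p = getattr(self, name)
            if not 0.0 <= p < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")

    @property
    def copies_per_well(self) -> int:
        return int(round(self.dna_ng_per_well * self.copies_per_ng))

    @property
    def wells_per_sample(self) -> int:
        return self.duplicates * self.wells_per_measurement


@dataclass(frozen=True)
class ElectrodeSpec:
    """One SEEG electrode: metadata plus the true mosaic VAF used to simulate it."""

    electrode_id: str
    patient_id: str
    zone: str  # EZN | PZN | NIN
    in_mri_lesion: bool
    thermocoagulated: bool
    dna_ng: float
    true_vaf: float
    assay: str = "ddpcr"  # ddpcr | amplicon

    def __post_init__(self) -> None:
        if self.zone not in ("EZN", "PZN", "NIN"):
            raise ValueError(f"zone must be EZN/PZN/NIN, got {self.zone!r}")
        if not 0.0 <= self.true_vaf <= 1.0:
            raise ValueError("true_vaf must be in [0, 1]")
        if self.dna_ng < 0:
            raise ValueError("dna_ng must be >= 0")
        if self.assay not in ("ddpcr", "amplicon"):
            raise ValueError(f"assay must be ddpcr/amplicon, got {self.assay!r}")

    @property
    def sample_id(self) -> str:
        return f"{self.patient_id}-{self.electrode_id}"


@dataclass
class StudyFixture:
    """Electrode layout, tissue-block VAFs and generator config for a study."""

    electrodes: list[ElectrodeSpec]
    tissue_blocks: dict[str, float] = field(default_factory=dict)
    config: GeneratorConfig = field(default_factory=GeneratorConfig)

    def __post_init__(self) -> None:
        seen = set()
        for e in self.electrodes:
            key = (e.patient_id, e.electrode_id)
            if key in seen:
                raise ValueError(f"duplicate electrode {key}")
            seen.add(key)

    def patient(self, patient_id: str) -> list[ElectrodeSpec]:
        return [e for e in self.electrodes if e.patient_id == patient_id]


def simulate_ddpcr_well(
    n_wt_copies: int,
    n_mut_copies: int,
    config: GeneratorConfig,
    rng: np.random.Generator,
    sample_id: str = "sample",
    well_id: str = "w1",
    replicate: int = 1,
) -> DropletWellCounts:
    """Partition template molecules over droplets and classify each droplet.

    Every molecule is dropped into a uniformly random droplet; spurious FAM+
    events fire independently per droplet with probability
    ``config.droplet_fp_prob``. All droplets are accepted (droplet-loss QC
    is exercised by feeding in wells with low accepted counts directly).
    """
    if n_wt_copies < 0 or n_mut_copies < 0:
        raise ValueError("copy numbers must be >= 0")
    d = config.droplets_per_well
    wt_pos = np.zeros(d, dtype=bool)
    if n_wt_copies:
        wt_pos = np.bincount(rng.integers(0, d, size=n_wt_copies), minlength=d) > 0
    fam_pos = np.zeros(d, dtype=bool)
    if n_mut_copies:
        fam_pos = np.bincount(rng.integers(0, d, size=n_mut_copies), minlength=d) > 0
    if config.droplet_fp_prob > 0:
        fam_pos |= rng.random(d) < config.droplet_fp_prob
    return DropletWellCounts(
        sample_id=sample_id,
        well_id=well_id,
        accepted=d,
        fam_only=int(np.sum(fam_pos & ~wt_pos)),
        hex_only=int(np.sum(wt_pos & ~fam_pos)),
        double_pos=int(np.sum(fam_pos & wt_pos)),
        double_neg=int(np.sum(~fam_pos & ~wt_pos)),
        replicate=replicate,
    )


def _simulate_sample_wells(
    sample_id: str,
    true_vaf: float,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> list[DropletWellCounts]:
    wells = []
    for rep in range(1, config.duplicates + 1):
        for w in range(1, config.wells_per_measurement + 1):
            total = config.copies_per_well
            n_mut = int(rng.binomial(total, true_vaf)) if true_vaf > 0 else 0
            wells.append(
                simulate_ddpcr_well(
                    total - n_mut,
                    n_mut,
                    config,
                    rng,
                    sample_id=sample_id,
                    well_id=f"r{rep}w{w}",
                    replicate=rep,
                )
            )
    return wells


def simulate_electrode_sample(
    spec: ElectrodeSpec, config: GeneratorConfig, rng: np.random.Generator
) -> list[DropletWellCounts]:
    """Simulate the full ddPCR layout for one electrode.

    duplicates x wells_per_measurement wells; per well the template is
    ``dna_ng_per_well * copies_per_ng`` copies, of which a binomial draw at
    the electrode's true VAF is mutant.
    """
    return _simulate_sample_wells(spec.sample_id, spec.true_vaf, config, rng)


def simulate_negative_control_ddpcr(
    config: GeneratorConfig, rng: np.random.Generator, sample_id: str = "NC"
) -> list[DropletWellCounts]:
    """A mutation-negative control processed with the sample well layout."""
    return _simulate_sample_wells(sample_id, 0.0, config, rng)


def simulate_amplicon_sample(
    true_vaf: float,
    config: GeneratorConfig,
    rng: np.random.Generator,
    sample_id: str = "sample",
    locus: Locus = DEPDC5_R843X,
) -> SiteAlleleCounts:
    """Site-level allele counts for one amplicon-sequenced sample."""
    if not 0.0 <= true_vaf <= 1.0:
        raise ValueError("true_vaf must be in [0, 1]")
    coverage = int(rng.poisson(config.amplicon_coverage))
    if config.amplicon_additive_noise:
        p = min(true_vaf + config.amplicon_error_vaf, 1.0)
    else:
        p = max(true_vaf, config.amplicon_error_vaf)
    alt = int(rng.binomial(coverage, p)) if coverage and p > 0 else 0
    return SiteAlleleCounts(
        sample_id=sample_id,
        locus=locus,
        ref_count=coverage - alt,
        alt_count=alt,
        other_count=0,
    )


# --- three-patient study fixture ------------------------------------------
#
# Per-electrode rows: (electrode_id, dna_ng, zone, in_mri_lesion,
# thermocoagulated, true_vaf). The assayed electrodes carry the published
# per-electrode DNA yields and detected VAFs (non-detections -> true VAF 0).
# The low-DNA electrodes excluded from testing have no published per-electrode
# values; their rows are synthetic stand-ins consistent with the exclusion
# rule (< 20 ng for ddPCR patients).

_SE1_ASSAYED = [
    ("PI", 66.0, "EZN", True, True, 0.011),
    ("PS", 208.0, "EZN", True, True, 0.008),
    ("FA", 91.0, "EZN", True, True, 0.004),
    ("AS", 188.0, "PZN", True, True, 0.0),
    ("IA", 127.0, "PZN", True, True, 0.0),
    ("OM", 501.0, "PZN", True, True, 0.0),
    ("MS", 104.0, "PZN", True, True, 0.0),
    ("PA", 85.0, "PZN", True, True, 0.0),
    ("TS", 240.0, "NIN", False, False, 0.0),
]
_SE1_EXCLUDED = [  # synthetic low-DNA rows
    ("FS", 12.0, "PZN", True, False, 0.0),
    ("OP", 9.0, "PZN", False, False, 0.0),
    ("PP", 15.0, "PZN", False, False, 0.0),
    ("TA", 6.0, "NIN", False, False, 0.0),
]

# SE2: the tissue variant sat at 0.25% VAF and was not detected on any
# electrode; electrodes are simulated mutation-free (the true per-electrode
# mosaicism is unknowable). DNA yields are synthetic within the published
# 1-44 ng range, with the two excluded electrodes below the eligibility cut.
_SE2_ASSAYED = [
    ("FS", 44.0, "EZN", True, True, 0.0),
    ("MS", 38.0, "EZN", True, True, 0.0),
    ("PA", 31.0, "EZN", True, True, 0.0),
    ("FA", 25.0, "PZN", True, False, 0.0),
    ("OM", 29.0, "PZN", False, False, 0.0),
    ("AS", 24.0, "NIN", False, False, 0.0),
    ("BL", 27.0, "NIN", False, False, 0.0),
    ("BM", 22.0, "NIN", False, False, 0.0),
    ("CA", 26.0, "NIN", False, False, 0.0),
    ("FI", 21.0, "NIN", False, False, 0.0),
    ("OP", 23.0, "NIN", False, False, 0.0),
    ("PI", 20.0, "NIN", False, False, 0.0),
]
_SE2_EXCLUDED = [  # synthetic low-DNA rows
    ("LS", 12.0, "NIN", False, False, 0.0),
    ("PP", 1.0, "NIN", False, False, 0.0),
]

_SE3_ASSAYED = [
    ("LP", 7.4, "EZN", True, False, 0.0),
    ("FS", 113.0, "EZN", True, False, 0.0),
    ("CA", 105.0, "PZN", False, False, 0.0039),
    ("OM", 87.0, "PZN", False, False, 0.0),
    ("FA", 245.0, "PZN", True, False, 0.0),
    ("PS", 17.0, "PZN", False, False, 0.0),
    ("FI", 7.2, "NIN", False, False, 0.0),
    ("FB", 157.0, "NIN", False, False, 0.0),
    ("BL", 62.0, "NIN", False, False, 0.0),
    ("BM", 5.4, "NIN", False, False, 0.0),
    ("FM", 33.0, "NIN", False, False, 0.0),
]

_PATIENT_ROWS = {
    "SE1": (_SE1_ASSAYED, _SE1_EXCLUDED, "ddpcr"),
    "SE2": (_SE2_ASSAYED, _SE2_EXCLUDED, "ddpcr"),
    "SE3": (_SE3_ASSAYED, [], "amplicon"),
}

#: tissue-block VAF gradient of the first patient (fronto-lateral cortex ->
#: premotor cortex -> periventricular region -> adjacent temporal cortex)
SE1_TISSUE_BLOCKS = {
    "block1-frontolateral": 0.07,
    "block2-premotor": 0.05,
    "block3-periventricular": 0.02,
    "block4-temporal": 0.005,
}


def make_study_fixture(
    which: Iterable[str] = ("SE1", "SE2", "SE3"),
    include_low_dna: bool = False,
    config: GeneratorConfig | None = None,
) -> StudyFixture:
    """Electrode layout of the three-patient study.

    ``which`` selects a patient subset. By default only the assayed
    electrodes are returned (9 for SE1, 12 for SE2, 11 for SE3);
    ``include_low_dna=True`` adds the electrodes that were excluded for low
    DNA yield (13 and 14 implanted electrodes for SE1 and SE2), so the
    eligibility filter can be exercised end to end.
    """
    patients = list(which)
    unknown = [p for p in patients if p not in _PATIENT_ROWS]
    if unknown:
        raise ValueError(f"unknown patient label(s): {unknown}; expected SE1/SE2/SE3")
    electrodes = []
    for pid in patients:
        assayed, excluded, assay = _PATIENT_ROWS[pid]
        rows = assayed + (excluded if include_low_dna else [])
        for eid, ng, zone, lesion, rftc, vaf in rows:
            electrodes.append(
                ElectrodeSpec(
                    electrode_id=eid,
                    patient_id=pid,
                    zone=zone,
                    in_mri_lesion=lesion,
                    thermocoagulated=rftc,
                    dna_ng=ng,
                    true_vaf=vaf,
                    assay=assay,
                )
            )
    blocks = dict(SE1_TISSUE_BLOCKS) if "SE1" in patients else {}
    return StudyFixture(
        electrodes=electrodes,
        tissue_blocks=blocks,
        config=config if config is not None else GeneratorConfig(),
    )
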