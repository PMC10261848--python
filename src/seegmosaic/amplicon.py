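"""Targeted-amplicon positivity test for a known somatic SNV.

When no ddPCR assay exists for a variant, deep amplicon sequencing
(~4000x at the target site) provides per-site allele counts. Sequencing
artifacts produce a nonzero background alt-read fraction even in
mutation-negative DNA, so a sample VAF is called positive only when it
significantly exceeds the technical false-positive VAF distribution
estimated from negative controls, with a directionality gate (a
significantly *low* VAF is not a variant call).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .limits import single_observation_t_test

__all__ = [
    "Locus",
    "SiteAlleleCounts",
    "AmpliconNoiseModel",
    "AmpliconCall",
    "compute_site_vaf",
    "fit_noise_model",
    "call_amplicon_variant",
    "write_vcf",
]


@dataclass(frozen=True)
class Locus:
    """A biallelic SNV site: contig, 1-based position, ref and alt alleles."""

    contig: str
    pos: int
    ref: str
    alt: str

    def __str__(self) -> str:
        return f"{self.contig}:{self.pos}{self.ref}>{self.alt}"


@dataclass
class SiteAlleleCounts:
    """Read counts at the target site for one sample.

    ``other_count`` holds reads matching neither allele; they are excluded
    from the VAF denominator.
    """

    sample_id: str
    locus: Locus
    ref_count: int
    alt_count: int
    other_count: int = 0

    def __post_init__(self) -> None:
        if min(self.ref_count, self.alt_count, self.other_count) < 0:
            raise ValueError("allele counts must be >= 0")

    @property
    def coverage(self) -> int:
        return self.ref_count + self.alt_count + self.other_count


@dataclass
class AmpliconNoiseModel:
    """Technical false-positive VAF distribution from negative controls."""

    control_vafs: list[float]
    mean_fp_vaf: float
    min_vaf: float
    max_vaf: float

    @property
    def sd(self) -> float:
        return float(np.std(self.control_vafs, ddof=1))

    @property
    def n_controls(self) -> int:
        return len(self.control_vafs)


@dataclass
class AmpliconCall:
    sample_id: str
    coverage: int
    vaf: float
    t: float
    p: float
    call: str  # positive | negative | not-evaluable
    flags: list[str] = field(default_factory=list)


def compute_site_vaf(counts: SiteAlleleCounts) -> float:
    """VAF = alt / (alt + ref); ``other`` reads are excluded (and logged)."""
    informative = counts.ref_count + counts.alt_count
    if informative == 0:
        return math.nan
    if counts.other_count > 0:
        import logging

        logging.getLogger(__name__).info(
            "sample %s: excluding %d non-ref/non-alt reads at %s",
            counts.sample_id,
            counts.other_count,
            counts.locus,
        )
    return counts.alt_count / informative


def fit_noise_model(controls: Sequence[SiteAlleleCounts]) -> AmpliconNoiseModel:
    """Per-control VAFs and their mean/range from mutation-negative controls."""
    if len(controls) < 2:
        raise ValueError("need >= 2 negative controls to fit the noise model")
    vafs = [compute_site_vaf(c) for c in controls]
    if any(math.isnan(v) for v in vafs):
        raise ValueError("a negative control has zero informative coverage")
    return AmpliconNoiseModel(
        control_vafs=vafs,
        mean_fp_vaf=float(np.mean(vafs)),
        min_vaf=min(vafs),
        max_vaf=max(vafs),
    )


def call_amplicon_variant(
    sample: SiteAlleleCounts,
    noise: AmpliconNoiseModel,
    alpha: float = 0.05,
) -> AmpliconCall:
    """Call the known variant in one sample against the noise model.

    Single-observation prediction-interval t-test of the sample VAF against
    the control VAFs (df = n_controls - 1, two-sided p); positive requires
    both vaf > mean control VAF and p < alpha. If the controls are
    degenerate (zero spread) the call falls back to strict exceedance of the
    maximum control VAF, flagged.
    """
    vaf = compute_site_vaf(sample)
    if math.isnan(vaf):
        return AmpliconCall(sample.sample_id, 0, math.nan, math.nan, math.nan,
                            "not-evaluable", flags=["zero-coverage"])
    if noise.sd == 0:
        positive = vaf > noise.max_vaf
        return AmpliconCall(
            sample.sample_id, sample.coverage, vaf, math.nan, math.nan,
            "positive" if positive else "negative",
            flags=["degenerate-noise-model"],
        )
    t, p = single_observation_t_test(vaf, noise.control_vafs)
    positive = (vaf > noise.mean_fp_vaf) and (p < alpha)
    return AmpliconCall(sample.sample_id, sample.coverage, vaf, t, p,
                        "positive" if positive else "negative")


def write_vcf(
    calls: Sequence[AmpliconCall],
    samples: Sequence[SiteAlleleCounts],
    path: str,
    reference: str = "synthetic",
) -> None:
    """Emit the site as a minimal VCF 4.2 record, one sample column per electrode.

    AF carries each sample's observed VAF (FORMAT) and the mean VAF of
    positive samples (INFO); AD carries ref,alt depths. FILTER is PASS when
    at least one sample is called positive.
    """
    if not samples:
        raise ValueError("no samples to write")
    locus = samples[0].locus
    by_id = {c.sample_id: c for c in calls}
    pos_vafs = [c.vaf for c in calls if c.call == "positive"]
    info = f"AF={np.mean(pos_vafs):.6f};NS={len(samples)}" if pos_vafs else f"NS={len(samples)}"
    filt = "PASS" if pos_vafs else "no_sample_above_noise"
    lines = [
        "##fileformat=VCFv4.2",
        f"##reference={reference}",
        f"##contig=<ID={locus.contig}>",
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Mean VAF of mutation-positive samples">',
        '##INFO=<ID=NS,Number=1,Type=Integer,Description="Number of samples">',
        '##FILTER=<ID=no_sample_above_noise,Description="No sample VAF significantly above technical noise">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype (./1 mosaic positive, 0/0 negative)">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Ref,alt read depths">',
        '##FORMAT=<ID=AF,Number=A,Type=Float,Description="Observed variant allele frequency">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(s.sample_id for s in samples),
    ]
    fields = []
    for s in samples:
        call = by_id.get(s.sample_id)
        vaf = compute_site_vaf(s)
        gt = "./1" if call is not None and call.call == "positive" else "0/0"
        af = "." if math.isnan(vaf) else f"{vaf:.6f}"
        fields.append(f"{gt}:{s.ref_count},{s.alt_count}:{af}")
    lines.append(
        f"{locus.contig}\t{locus.pos}\t.\t{locus.ref}\t{locus.alt}\t.\t{filt}\t{info}\tGT:AD:AF\t"
        + "\t".join(fields)
    )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
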