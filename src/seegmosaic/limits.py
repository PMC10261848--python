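"""Limit-of-blank / limit-of-detection decision rule for rare-mutation ddPCR.

Technical false positives (spurious FAM+ droplets in mutation-negative DNA)
set the floor for calling a low-level mosaic variant. Let Lambda_FP be the
mean FAM+ droplet count over negative-control samples processed exactly like
the test samples. Then

    LOB = Lambda_FP + 1.645 * sqrt(Lambda_FP) + 0.8
    LOD = (1.645 + sqrt(1.645^2 + 4 * LOB))^2 / 4, rounded up to an integer

where 1.645 is the one-sided 95% normal quantile and 0.8 a continuity
correction for low-count Poisson blanks (Milbury-style construction). The
LOB is the highest count expected from a blank; the LOD is the lowest count
whose Poisson distribution exceeds the LOB with 95% probability. A sample is
called mutation-positive when its summed FAM+ droplet count is strictly
above the integer LOD. The framework applies in the Lambda_FP > 0.05
regime; below it, calls are suppressed as not-evaluable rather than made
silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .ddpcr import DdpcrQuantResult

__all__ = [
    "Z_CONSTANT",
    "CORRECTION_CONSTANT",
    "MIN_APPLICABLE_LAMBDA_FP",
    "NegativeControlSet",
    "DetectionThresholds",
    "MutationCall",
    "estimate_lambda_fp",
    "compute_lob",
    "compute_lod",
    "classify_sample",
    "vaf_t_test",
    "single_observation_t_test",
]

Z_CONSTANT = 1.645
CORRECTION_CONSTANT = 0.8
#: below this mean false-positive count the LOB/LOD construction is not applicable
MIN_APPLICABLE_LAMBDA_FP = 0.05


@dataclass
class NegativeControlSet:
    """FAM+ droplet counts (and optional VAFs) from mutation-negative controls.

    Controls must be processed with the same well-count/merge scheme as the
    test samples; the ``scheme`` tag records it and is checked at
    classification time.
    """

    fam_pos_counts: list[int]
    vafs: list[float] | None = None
    scheme: str = "per-duplicate-mean"

    def __post_init__(self) -> None:
        if len(self.fam_pos_counts) < 2:
            raise ValueError("need at least 2 negative controls")
        if any(c < 0 for c in self.fam_pos_counts):
            raise ValueError("control FAM+ counts must be >= 0")
        if self.vafs is not None and len(self.vafs) != len(self.fam_pos_counts):
            raise ValueError("vafs and fam_pos_counts lengths differ")

    def __len__(self) -> int:
        return len(self.fam_pos_counts)


def estimate_lambda_fp(controls: NegativeControlSet) -> float:
    """Mean FAM+ droplet count over the negative controls (Lambda_FP)."""
    return float(np.mean(controls.fam_pos_counts))


def compute_lob(lambda_fp: float) -> float:
    """Limit of blank, un-rounded."""
    if lambda_fp < 0:
        raise ValueError(f"lambda_fp must be >= 0, got {lambda_fp}")
    return lambda_fp + Z_CONSTANT * math.sqrt(lambda_fp) + CORRECTION_CONSTANT


def compute_lod(lob: float, rounded: bool = True) -> float:
    """Limit of detection from the un-rounded LOB.

    The closed form is evaluated on the real-valued LOB; only the final LOD
    is rounded (up, to the nearest integer). Rounding the LOB first would
    inflate the LOD by one count at sub-unit Lambda_FP.
    """
    if lob < 0:
        raise ValueError(f"lob must be >= 0, got {lob}")
    real = (Z_CONSTANT + math.sqrt(Z_CONSTANT**2 + 4.0 * lob)) ** 2 / 4.0
    return float(math.ceil(real)) if rounded else real


@dataclass
class DetectionThresholds:
    """Lambda_FP, LOB and LOD derived from a negative-control set."""

    lambda_fp: float
    lob: float
    lod_real: float
    lod: int
    applicable: bool
    n_controls: int
    scheme: str = "per-duplicate-mean"
    z_constant: float = Z_CONSTANT
    correction_constant: float = CORRECTION_CONSTANT

    @classmethod
    def from_controls(cls, controls: NegativeControlSet) -> "DetectionThresholds":
        lam = estimate_lambda_fp(controls)
        lob = compute_lob(lam)
        return cls(
            lambda_fp=lam,
            lob=lob,
            lod_real=compute_lod(lob, rounded=False),
            lod=int(compute_lod(lob)),
            applicable=lam > MIN_APPLICABLE_LAMBDA_FP,
            n_controls=len(controls),
            scheme=controls.scheme,
        )


@dataclass
class MutationCall:
    """Per-sample mutation-positivity decision.

    Negative calls carry no VAF ("ns" semantics in tabular output);
    ``p_vs_controls`` compares the sample VAF against the control VAF
    distribution when control VAFs are available.
    """

    sample_id: str
    fam_pos_count: int
    lod: int
    call: str  # positive | negative | not-evaluable
    vaf: float | None = None
    p_vs_controls: float | None = None
    flags: list[str] = field(default_factory=list)


def classify_sample(
    result: DdpcrQuantResult,
    thresholds: DetectionThresholds,
    controls: NegativeControlSet | None = None,
    strict: bool = True,
) -> MutationCall:
    """Call a sample mutation-positive iff its FAM+ count exceeds the LOD.

    "Above the LOD" is read as strictly greater (``strict=True``); set
    ``strict=False`` for count >= LOD. If the thresholds are not applicable
    (Lambda_FP <= 0.05) the call is ``not-evaluable``.
    """
    flags = list(result.flags)
    if result.scheme != thresholds.scheme:
        raise ValueError(
            f"sample processed with scheme {result.scheme!r} but thresholds "
            f"derived under {thresholds.scheme!r}; controls and samples must "
            "share a processing scheme"
        )
    if not thresholds.applicable:
        flags.append("thresholds-not-applicable")
        return MutationCall(
            sample_id=result.sample_id,
            fam_pos_count=result.fam_pos_count,
            lod=thresholds.lod,
            call="not-evaluable",
            flags=flags,
        )
    if result.wells_used == 0:
        flags.append("no-wells")
        return MutationCall(result.sample_id, 0, thresholds.lod, "not-evaluable", flags=flags)

    count = result.fam_pos_count
    positive = count > thresholds.lod if strict else count >= thresholds.lod

    p_vs = None
    if controls is not None and controls.vafs is not None and not math.isnan(result.fractional_abundance):
        _, p_vs = single_observation_t_test(result.fractional_abundance, controls.vafs)

    return MutationCall(
        sample_id=result.sample_id,
        fam_pos_count=count,
        lod=thresholds.lod,
        call="positive" if positive else "negative",
        vaf=result.fractional_abundance if positive else None,
        p_vs_controls=p_vs,
        flags=flags,
    )


def vaf_t_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-tailed equal-variance (pooled) two-sample t-test on VAF values.

    Returns (t, p). Degenerate cases: all values identical across both
    groups -> (0.0, 1.0); zero pooled variance with unequal means -> p = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values for the two-sample test")
    pooled_var = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
        len(a) + len(b) - 2
    )
    if pooled_var == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def single_observation_t_test(
    x: float, reference: Sequence[float]
) -> tuple[float, float]:
    """Prediction-interval t-test of one observation against reference values.

    t = (x - mean_ref) / (sd_ref * sqrt(1 + 1/n)), df = n - 1, two-sided p.
    This is the natural form when a sample yields a single VAF and the noise
    distribution comes from n technical controls.
    """
    ref = np.asarray(reference, dtype=float)
    n = len(ref)
    if n < 2:
        raise ValueError("need >= 2 reference values")
    sd = ref.std(ddof=1)
    if sd == 0:
        if x == ref.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, x - ref.mean()), 0.0
    t = (x - ref.mean()) / (sd * math.sqrt(1.0 + 1.0 / n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)
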