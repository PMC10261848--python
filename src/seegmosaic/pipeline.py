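"""End-to-end study runners: simulate -> quantify -> threshold -> classify.

These glue the generator and the callers together the way the study was
run: per-patient negative controls define the detection thresholds, each
electrode sample is quantified and classified against them, and the calls
join back onto the electrode metadata.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

import numpy as np

from .amplicon import AmpliconCall, call_amplicon_variant, fit_noise_model
from .ddpcr import qc_filter_wells, quantify_sample
from .electrodes import ElectrodeRecord, filter_eligible
from .limits import (
    DetectionThresholds,
    MutationCall,
    NegativeControlSet,
    classify_sample,
)
from .synthetic import (
    ElectrodeSpec,
    GeneratorConfig,
    StudyFixture,
    simulate_amplicon_sample,
    simulate_electrode_sample,
    simulate_negative_control_ddpcr,
)

__all__ = [
    "simulate_ddpcr_controls",
    "thresholds_from_simulated_controls",
    "run_ddpcr_electrodes",
    "run_amplicon_electrodes",
    "run_patient",
    "lod_replicate",
    "modal_value",
]


def simulate_ddpcr_controls(
    config: GeneratorConfig,
    rng: np.random.Generator,
    scheme: str = "per-duplicate-mean",
) -> NegativeControlSet:
    """Simulate the ddPCR negative-control panel, processed like samples."""
    counts, vafs = [], []
    for i in range(config.n_negative_controls_ddpcr):
        wells = qc_filter_wells(
            simulate_negative_control_ddpcr(config, rng, sample_id=f"NC{i + 1:02d}")
        )
        res = quantify_sample(wells, scheme=scheme)
        counts.append(res.fam_pos_count)
        vafs.append(0.0 if np.isnan(res.fractional_abundance) else res.fractional_abundance)
    return NegativeControlSet(fam_pos_counts=counts, vafs=vafs, scheme=scheme)


def thresholds_from_simulated_controls(
    config: GeneratorConfig,
    rng: np.random.Generator,
    scheme: str = "per-duplicate-mean",
) -> tuple[DetectionThresholds, NegativeControlSet]:
    controls = simulate_ddpcr_controls(config, rng, scheme=scheme)
    return DetectionThresholds.from_controls(controls), controls


def run_ddpcr_electrodes(
    specs: Sequence[ElectrodeSpec],
    config: GeneratorConfig,
    rng: np.random.Generator,
    thresholds: DetectionThresholds,
    controls: NegativeControlSet | None = None,
    scheme: str = "per-duplicate-mean",
) -> dict[str, MutationCall]:
    """Simulate, quantify and classify each ddPCR electrode; keyed by sample id."""
    calls = {}
    for spec in specs:
        wells = qc_filter_wells(simulate_electrode_sample(spec, config, rng))
        result = quantify_sample(wells, scheme=scheme)
        calls[spec.sample_id] = classify_sample(result, thresholds, controls=controls)
    return calls


def run_amplicon_electrodes(
    specs: Sequence[ElectrodeSpec],
    config: GeneratorConfig,
    rng: np.random.Generator,
    alpha: float = 0.05,
) -> dict[str, AmpliconCall]:
    """Simulate amplicon controls + electrodes and call each electrode."""
    controls = [
        simulate_amplicon_sample(0.0, config, rng, sample_id=f"ANC{i + 1:02d}")
        for i in range(config.n_negative_controls_amplicon)
    ]
    noise = fit_noise_model(controls)
    return {
        spec.sample_id: call_amplicon_variant(
            simulate_amplicon_sample(spec.true_vaf, config, rng, sample_id=spec.sample_id),
            noise,
            alpha=alpha,
        )
        for spec in specs
    }


def run_patient(
    fixture: StudyFixture,
    patient_id: str,
    rng: np.random.Generator,
    scheme: str = "per-duplicate-mean",
) -> list[ElectrodeRecord]:
    """Full single-patient replicate: eligibility, thresholds, calls, join.

    Returns one ElectrodeRecord per electrode of the patient (excluded
    electrodes carry no call).
    """
    specs = fixture.patient(patient_id)
    if not specs:
        raise ValueError(f"no electrodes for patient {patient_id!r} in fixture")
    records = filter_eligible([ElectrodeRecord(spec=s) for s in specs])
    eligible = [r for r in records if r.eligibility == "eligible"]
    assay = specs[0].assay
    if assay == "ddpcr":
        thresholds, controls = thresholds_from_simulated_controls(
            fixture.config, rng, scheme=scheme
        )
        calls = run_ddpcr_electrodes(
            [r.spec for r in eligible], fixture.config, rng, thresholds, controls, scheme
        )
    else:
        calls = run_amplicon_electrodes([r.spec for r in eligible], fixture.config, rng)
    for rec in eligible:
        rec.call = calls[rec.spec.sample_id]
    return records


def lod_replicate(config: GeneratorConfig, rng: np.random.Generator) -> int:
    """One negative-control replicate: simulate the panel, return the integer LOD."""
    thresholds, _ = thresholds_from_simulated_controls(config, rng)
    return thresholds.lod


def modal_value(values: Iterable[int]) -> int:
    """Most frequent value; smallest wins ties (deterministic)."""
    counts = Counter(values)
    best = max(counts.values())
    return min(v for v, c in counts.items() if c == best)
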