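"""Integration of per-electrode mutation calls with SEEG zone metadata.

Joins mutation calls (ddPCR or amplicon) to electrode records, applies the
DNA-yield eligibility rule (< 20 ng excluded for ddPCR; amplicon samples are
kept but flagged low-input, mirroring how 1.2-6.7 ng electrodes were still
sequenced), and produces the integrative outputs: per-zone positivity
summary, lesion concordance and the tissue-block mutation gradient.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

from .amplicon import AmpliconCall
from .limits import DetectionThresholds, MutationCall
from .synthetic import ElectrodeSpec

__all__ = [
    "DEFAULT_MIN_DNA_NG",
    "ElectrodeRecord",
    "ZoneSummary",
    "GradientReport",
    "filter_eligible",
    "summarize_by_zone",
    "mutation_gradient",
    "build_report",
    "parse_table2_like",
]

DEFAULT_MIN_DNA_NG = 20.0
ZONES = ("EZN", "PZN", "NIN")

#: amplicon inputs below this are flagged (not excluded)
LOW_INPUT_FLAG_NG = 10.0


@dataclass
class ElectrodeRecord:
    """An electrode joined to its eligibility status and (optional) call."""

    spec: ElectrodeSpec
    eligibility: str = "eligible"  # eligible | excluded-low-dna | excluded-other
    call: MutationCall | AmpliconCall | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.eligibility != "eligible" and self.call is not None:
            raise ValueError(
                f"excluded electrode {self.spec.sample_id} must not carry a call"
            )

    @property
    def assay(self) -> str:
        return self.spec.assay

    @property
    def is_positive(self) -> bool:
        return self.call is not None and self.call.call == "positive"

    @property
    def vaf(self) -> float | None:
        if self.call is None:
            return None
        if isinstance(self.call, MutationCall):
            return self.call.vaf
        return self.call.vaf if self.call.call == "positive" else None


def filter_eligible(
    records: list[ElectrodeRecord], min_dna_ng: float = DEFAULT_MIN_DNA_NG
) -> list[ElectrodeRecord]:
    """Apply the DNA-yield eligibility rule in place; returns the records.

    ddPCR electrodes with dna_ng strictly below ``min_dna_ng`` are marked
    ``excluded-low-dna`` (exactly 20 ng stays eligible). Amplicon electrodes
    are never excluded on yield but get a ``low-input`` flag below 10 ng.
    """
    for rec in records:
        if rec.assay == "ddpcr" and rec.spec.dna_ng < min_dna_ng:
            rec.eligibility = "excluded-low-dna"
            rec.call = None
        elif rec.assay == "amplicon" and rec.spec.dna_ng < LOW_INPUT_FLAG_NG:
            if "low-input" not in rec.flags:
                rec.flags.append("low-input")
    return records


@dataclass
class ZoneSummary:
    """Counts and VAFs per zone and per MRI-lesion status."""

    per_zone: dict[str, dict]
    per_lesion: dict[str, dict]
    n_positive_total: int
    ezn_fraction_of_positives: float  # NaN when there are no positives


def summarize_by_zone(records: list[ElectrodeRecord]) -> ZoneSummary:
    """Tabulate electrode counts, eligibility and positivity by zone and lesion."""

    def _bucket() -> dict:
        return {"n_electrodes": 0, "n_eligible": 0, "n_positive": 0, "vafs": []}

    per_zone = {z: _bucket() for z in ZONES}
    per_lesion = {"in_lesion": _bucket(), "outside_lesion": _bucket()}
    n_pos = 0
    ezn_pos = 0
    for rec in records:
        buckets = [
            per_zone[rec.spec.zone],
            per_lesion["in_lesion" if rec.spec.in_mri_lesion else "outside_lesion"],
        ]
        for b in buckets:
            b["n_electrodes"] += 1
            if rec.eligibility == "eligible":
                b["n_eligible"] += 1
            if rec.is_positive:
                b["n_positive"] += 1
                if rec.vaf is not None:
                    b["vafs"].append(rec.vaf)
        if rec.is_positive:
            n_pos += 1
            if rec.spec.zone == "EZN":
                ezn_pos += 1
    return ZoneSummary(
        per_zone=per_zone,
        per_lesion=per_lesion,
        n_positive_total=n_pos,
        ezn_fraction_of_positives=(ezn_pos / n_pos) if n_pos else math.nan,
    )


@dataclass
class GradientReport:
    """Tissue blocks ordered by VAF, with monotonicity flag and max/min ratio."""

    ordered: list[tuple[str, float]]
    monotone: bool
    ratio: float | None  # max/min VAF; None when the minimum is zero


def mutation_gradient(blocks: dict[str, float]) -> GradientReport:
    """Sort tissue blocks by VAF descending and report the gradient shape.

    ``monotone`` is True only for strictly decreasing VAFs (ties break it);
    tied blocks keep their insertion order (stable sort).
    """
    if len(blocks) < 2:
        raise ValueError("need >= 2 tissue blocks for a gradient")
    ordered = sorted(blocks.items(), key=lambda kv: -kv[1])
    vafs = [v for _, v in ordered]
    monotone = all(a > b for a, b in zip(vafs, vafs[1:]))
    ratio = (max(vafs) / min(vafs)) if min(vafs) > 0 else None
    return GradientReport(ordered=ordered, monotone=monotone, ratio=ratio)


def _vaf_or_ns(rec: ElectrodeRecord) -> str:
    if rec.eligibility != "eligible":
        return ""
    v = rec.vaf
    return "ns" if (v is None or not rec.is_positive) else f"{100 * v:.2f}%"


def build_report(
    records: list[ElectrodeRecord],
    summary: ZoneSummary,
    thresholds: DetectionThresholds | None,
    outdir: str,
    gradient: GradientReport | None = None,
) -> dict:
    """Write the report bundle: report.json, zone_summary.tsv, table2_like.tsv.

    The table2-shaped TSV renders negative calls as "ns" and excluded
    electrodes with their exclusion reason and no VAF; report.json carries
    explicit nulls instead. Returns the JSON-ready report dict.
    """
    os.makedirs(outdir, exist_ok=True)

    report = {
        "n_electrodes": len(records),
        "n_eligible": sum(r.eligibility == "eligible" for r in records),
        "n_positive": summary.n_positive_total,
        "ezn_fraction_of_positives": (
            None
            if math.isnan(summary.ezn_fraction_of_positives)
            else summary.ezn_fraction_of_positives
        ),
        "thresholds": (
            {
                "lambda_fp": thresholds.lambda_fp,
                "lob": thresholds.lob,
                "lod_real": thresholds.lod_real,
                "lod": thresholds.lod,
                "applicable": thresholds.applicable,
                "n_controls": thresholds.n_controls,
            }
            if thresholds is not None
            else None
        ),
        "zones": summary.per_zone,
        "lesion": summary.per_lesion,
        "electrodes": [
            {
                "patient_id": r.spec.patient_id,
                "electrode_id": r.spec.electrode_id,
                "zone": r.spec.zone,
                "in_mri_lesion": r.spec.in_mri_lesion,
                "thermocoagulated": r.spec.thermocoagulated,
                "dna_ng": r.spec.dna_ng,
                "assay": r.assay,
                "eligibility": r.eligibility,
                "call": r.call.call if r.call is not None else None,
                "vaf": r.vaf,
                "flags": r.flags,
            }
            for r in records
        ],
    }
    if gradient is not None:
        report["tissue_gradient"] = {
            "ordered": gradient.ordered,
            "monotone": gradient.monotone,
            "max_min_ratio": gradient.ratio,
        }

    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2)

    with open(os.path.join(outdir, "zone_summary.tsv"), "w") as fh:
        fh.write("stratum\tlevel\tn_electrodes\tn_eligible\tn_positive\tvafs\n")
        for stratum, table in (("zone", summary.per_zone), ("lesion", summary.per_lesion)):
            for level, b in table.items():
                vafs = ",".join(f"{v:.6f}" for v in b["vafs"])
                fh.write(
                    f"{stratum}\t{level}\t{b['n_electrodes']}\t{b['n_eligible']}"
                    f"\t{b['n_positive']}\t{vafs}\n"
                )

    with open(os.path.join(outdir, "table2_like.tsv"), "w") as fh:
        fh.write(
            "patient_id\telectrode_id\tdna_ng\tzone\tin_mri_lesion"
            "\tthermocoagulated\teligibility\tvaf\n"
        )
        for r in records:
            fh.write(
                f"{r.spec.patient_id}\t{r.spec.electrode_id}\t{r.spec.dna_ng:g}"
                f"\t{r.spec.zone}\t{'yes' if r.spec.in_mri_lesion else 'no'}"
                f"\t{'yes' if r.spec.thermocoagulated else 'no'}"
                f"\t{r.eligibility}\t{_vaf_or_ns(r)}\n"
            )
    return report


def parse_table2_like(path: str) -> list[dict]:
    """Parse a table2_like.tsv back into row dicts (round-trip check hook).

    VAF strings like "1.10%" come back as fractions; "ns" as None with a
    negative call; empty VAF marks an excluded electrode.
    """
    import pandas as pd

    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    rows = []
    for _, row in frame.iterrows():
        vaf_str = row["vaf"]
        if vaf_str == "ns":
            vaf, call = None, "negative"
        elif vaf_str == "":
            vaf, call = None, None
        else:
            vaf, call = float(vaf_str.rstrip("%")) / 100.0, "positive"
        rows.append(
            {
                "patient_id": row["patient_id"],
                "electrode_id": row["electrode_id"],
                "dna_ng": float(row["dna_ng"]),
                "zone": row["zone"],
                "in_mri_lesion": row["in_mri_lesion"] == "yes",
                "thermocoagulated": row["thermocoagulated"] == "yes",
                "eligibility": row["eligibility"],
                "call": call,
                "vaf": vaf,
            }
        )
    return rows
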