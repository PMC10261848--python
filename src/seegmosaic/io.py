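"""Tab-separated table I/O for the pipeline's fixed schemas.

All tables are TSV with a single header row. Schemas:

* ddpcr_wells.tsv: sample_id, well_id, replicate, accepted, fam_only,
  hex_only, double_pos, double_neg
* amplicon_counts.tsv: sample_id, contig, pos, ref, alt, ref_count,
  alt_count, other_count
* electrodes.tsv: electrode_id, patient_id, zone, in_mri_lesion,
  thermocoagulated, dna_ng, true_vaf, assay
* thresholds.json: lambda_fp, lob, lod_real, lod, applicable, n_controls,
  scheme

Missing droplet-class columns default to 0 with a warning; any other
missing column is an error.
"""

from __future__ import annotations

import json
import warnings

import pandas as pd

from .amplicon import Locus, SiteAlleleCounts
from .ddpcr import DropletWellCounts
from .limits import DetectionThresholds
from .synthetic import ElectrodeSpec

WELL_CLASS_COLUMNS = ("fam_only", "hex_only", "double_pos", "double_neg")


def write_wells(wells: list[DropletWellCounts], path: str) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": w.sample_id,
                "well_id": w.well_id,
                "replicate": w.replicate,
                "accepted": w.accepted,
                "fam_only": w.fam_only,
                "hex_only": w.hex_only,
                "double_pos": w.double_pos,
                "double_neg": w.double_neg,
            }
            for w in wells
        ]
    ).to_csv(path, sep="\t", index=False)


def read_wells(path: str) -> list[DropletWellCounts]:
    frame = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "well_id", "accepted"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    for col in WELL_CLASS_COLUMNS:
        if col not in frame.columns:
            warnings.warn(f"{path}: missing droplet class column {col!r}; assuming 0")
            frame[col] = 0
    if "replicate" not in frame.columns:
        frame["replicate"] = 1
    return [
        DropletWellCounts(
            sample_id=str(row.sample_id),
            well_id=str(row.well_id),
            accepted=int(row.accepted),
            fam_only=int(row.fam_only),
            hex_only=int(row.hex_only),
            double_pos=int(row.double_pos),
            double_neg=int(row.double_neg),
            replicate=int(row.replicate),
        )
        for row in frame.itertuples()
    ]


def write_amplicon_counts(samples: list[SiteAlleleCounts], path: str) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "contig": s.locus.contig,
                "pos": s.locus.pos,
                "ref": s.locus.ref,
                "alt": s.locus.alt,
                "ref_count": s.ref_count,
                "alt_count": s.alt_count,
                "other_count": s.other_count,
            }
            for s in samples
        ]
    ).to_csv(path, sep="\t", index=False)


def read_amplicon_counts(path: str) -> list[SiteAlleleCounts]:
    frame = pd.read_csv(path, sep="\t")
    required = {"sample_id", "contig", "pos", "ref", "alt", "ref_count", "alt_count"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    if "other_count" not in frame.columns:
        frame["other_count"] = 0
    return [
        SiteAlleleCounts(
            sample_id=str(row.sample_id),
            locus=Locus(str(row.contig), int(row.pos), str(row.ref), str(row.alt)),
            ref_count=int(row.ref_count),
            alt_count=int(row.alt_count),
            other_count=int(row.other_count),
        )
        for row in frame.itertuples()
    ]


def write_electrodes(specs: list[ElectrodeSpec], path: str) -> None:
    pd.DataFrame(
        [
            {
                "electrode_id": e.electrode_id,
                "patient_id": e.patient_id,
                "zone": e.zone,
                "in_mri_lesion": e.in_mri_lesion,
                "thermocoagulated": e.thermocoagulated,
                "dna_ng": e.dna_ng,
                "true_vaf": e.true_vaf,
                "assay": e.assay,
            }
            for e in specs
        ]
    ).to_csv(path, sep="\t", index=False)


def read_electrodes(path: str) -> list[ElectrodeSpec]:
    frame = pd.read_csv(path, sep="\t")
    return [
        ElectrodeSpec(
            electrode_id=str(row.electrode_id),
            patient_id=str(row.patient_id),
            zone=str(row.zone),
            in_mri_lesion=bool(row.in_mri_lesion),
            thermocoagulated=bool(row.thermocoagulated),
            dna_ng=float(row.dna_ng),
            true_vaf=float(row.true_vaf),
            assay=str(row.assay),
        )
        for row in frame.itertuples()
    ]


def write_thresholds(thresholds: DetectionThresholds, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "lambda_fp": thresholds.lambda_fp,
                "lob": thresholds.lob,
                "lod_real": thresholds.lod_real,
                "lod": thresholds.lod,
                "applicable": thresholds.applicable,
                "n_controls": thresholds.n_controls,
                "scheme": thresholds.scheme,
            },
            fh,
            indent=2,
        )


def read_thresholds(path: str) -> DetectionThresholds:
    with open(path) as fh:
        d = json.load(fh)
    return DetectionThresholds(
        lambda_fp=d["lambda_fp"],
        lob=d["lob"],
        lod_real=d["lod_real"],
        lod=int(d["lod"]),
        applicable=bool(d["applicable"]),
        n_controls=int(d["n_controls"]),
        scheme=d.get("scheme", "per-duplicate-mean"),
    )
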