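"""Poisson quantification of mutant/wild-type template from ddPCR droplet counts.

A droplet digital PCR well partitions template DNA into ~20,000 nanoliter
droplets. Each droplet is end-point classified on two fluorescence channels:
FAM reports the mutant probe, HEX the wild-type probe. Because template
molecules distribute over droplets approximately Poisson, the mean number of
copies per droplet on a channel is recovered from the fraction of droplets
*negative* on that channel, lambda = -ln(n_negative / n_total). The mutant
fractional abundance lambda_mut / (lambda_mut + lambda_wt) is the ddPCR
estimate of the variant allele frequency (VAF) and automatically corrects for
co-encapsulation of multiple molecules in one droplet.

This module applies the study's processing rules: wells with fewer than
10,000 accepted droplets are discarded, split wells are merged by summing
droplet-class counts, and the reported VAF is the mean fractional abundance
over duplicate measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "DropletWellCounts",
    "DdpcrQuantResult",
    "SaturationError",
    "qc_filter_wells",
    "merge_wells",
    "estimate_lambda",
    "fractional_abundance",
    "quantify_sample",
]

#: accepted-droplet minimum below which a well is discarded
DEFAULT_MIN_ACCEPTED = 10_000


class SaturationError(ValueError):
    """A channel has zero negative droplets: concentration is unbounded.

    Raised instead of capping, so that saturated inputs (which cannot occur
    at mosaic VAFs on 2.5 ng of template) surface as errors.
    """


@dataclass(frozen=True)
class DropletWellCounts:
    """Droplet counts for one well, partitioned by FAM/HEX positivity.

    ``replicate`` identifies the duplicate measurement the well belongs to
    (the assay runs each 5 ng sample as two duplicates, each split over two
    2.5 ng wells); it drives the per-duplicate VAF averaging.
    """

    sample_id: str
    well_id: str
    accepted: int
    fam_only: int
    hex_only: int
    double_pos: int
    double_neg: int
    replicate: int = 1

    def __post_init__(self) -> None:
        for name in ("accepted", "fam_only", "hex_only", "double_pos", "double_neg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        total = self.fam_only + self.hex_only + self.double_pos + self.double_neg
        if total != self.accepted:
            raise ValueError(
                f"droplet classes sum to {total}, accepted is {self.accepted} "
                f"(sample {self.sample_id!r}, well {self.well_id!r})"
            )

    @property
    def fam_pos(self) -> int:
        """FAM-positive (mutant-channel) droplets."""
        return self.fam_only + self.double_pos

    @property
    def hex_pos(self) -> int:
        """HEX-positive (wild-type-channel) droplets."""
        return self.hex_only + self.double_pos

    @property
    def fam_neg(self) -> int:
        return self.hex_only + self.double_neg

    @property
    def hex_neg(self) -> int:
        return self.fam_only + self.double_neg


@dataclass
class DdpcrQuantResult:
    """Per-sample quantification: channel concentrations and VAF.

    ``fractional_abundance`` is NaN when both channels are empty (flagged).
    ``fam_pos_count`` is summed over *all* retained wells of the sample; it
    is the count the limit-of-detection classifier operates on.
    """

    sample_id: str
    lambda_mut: float
    lambda_wt: float
    fractional_abundance: float
    fam_pos_count: int
    wells_used: int
    scheme: str = "per-duplicate-mean"
    flags: list[str] = field(default_factory=list)


def qc_filter_wells(
    wells: list[DropletWellCounts], min_accepted: int = DEFAULT_MIN_ACCEPTED
) -> list[DropletWellCounts]:
    """Discard wells with fewer than ``min_accepted`` accepted droplets.

    Returns the retained wells in input order. Discarded wells are recorded
    on the module logger with their sample and well ids.
    """
    kept = []
    for well in wells:
        if well.accepted >= min_accepted:
            kept.append(well)
        else:
            _log_discard(well, min_accepted)
    return kept


def _log_discard(well: DropletWellCounts, min_accepted: int) -> None:
    import logging

    logging.getLogger(__name__).info(
        "discarding well %s/%s: %d accepted droplets < %d",
        well.sample_id,
        well.well_id,
        well.accepted,
        min_accepted,
    )


def merge_wells(wells: list[DropletWellCounts]) -> DropletWellCounts:
    """Merge wells of one sample by summing droplet-class counts.

    Mirrors the 'merge wells' operation of the ddPCR analysis software: the
    merged well behaves as a single larger partition experiment. All wells
    must share a sample id.
    """
    if not wells:
        raise ValueError("cannot merge an empty well list")
    sample_ids = {w.sample_id for w in wells}
    if len(sample_ids) > 1:
        raise ValueError(f"refusing to merge wells from different samples: {sorted(sample_ids)}")
    if len(wells) == 1:
        return wells[0]
    replicates = {w.replicate for w in wells}
    return DropletWellCounts(
        sample_id=wells[0].sample_id,
        well_id="merged(" + "+".join(w.well_id for w in wells) + ")",
        accepted=sum(w.accepted for w in wells),
        fam_only=sum(w.fam_only for w in wells),
        hex_only=sum(w.hex_only for w in wells),
        double_pos=sum(w.double_pos for w in wells),
        double_neg=sum(w.double_neg for w in wells),
        replicate=replicates.pop() if len(replicates) == 1 else 0,
    )


def estimate_lambda(n_channel_negative: int, n_total: int) -> float:
    """Mean copies per droplet from the channel-negative droplet count.

    Maximum-likelihood Poisson occupancy estimate: with lambda copies per
    droplet on average, a droplet is channel-negative with probability
    e^(-lambda), so lambda = -ln(n_negative / n_total).
    """
    if n_total <= 0:
        raise ValueError(f"total droplet count must be positive, got {n_total}")
    if n_channel_negative > n_total:
        raise ValueError(
            f"negative count {n_channel_negative} exceeds total {n_total}"
        )
    if n_channel_negative == 0:
        raise SaturationError(
            "all droplets channel-positive: concentration unbounded "
            "(template overload; dilute and rerun)"
        )
    return -math.log(n_channel_negative / n_total)


def fractional_abundance(lambda_mut: float, lambda_wt: float) -> float:
    """Mutant fraction lambda_mut / (lambda_mut + lambda_wt); NaN if both zero."""
    if lambda_mut < 0 or lambda_wt < 0:
        raise ValueError("concentrations must be >= 0")
    total = lambda_mut + lambda_wt
    if total == 0:
        return math.nan
    return lambda_mut / total


def _estimate_pair(well: DropletWellCounts) -> tuple[float, float]:
    """(lambda_mut, lambda_wt) for one (possibly merged) well."""
    lam_mut = estimate_lambda(well.fam_neg, well.accepted)
    lam_wt = estimate_lambda(well.hex_neg, well.accepted)
    return lam_mut, lam_wt


def quantify_sample(
    wells: list[DropletWellCounts],
    scheme: str = "per-duplicate-mean",
) -> DdpcrQuantResult:
    """Quantify one sample from its retained wells.

    scheme="per-duplicate-mean" (the study's rule): merge the split wells of
    each duplicate, compute the fractional abundance per duplicate, and
    report the mean of the duplicate values as the VAF.
    scheme="pooled": merge all wells, compute once.

    Either way ``lambda_mut``/``lambda_wt`` are reported from the pooled
    merge and ``fam_pos_count`` is summed over all retained wells — the
    classifier consumes the summed count, not the VAF.
    """
    if scheme not in ("per-duplicate-mean", "pooled"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if not wells:
        return DdpcrQuantResult(
            sample_id="",
            lambda_mut=math.nan,
            lambda_wt=math.nan,
            fractional_abundance=math.nan,
            fam_pos_count=0,
            wells_used=0,
            scheme=scheme,
            flags=["no-wells"],
        )
    pooled = merge_wells(wells)
    lam_mut, lam_wt = _estimate_pair(pooled)
    flags: list[str] = []

    if scheme == "pooled":
        vaf = fractional_abundance(lam_mut, lam_wt)
    else:
        by_rep: dict[int, list[DropletWellCounts]] = {}
        for w in wells:
            by_rep.setdefault(w.replicate, []).append(w)
        vafs = []
        for rep in sorted(by_rep):
            lm, lw = _estimate_pair(merge_wells(by_rep[rep]))
            vafs.append(fractional_abundance(lm, lw))
        finite = [v for v in vafs if not math.isnan(v)]
        if len(finite) < len(vafs):
            flags.append("empty-duplicate")
        vaf = sum(finite) / len(finite) if finite else math.nan
    if math.isnan(vaf):
        flags.append("undefined-vaf")

    return DdpcrQuantResult(
        sample_id=pooled.sample_id,
        lambda_mut=lam_mut,
        lambda_wt=lam_wt,
        fractional_abundance=vaf,
        fam_pos_count=sum(w.fam_pos for w in wells),
        wells_used=len(wells),
        scheme=scheme,
        flags=flags,
    )
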