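"""Poisson quantification of droplet counts: copies, VAFs, LODs,
detection calls, dilution linearity, and a Cq-based qPCR comparator.

Digital PCR distributes target molecules over droplets approximately as a
Poisson process, so the mean number of copies per droplet is recovered
from the fraction of negative droplets: ``lambda = -ln(1 - p)`` with
``p = positives / accepted``.  A variant allele frequency is the ratio of
mutant copies (SuperSelective channel) to total copies (standard channel)
times 100.  The limit of detection of an assay is the mean background VAF
in wild-type-only material plus three standard deviations, over nine or
more replicate measurements.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Sequence

import numpy as np
from scipy import stats

from .droplet_sim import Channel, PartitionConfig, ReplicateSet, WellCount
from .errors import InputError

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class OverUnityWarning(UserWarning):
    """A VAF above 100% was computed (more SSP than standard copies)."""


class SingleReplicateWarning(UserWarning):
    """Dispersion requested from a single replicate; SD reported as 0."""


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Absolute concentration from one well's droplet counts."""

    lambda_per_droplet: float
    copies_in_partition: float   # lambda * accepted droplets
    copies_per_microliter: float
    copies_per_reaction: float   # scaled to the full reaction volume
    ci95: tuple[float, float]
    saturated_flag: bool


@dataclass(frozen=True)
class ReplicateStats:
    mean: float
    sd: float
    sem: float
    n: int


@dataclass(frozen=True)
class VafMeasurement:
    snv_copies: float
    total_copies: float
    vaf_percent: float
    replicate_values: tuple[float, ...]
    mean: float
    sem: float

    @property
    def n(self) -> int:
        return len(self.replicate_values)


@dataclass(frozen=True)
class LodEstimate:
    """Limit of detection: background mean + k * SD (k defaults to 3)."""

    mean_background_vaf: float
    sd_background_vaf: float
    k: float
    n_replicates: int | None
    lod_percent: float
    low_n_warning: bool

    @classmethod
    def from_summary(
        cls, mean: float, sd: float, k: float = 3.0,
        n: int | None = None, min_n: int = 9,
    ) -> "LodEstimate":
        if sd < 0:
            raise InputError("sd must be >= 0")
        return cls(mean, sd, k, n, mean + k * sd, n is not None and n < min_n)


@dataclass(frozen=True)
class DilutionFit:
    expected_vafs: tuple[float, ...]
    measured_means: tuple[float, ...]
    slope: float
    intercept: float
    pearson_r: float
    r_squared: float
    p_value: float


# ---------------------------------------------------------------------------


def estimate_lambda(
    well: WellCount, config: PartitionConfig = PartitionConfig()
) -> ConcentrationEstimate:
    """Poisson-corrected copies from positive/accepted droplet counts.

    ``copies_in_partition`` is the estimated molecule count inside the
    accepted droplets; ``copies_per_reaction`` additionally scales to the
    nominal reaction volume (instrument-software convention), which
    matters only when the droplets do not hold the whole reaction.
    A fully positive well is flagged saturated with an infinite sentinel.
    """
    n = well.accepted_droplets
    p = well.positives / n
    if well.positives == n:
        inf = math.inf
        return ConcentrationEstimate(inf, inf, inf, inf, (inf, inf), True)
    lam = -math.log1p(-p)
    # delta method on the positive fraction: var(lambda) = p / ((1-p) n)
    se = math.sqrt(p / ((1.0 - p) * n)) if p > 0 else 0.0
    ci = (max(0.0, lam - Z_95 * se), lam + Z_95 * se)
    copies_partition = lam * n
    copies_per_ul = lam / (config.droplet_volume_nl * 1e-3)
    copies_reaction = copies_per_ul * config.reaction_volume_ul
    return ConcentrationEstimate(
        lam, copies_partition, copies_per_ul, copies_reaction, ci, False
    )


def compute_vaf(snv_copies: float, total_copies: float) -> float:
    """Variant allele frequency in percent: 100 * SNV / total copies."""
    if total_copies <= 0:
        raise InputError("total_copies must be > 0")
    if snv_copies < 0:
        raise InputError("snv_copies must be >= 0")
    vaf = 100.0 * snv_copies / total_copies
    if vaf > 100.0:
        warnings.warn(
            f"VAF {vaf:.2f}% exceeds 100% (SNV copies above total copies)",
            OverUnityWarning,
            stacklevel=2,
        )
    return vaf


def vaf_from_reads(variant_reads: int, total_reads: int) -> float:
    """Sequencing VAF from read counts, rounded half-even to 2 decimals
    (report convention)."""
    if total_reads <= 0:
        raise InputError("total_reads must be > 0")
    if not 0 <= variant_reads <= total_reads:
        raise InputError("variant_reads must be in [0, total_reads]")
    exact = Decimal(100 * variant_reads) / Decimal(total_reads)
    return float(exact.quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))


def aggregate_replicates(values: Sequence[float]) -> ReplicateStats:
    """Mean, sample SD (n-1 denominator) and SEM of replicate VAFs."""
    if len(values) == 0:
        raise InputError("values must be non-empty")
    arr = np.asarray(values, dtype=float)
    n = arr.size
    mean = float(arr.mean())
    if n == 1:
        warnings.warn(
            "single replicate: SD reported as 0", SingleReplicateWarning,
            stacklevel=2,
        )
        return ReplicateStats(mean, 0.0, 0.0, 1)
    sd = float(arr.std(ddof=1))
    return ReplicateStats(mean, sd, sd / math.sqrt(n), n)


def estimate_lod(
    background_vafs: Sequence[float],
    k: float = 3.0,
    min_n: int = 9,
) -> LodEstimate:
    """LOD = mean + k*SD of blank (0%-VAF) replicate measurements.

    Fewer than ``min_n`` replicates yields a valid estimate with a
    low-confidence warning flag.
    """
    if len(background_vafs) < 2:
        raise InputError("need at least 2 background measurements")
    stats_ = aggregate_replicates(background_vafs)
    return LodEstimate(
        stats_.mean, stats_.sd, k, stats_.n,
        stats_.mean + k * stats_.sd, stats_.n < min_n,
    )


def classify_detection(measurement: VafMeasurement, lod: LodEstimate) -> str:
    """``"detected"`` iff the mean VAF strictly exceeds the LOD (a tie is
    conservatively not detected)."""
    return "detected" if measurement.mean > lod.lod_percent else "not_detected"


def fit_dilution(
    expected: Sequence[float], measured: Sequence[float]
) -> DilutionFit:
    """Least-squares fit and Pearson correlation of measured vs expected
    VAF over a dilution series (two-sided p from t with n-2 df)."""
    x = np.asarray(expected, dtype=float)
    y = np.asarray(measured, dtype=float)
    if x.size != y.size:
        raise InputError("expected and measured must have equal length")
    if x.size < 3:
        raise InputError("need at least 3 dilution points")
    if np.allclose(x, x[0]):
        raise InputError("expected VAFs must not all be equal")
    res = stats.linregress(x, y)
    return DilutionFit(
        tuple(x.tolist()), tuple(y.tolist()),
        float(res.slope), float(res.intercept),
        float(res.rvalue), float(res.rvalue ** 2), float(res.pvalue),
    )


@dataclass(frozen=True)
class GenomeEquivalents:
    exact: float
    rounded: int


def mass_to_genome_equivalents(
    mass_ng: float, pg_per_haploid: float = 3.3
) -> GenomeEquivalents:
    """Convert input DNA mass to haploid genome equivalents
    (~3.3 pg per haploid human genome); 33 ng -> 10,000."""
    if pg_per_haploid <= 0:
        raise InputError("pg_per_haploid must be > 0")
    if mass_ng < 0:
        raise InputError("mass_ng must be >= 0")
    exact = mass_ng * 1000.0 / pg_per_haploid
    return GenomeEquivalents(exact, round(exact))


def vaf_from_cq(
    cq_mutant: float, cq_total: float, efficiency: float = 2.0
) -> float | None:
    """qPCR comparator: VAF% = 100 * efficiency^(Cq_total - Cq_mutant).

    Non-finite Cq (no amplification) returns ``None`` (not detected).
    """
    if not 1.0 < efficiency <= 2.0:
        raise InputError("efficiency must be in (1, 2]")
    if not (math.isfinite(cq_mutant) and math.isfinite(cq_total)):
        return None
    return 100.0 * efficiency ** (cq_total - cq_mutant)


# ---------------------------------------------------------------------------
# Well-pair pipeline


def vaf_from_well_pair(
    ssp_well: WellCount,
    standard_well: WellCount,
    config: PartitionConfig = PartitionConfig(),
) -> float:
    """Single-replicate ddPCR VAF from a paired SSP/STANDARD well."""
    if ssp_well.channel != Channel.SSP or standard_well.channel != Channel.STANDARD:
        raise InputError("expected one SSP well and one STANDARD well")
    snv = estimate_lambda(ssp_well, config)
    tot = estimate_lambda(standard_well, config)
    if tot.saturated_flag or snv.saturated_flag:
        raise InputError("saturated well: VAF is undefined")
    return compute_vaf(snv.copies_in_partition, tot.copies_in_partition)


def quantify_replicate_set(
    rs: ReplicateSet, config: PartitionConfig | None = None
) -> VafMeasurement:
    """VAF measurement (mean +- SEM over replicates) for one scenario."""
    cfg = config if config is not None else rs.config
    values = []
    snv_copies = []
    total_copies = []
    for ssp_well, std_well in rs.pairs:
        snv = estimate_lambda(ssp_well, cfg)
        tot = estimate_lambda(std_well, cfg)
        if snv.saturated_flag or tot.saturated_flag:
            raise InputError(
                f"saturated well in scenario {rs.label!r}: VAF undefined"
            )
        snv_copies.append(snv.copies_in_partition)
        total_copies.append(tot.copies_in_partition)
        values.append(compute_vaf(snv.copies_in_partition, tot.copies_in_partition))
    agg = aggregate_replicates(values)
    mean_snv = float(np.mean(snv_copies))
    mean_total = float(np.mean(total_copies))
    return VafMeasurement(
        mean_snv, mean_total,
        compute_vaf(mean_snv, mean_total) if mean_total > 0 else 0.0,
        tuple(values), agg.mean, agg.sem,
    )


def quantify_dilution_series(
    series: Sequence[ReplicateSet], config: PartitionConfig | None = None
) -> DilutionFit:
    """Quantify every level of a dilution series and fit measured-vs-
    expected VAF."""
    expected = [rs.true_vaf for rs in series]
    measured = [quantify_replicate_set(rs, config).mean for rs in series]
    return fit_dilution(expected, measured)
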