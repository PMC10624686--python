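"""Prioritization cascade for whole-exome SNV calls.

Candidate somatic variants for ddPCR validation are selected from an
annotated call table in two stages: hard filters (minimum read depth,
exclusion of population-frequent variants by the highest gnomAD allele
frequency across populations), then a functional cascade (SnpEff impact
MODERATE/HIGH, at least 3 of 5 pathogenicity predictors positive, COSMIC
membership, and a WES VAF cap targeting low-frequency variants).

Missing annotation fields conservatively fail the criterion that needs
them, and the audit trail marks them "missing".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import InputError
from .quantify import vaf_from_reads

IMPACT_LEVELS = ("LOW", "MODIFIER", "MODERATE", "HIGH")

#: Pathogenicity predictor thresholds (strict inequalities; a boundary
#: value is not a vote). MutationTaster votes on an exact call string.
POLYPHEN_MIN = 0.85
LRT_MAX = 0.1
SIFT_MAX = 0.05
CADD_MIN = 15.0
MUTATION_TASTER_CALLS = frozenset({"D", "D,D"})


@dataclass(frozen=True)
class AnnotatedVariant:
    """One WES call with the annotations the cascade consumes."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene_symbol: str
    hgvs_c: str
    impact: str
    total_reads: int
    variant_reads: int
    gnomad_max_af: float | None = None
    polyphen: float | None = None
    lrt: float | None = None
    sift: float | None = None
    cadd: float | None = None
    mutation_taster: str | None = None
    cosmic_id: str | None = None
    in_both_callers: bool | None = None

    def __post_init__(self) -> None:
        if self.impact not in IMPACT_LEVELS:
            raise InputError(
                f"impact must be one of {IMPACT_LEVELS}, got {self.impact!r}"
            )
        if self.total_reads < 0 or not 0 <= self.variant_reads <= max(
            self.total_reads, 0
        ):
            raise InputError("need 0 <= variant_reads <= total_reads")
        if self.gnomad_max_af is not None and not 0 <= self.gnomad_max_af <= 1:
            raise InputError("gnomad_max_af must be in [0, 1] or missing")

    @property
    def wes_vaf_percent(self) -> float:
        """WES VAF in percent (2-decimal report rounding)."""
        return vaf_from_reads(self.variant_reads, self.total_reads)


@dataclass(frozen=True)
class PrioritizationConfig:
    min_total_reads: int = 10
    max_gnomad_af: float = 0.05
    allowed_impacts: frozenset[str] = frozenset({"MODERATE", "HIGH"})
    min_pathogenic_votes: int = 3
    require_cosmic: bool = True
    max_wes_vaf_percent: float | None = 10.0
    require_both_callers: bool = False

    def __post_init__(self) -> None:
        if self.min_total_reads < 0:
            raise InputError("min_total_reads must be >= 0")
        if not 0 <= self.max_gnomad_af <= 1:
            raise InputError("max_gnomad_af must be in [0, 1]")
        if not 0 <= self.min_pathogenic_votes <= 5:
            raise InputError("min_pathogenic_votes must be in [0, 5]")
        if unknown := set(self.allowed_impacts) - set(IMPACT_LEVELS):
            raise InputError(f"unknown impact levels: {sorted(unknown)}")


@dataclass(frozen=True)
class AuditRecord:
    """Which criteria a variant passed; values are 'pass', 'fail' or
    'missing' (missing annotation counts as a failure)."""

    variant: AnnotatedVariant
    criteria: dict[str, str]
    votes: int
    selected: bool


def pathogenicity_calls(variant: AnnotatedVariant) -> dict[str, bool | None]:
    """Per-predictor votes; ``None`` marks a missing score."""
    mt = variant.mutation_taster.strip() if variant.mutation_taster else None
    return {
        "polyphen": None if variant.polyphen is None else variant.polyphen > POLYPHEN_MIN,
        "lrt": None if variant.lrt is None else variant.lrt < LRT_MAX,
        "sift": None if variant.sift is None else variant.sift < SIFT_MAX,
        "cadd": None if variant.cadd is None else variant.cadd > CADD_MIN,
        "mutation_taster": None if not mt else mt in MUTATION_TASTER_CALLS,
    }


def score_pathogenicity(variant: AnnotatedVariant) -> int:
    """Number of positive pathogenicity predictors (0-5). Thresholds are
    strict, so e.g. CADD exactly 15 does not vote; missing scores never
    vote."""
    return sum(1 for v in pathogenicity_calls(variant).values() if v is True)


def apply_hard_filters(
    variants: Sequence[AnnotatedVariant],
    config: PrioritizationConfig = PrioritizationConfig(),
) -> list[AnnotatedVariant]:
    """Depth and population-frequency filters; preserves input order.

    A variant survives when ``total_reads >= min_total_reads`` and its
    highest gnomAD population AF is missing or <= ``max_gnomad_af``.
    """
    out = []
    for v in variants:
        if v.total_reads < config.min_total_reads:
            continue
        if v.gnomad_max_af is not None and v.gnomad_max_af > config.max_gnomad_af:
            continue
        out.append(v)
    return out


def _chrom_sort_key(chrom: str) -> tuple[int, int, str]:
    c = chrom.removeprefix("chr")
    if c.isdigit():
        return (0, int(c), "")
    return (1, 0, c)


def prioritize_variants(
    variants: Sequence[AnnotatedVariant],
    config: PrioritizationConfig = PrioritizationConfig(),
    apply_hard: bool = True,
) -> tuple[list[AnnotatedVariant], list[AuditRecord]]:
    """Full cascade; returns (selected variants, per-variant audit trail).

    Selected variants are ranked by (votes descending, WES VAF ascending,
    genomic position); records are never mutated, and the output is always
    a subset of the input.
    """
    pool = apply_hard_filters(variants, config) if apply_hard else list(variants)
    pool_set = {id(v) for v in pool}
    audit: list[AuditRecord] = []
    selected: list[tuple[tuple, AnnotatedVariant]] = []
    for v in variants:
        criteria: dict[str, str] = {}
        if id(v) not in pool_set:
            criteria["hard_filters"] = "fail"
            audit.append(AuditRecord(v, criteria, score_pathogenicity(v), False))
            continue
        criteria["hard_filters"] = "pass"
        criteria["impact"] = (
            "pass" if v.impact in config.allowed_impacts else "fail"
        )
        votes = score_pathogenicity(v)
        criteria["pathogenic_votes"] = (
            "pass" if votes >= config.min_pathogenic_votes else "fail"
        )
        if config.require_cosmic:
            criteria["cosmic"] = (
                "pass" if v.cosmic_id else
                ("missing" if v.cosmic_id is None else "fail")
            )
        if config.max_wes_vaf_percent is not None:
            vaf = v.wes_vaf_percent
            criteria["wes_vaf"] = (
                "pass" if vaf <= config.max_wes_vaf_percent else "fail"
            )
        if config.require_both_callers:
            if v.in_both_callers is None:
                criteria["both_callers"] = "missing"
            else:
                criteria["both_callers"] = "pass" if v.in_both_callers else "fail"
        ok = all(s == "pass" for s in criteria.values())
        audit.append(AuditRecord(v, criteria, votes, ok))
        if ok:
            key = (-votes, v.wes_vaf_percent, _chrom_sort_key(v.chrom), v.pos)
            selected.append((key, v))
    selected.sort(key=lambda kv: kv[0])
    return [v for _, v in selected], audit
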