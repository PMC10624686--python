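"""Design and validation of SuperSelective ddPCR assays.

A SuperSelective primer (SSP) discriminates a single-nucleotide variant by
its architecture: a long 5' anchor that hybridizes stably to the target, a
short 3' foot that carries the interrogated nucleotide (matching the
mutant allele) and gates extension, and an A/T bridge between them that
forms an asymmetric single-stranded bubble with the non-complementary
intervening template. The absolute number of mutant copies measured with
the SSP is normalized by total copies measured with a standard primer pair
that reuses the SSP anchor.

All sequences are 5'->3' on their own strand; reverse designs are
constructed on the reverse complement of the template and reported 5'->3'.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .errors import DesignError, GeometryError, InputError, StrategyError
from .seq import (
    gc_fraction,
    is_complementary,
    iupac_regex,
    iupac_reverse_complement,
    reverse_complement,
    validate_dna,
)
from .strategy import FOOT_STRATEGIES, StrategySpec
from .thermo import DEFAULT_THERMO, ThermoParams, compute_tm

MAX_TEMPLATE_LENGTH = 200
MAX_STANDARD_AMPLICON = 100
DEFAULT_TM_TOLERANCE_C = 2.0
DEFAULT_MAX_COMPLEMENTARY_RUN = 3


class Direction(str, Enum):
    FORWARD = "forward"
    REVERSE = "reverse"


@dataclass(frozen=True)
class VariantSpec:
    """A single-nucleotide variant to be interrogated."""

    gene_symbol: str
    hgvs_c: str
    ref_allele: str
    alt_allele: str
    chrom: str | None = None
    position: int | None = None  # 1-based genomic coordinate

    def __post_init__(self) -> None:
        for name in ("ref_allele", "alt_allele"):
            allele = getattr(self, name)
            if allele not in ("A", "C", "G", "T"):
                raise InputError(f"{name} must be one of A/C/G/T, got {allele!r}")
        if self.ref_allele == self.alt_allele:
            raise InputError("ref_allele and alt_allele must differ")


@dataclass(frozen=True)
class AmpliconTemplate:
    """Top-strand amplicon sequence with the interrogated position marked.

    ``variant_offset`` is the 0-based index of the variant in ``sequence``;
    the template carries the reference allele there.
    """

    sequence: str
    variant_offset: int
    variant: VariantSpec

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_dna(self.sequence, "template"))
        if len(self.sequence) > MAX_TEMPLATE_LENGTH:
            raise InputError(
                f"template longer than {MAX_TEMPLATE_LENGTH} nt "
                f"({len(self.sequence)})"
            )
        if not 0 <= self.variant_offset < len(self.sequence):
            raise InputError("variant_offset outside template")
        found = self.sequence[self.variant_offset]
        if found != self.variant.ref_allele:
            raise InputError(
                f"template base at variant_offset is {found}, expected "
                f"reference allele {self.variant.ref_allele}"
            )

    @property
    def mutant_sequence(self) -> str:
        """Template with the alternative allele substituted."""
        s = self.sequence
        i = self.variant_offset
        return s[:i] + self.variant.alt_allele + s[i + 1:]

    def working_strand(self, direction: Direction) -> tuple[str, int, str, str]:
        """(strand 5'->3', variant offset, ref base, alt base) for a design
        direction. Reverse designs operate on the reverse complement."""
        if direction == Direction.FORWARD:
            return (
                self.sequence,
                self.variant_offset,
                self.variant.ref_allele,
                self.variant.alt_allele,
            )
        rc = reverse_complement(self.sequence)
        off = len(self.sequence) - 1 - self.variant_offset
        return (
            rc,
            off,
            reverse_complement(self.variant.ref_allele),
            reverse_complement(self.variant.alt_allele),
        )


@dataclass(frozen=True)
class SuperSelectivePrimer:
    """Anchor + bridge + foot, 5'->3'."""

    anchor: str
    bridge: str
    foot: str
    direction: Direction
    strategy: StrategySpec

    @property
    def full_sequence(self) -> str:
        return self.anchor + self.bridge + self.foot

    @property
    def interrogated_base(self) -> str:
        return self.foot[self.strategy.interrogated_index]

    def check_invariants(self) -> None:
        """Raise if segment lengths or composition contradict the strategy.

        Kept out of ``__post_init__`` so that primers transcribed from a
        published table can be represented verbatim and audited by
        :func:`validate_assay` even when the printed segments are
        internally inconsistent.
        """
        if len(self.anchor) != self.strategy.anchor_len:
            raise StrategyError(
                f"anchor length {len(self.anchor)} != strategy "
                f"{self.strategy.anchor_len}"
            )
        if len(self.bridge) != self.strategy.bridge_len:
            raise StrategyError(
                f"bridge length {len(self.bridge)} != strategy "
                f"{self.strategy.bridge_len}"
            )
        if len(self.foot) != self.strategy.foot_len:
            raise StrategyError(
                f"foot length {len(self.foot)} != strategy {self.strategy.foot_len}"
            )
        if set(self.bridge) - {"A", "T"}:
            raise StrategyError("bridge must contain only A and T")


@dataclass(frozen=True)
class StandardPrimerPair:
    """Standard pair for total-copy quantification: the SSP anchor reused
    plus a complementary primer on the opposite strand."""

    anchor_primer: str
    complementary_primer: str
    amplicon_len: int
    tm_anchor: float
    tm_complementary: float


@dataclass(frozen=True)
class CheckResult:
    name: str
    passed: bool
    message: str
    structural: bool = True


@dataclass(frozen=True)
class ValidationReport:
    checks: tuple[CheckResult, ...]

    @property
    def overall(self) -> bool:
        return all(c.passed for c in self.checks)

    @property
    def structural_ok(self) -> bool:
        return all(c.passed for c in self.checks if c.structural)

    def failures(self) -> list[CheckResult]:
        return [c for c in self.checks if not c.passed]

    def __getitem__(self, name: str) -> CheckResult:
        for c in self.checks:
            if c.name == name:
                return c
        raise KeyError(name)


@dataclass(frozen=True)
class BridgeCheck:
    passed: bool
    longest_run: int


@dataclass(frozen=True)
class SpecificityHit:
    reference_id: str
    offset: int  # top-strand 0-based start of the matched window
    strand: str  # "+" or "-"
    mismatches: int


# ---------------------------------------------------------------------------
# SuperSelective primer construction


def _design_origin(strategy: StrategySpec, variant_offset: int) -> int:
    return (
        variant_offset
        - strategy.anchor_len
        - strategy.intervening_len
        - strategy.foot_5p
    )


def default_bridge(length: int, start: str = "A") -> str:
    """Alternating A/T bridge of ``length`` starting with ``start``."""
    pair = "AT" if start == "A" else "TA"
    return (pair * (length // 2 + 1))[:length]


def design_superselective(
    template: AmpliconTemplate,
    strategy: StrategySpec,
    direction: Direction | str,
    bridge_override: str | None = None,
    max_complementary_run: int = DEFAULT_MAX_COMPLEMENTARY_RUN,
) -> SuperSelectivePrimer:
    """Construct the SuperSelective primer for ``template`` under ``strategy``.

    The anchor copies ``anchor_len`` template bases ending
    ``intervening_len + foot_5p`` bases 5' of the variant; the foot copies
    the ``foot_len`` bases around the variant with the interrogated
    position replaced by the alternative allele. The bridge is
    ``bridge_override`` if given, otherwise an alternating-A/T sequence of
    the strategy's bridge length, starting with A unless that start
    violates the bubble-asymmetry check against the intervening template
    (then starting with T).
    """
    direction = Direction(direction)
    strand, voff, _, alt = template.working_strand(direction)
    origin = _design_origin(strategy, voff)
    end = voff + 1 + strategy.foot_3p
    if origin < 0 or end > len(strand):
        raise GeometryError(
            f"strategy {strategy.notation()} does not fit the template in "
            f"{direction.value} direction: needs bases {origin}..{end} of a "
            f"{len(strand)}-nt strand"
        )
    anchor = strand[origin:origin + strategy.anchor_len]
    intervening = strand[
        origin + strategy.anchor_len: origin + strategy.anchor_len
        + strategy.intervening_len
    ]
    foot = strand[voff - strategy.foot_5p: voff] + alt + strand[voff + 1: end]
    if bridge_override is not None:
        bridge = validate_dna(bridge_override, "bridge_override")
    else:
        bridge = default_bridge(strategy.bridge_len, "A")
        if not check_bridge_asymmetry(
            bridge, intervening, max_complementary_run
        ).passed:
            alt_bridge = default_bridge(strategy.bridge_len, "T")
            if check_bridge_asymmetry(
                alt_bridge, intervening, max_complementary_run
            ).passed:
                bridge = alt_bridge
    primer = SuperSelectivePrimer(anchor, bridge, foot, direction, strategy)
    if bridge_override is None:
        primer.check_invariants()
    return primer


def intervening_segment(
    template: AmpliconTemplate, strategy: StrategySpec, direction: Direction | str
) -> str:
    """The template bases bridged over by the bubble, 5'->3' on the design
    strand."""
    strand, voff, _, _ = template.working_strand(Direction(direction))
    origin = _design_origin(strategy, voff)
    start = origin + strategy.anchor_len
    return strand[start:start + strategy.intervening_len]


# ---------------------------------------------------------------------------
# Bridge asymmetry


def check_bridge_asymmetry(
    bridge: str,
    intervening_template: str,
    max_complementary_run: int = DEFAULT_MAX_COMPLEMENTARY_RUN,
) -> BridgeCheck:
    """Longest contiguous Watson-Crick complementary run between the bridge
    and the intervening template in antiparallel register.

    The bubble stays open only if no alignment of the two single strands
    can zip up a stable stem; the check fails when the longest run exceeds
    ``max_complementary_run`` (default 3).
    """
    b = validate_dna(bridge, "bridge")
    t = validate_dna(intervening_template, "intervening template")
    rev_t = t[::-1]  # antiparallel register
    longest = 0
    for shift in range(-(len(b) - 1), len(rev_t)):
        run = 0
        for i in range(len(b)):
            j = i + shift
            if 0 <= j < len(rev_t) and is_complementary(b[i], rev_t[j]):
                run += 1
                longest = max(longest, run)
            else:
                run = 0
    return BridgeCheck(longest <= max_complementary_run, longest)


# ---------------------------------------------------------------------------
# Standard primer pair


def design_standard_assay(
    template: AmpliconTemplate,
    anchor_primer: str,
    thermo: ThermoParams = DEFAULT_THERMO,
    tm_tolerance: float = DEFAULT_TM_TOLERANCE_C,
    max_amplicon: int = MAX_STANDARD_AMPLICON,
    primer_len_range: tuple[int, int] = (18, 28),
) -> StandardPrimerPair:
    """Pair the SSP anchor with a complementary primer on the opposite
    strand such that the amplicon is <= ``max_amplicon`` bp and the two Tm
    values agree within ``tm_tolerance`` degrees C.

    Among feasible candidates the pair with the closest Tm match is
    returned (ties broken toward the longer amplicon, then
    lexicographically).
    """
    anchor = validate_dna(anchor_primer, "anchor primer")
    seq = template.sequence
    on_top = seq.count(anchor)
    on_bottom = reverse_complement(seq).count(anchor)
    if on_top + on_bottom == 0:
        raise DesignError("anchor primer does not occur in the template")
    if on_top + on_bottom > 1:
        raise DesignError("anchor primer occurs more than once in the template")
    # Work on the strand the anchor sits on; the complementary primer is then
    # the reverse complement of a window downstream of the anchor.
    strand = seq if on_top else reverse_complement(seq)
    p = strand.index(anchor)
    tm_anchor = compute_tm(anchor, thermo)
    lo, hi = primer_len_range
    best: tuple[tuple[float, int, str], StandardPrimerPair] | None = None
    for end in range(p + len(anchor) + lo, min(len(strand), p + max_amplicon) + 1):
        amplicon_len = end - p
        for plen in range(lo, hi + 1):
            start = end - plen
            if start < p + len(anchor):
                continue  # primers must not overlap
            candidate = reverse_complement(strand[start:end])
            tm_c = compute_tm(candidate, thermo)
            delta = abs(tm_c - tm_anchor)
            if delta > tm_tolerance:
                continue
            key = (delta, -amplicon_len, candidate)
            if best is None or key < best[0]:
                best = (
                    key,
                    StandardPrimerPair(anchor, candidate, amplicon_len, tm_anchor, tm_c),
                )
    if best is None:
        raise DesignError(
            f"no complementary primer of length {lo}-{hi} within "
            f"{tm_tolerance} degC of the anchor Tm ({tm_anchor:.1f} degC) "
            f"yields an amplicon <= {max_amplicon} bp"
        )
    return best[1]


# ---------------------------------------------------------------------------
# Enumeration and ranking


def enumerate_designs(
    template: AmpliconTemplate,
    foot_strategies: Sequence[tuple[int, int]] = FOOT_STRATEGIES,
    anchor_len_range: tuple[int, int] = (18, 28),
    bridge_len_range: tuple[int, int] = (6, 10),
    intervening_len_range: tuple[int, int] = (4, 8),
    directions: Sequence[Direction | str] = (Direction.FORWARD, Direction.REVERSE),
    thermo: ThermoParams = DEFAULT_THERMO,
    target_tm: float = 60.0,
    max_complementary_run: int = DEFAULT_MAX_COMPLEMENTARY_RUN,
) -> list[SuperSelectivePrimer]:
    """All geometrically feasible SSP candidates, best first.

    Ranking: anchor Tm closeness to ``target_tm``, then the longest
    bridge/intervening complementary run (shorter is better), then foot GC
    fraction closeness to 0.5; deterministic tie-break on the full primer
    sequence.
    """
    ranked: list[tuple[tuple[float, int, float, str], SuperSelectivePrimer]] = []
    tm_cache: dict[str, float] = {}
    for direction in directions:
        for f5, f3 in foot_strategies:
            for a in range(anchor_len_range[0], anchor_len_range[1] + 1):
                for iv in range(
                    intervening_len_range[0], intervening_len_range[1] + 1
                ):
                    for b in range(bridge_len_range[0], bridge_len_range[1] + 1):
                        strategy = StrategySpec(a, b, iv, f5, f3)
                        try:
                            primer = design_superselective(
                                template,
                                strategy,
                                direction,
                                max_complementary_run=max_complementary_run,
                            )
                        except GeometryError:
                            continue
                        anchor = primer.anchor
                        if anchor not in tm_cache:
                            tm_cache[anchor] = compute_tm(anchor, thermo)
                        run = check_bridge_asymmetry(
                            primer.bridge,
                            intervening_segment(template, strategy, direction),
                            max_complementary_run,
                        )
                        if not run.passed:
                            continue
                        key = (
                            abs(tm_cache[anchor] - target_tm),
                            run.longest_run,
                            abs(gc_fraction(primer.foot) - 0.5),
                            primer.full_sequence,
                        )
                        ranked.append((key, primer))
    ranked.sort(key=lambda kv: kv[0])
    return [p for _, p in ranked]


# ---------------------------------------------------------------------------
# Validation


def validate_assay(
    ssp: SuperSelectivePrimer,
    pair: StandardPrimerPair | None,
    template: AmpliconTemplate,
    thermo: ThermoParams | None = DEFAULT_THERMO,
    tm_tolerance: float = DEFAULT_TM_TOLERANCE_C,
    max_complementary_run: int = DEFAULT_MAX_COMPLEMENTARY_RUN,
    max_amplicon: int = MAX_STANDARD_AMPLICON,
) -> ValidationReport:
    """Structural (and, when a pair is given, thermodynamic) audit of an
    assay. Failures are report entries, never exceptions, so printed
    designs with transcription inconsistencies can be diagnosed."""
    checks: list[CheckResult] = []
    strategy = ssp.strategy
    strand, voff, _, alt = template.working_strand(ssp.direction)
    mutant_strand = strand[:voff] + alt + strand[voff + 1:]
    origin = _design_origin(strategy, voff)
    end = voff + 1 + strategy.foot_3p
    geometry_ok = origin >= 0 and end <= len(strand)
    checks.append(
        CheckResult(
            "geometry",
            geometry_ok,
            "strategy fits the template around the variant"
            if geometry_ok
            else f"strategy needs strand bases {origin}..{end} "
            f"(strand length {len(strand)})",
        )
    )
    checks.append(
        CheckResult(
            "bridge_length",
            len(ssp.bridge) == strategy.bridge_len,
            f"bridge is {len(ssp.bridge)} nt, strategy says "
            f"{strategy.bridge_len} nt",
        )
    )
    checks.append(
        CheckResult(
            "bridge_composition",
            not set(ssp.bridge) - {"A", "T"},
            "bridge restricted to A/T",
        )
    )
    foot_len_ok = len(ssp.foot) == strategy.foot_len
    checks.append(
        CheckResult(
            "foot_length",
            foot_len_ok,
            f"foot is {len(ssp.foot)} nt, strategy says {strategy.foot_len} nt",
        )
    )
    if geometry_ok:
        expected_anchor = strand[origin:origin + strategy.anchor_len]
        checks.append(
            CheckResult(
                "anchor_matches_template",
                ssp.anchor == expected_anchor,
                f"anchor {ssp.anchor} vs template {expected_anchor}",
            )
        )
        foot_start = voff - strategy.foot_5p
        expected_foot = mutant_strand[foot_start:end]
        foot_mut_ok = ssp.foot == expected_foot
        checks.append(
            CheckResult(
                "foot_matches_mutant",
                foot_mut_ok,
                f"foot {ssp.foot} vs mutant template {expected_foot}",
            )
        )
        wt_segment = strand[foot_start:end]
        mismatches = (
            [i for i, (x, y) in enumerate(zip(ssp.foot, wt_segment)) if x != y]
            if foot_len_ok
            else []
        )
        single = mismatches == [strategy.interrogated_index]
        checks.append(
            CheckResult(
                "foot_single_mismatch_wildtype",
                single,
                f"foot/wild-type mismatches at {mismatches}; expected only "
                f"position {strategy.interrogated_index}",
            )
        )
        interrogated_ok = foot_len_ok and ssp.interrogated_base == alt
        checks.append(
            CheckResult(
                "interrogated_position",
                interrogated_ok,
                "interrogated base is the "
                + ("second-last" if strategy.foot_3p == 1 else "last")
                + " foot base and carries the alternative allele",
            )
        )
        intervening = strand[
            origin + strategy.anchor_len: origin + strategy.anchor_len
            + strategy.intervening_len
        ]
        bridge_check = check_bridge_asymmetry(
            ssp.bridge, intervening, max_complementary_run
        )
        checks.append(
            CheckResult(
                "bridge_asymmetry",
                bridge_check.passed,
                f"longest bridge/intervening complementary run "
                f"{bridge_check.longest_run} (max {max_complementary_run})",
            )
        )
    else:
        for name in (
            "anchor_matches_template",
            "foot_matches_mutant",
            "foot_single_mismatch_wildtype",
            "interrogated_position",
            "bridge_asymmetry",
        ):
            checks.append(
                CheckResult(name, False, "not evaluable: geometry check failed")
            )
    if pair is not None:
        checks.append(
            CheckResult(
                "amplicon_length",
                pair.amplicon_len <= max_amplicon,
                f"standard amplicon {pair.amplicon_len} bp (max {max_amplicon})",
            )
        )
        if thermo is not None:
            delta = abs(pair.tm_anchor - pair.tm_complementary)
            checks.append(
                CheckResult(
                    "tm_match",
                    delta <= tm_tolerance,
                    f"anchor/complementary Tm differ by {delta:.2f} degC "
                    f"(tolerance {tm_tolerance})",
                    structural=False,
                )
            )
    return ValidationReport(tuple(checks))


# ---------------------------------------------------------------------------
# Restriction-enzyme conflicts


def find_restriction_conflicts(
    amplicon: str, enzymes: Iterable[tuple[str, str]]
) -> list[str]:
    """Names of enzymes whose recognition site (IUPAC; either strand) occurs
    in the amplicon. The ddPCR workflow pre-digests the sample, so the
    chosen enzyme must not cut the target amplicon itself."""
    seq = validate_dna(amplicon, "amplicon")
    conflicts: list[str] = []
    for name, site in enzymes:
        pattern = iupac_regex(site)
        rc_site = iupac_reverse_complement(site)
        hit = bool(pattern.search(seq))
        if not hit and rc_site != site.upper():
            hit = bool(iupac_regex(rc_site).search(seq))
        if hit:
            conflicts.append(name)
    return conflicts


# ---------------------------------------------------------------------------
# In-silico specificity


def specificity_scan(
    primer: str,
    references: dict[str, str],
    max_mismatches: int = 2,
    require_3prime_match: int = 5,
) -> list[SpecificityHit]:
    """Mismatch-tolerant scan of ``primer`` against reference sequences.

    A window on either strand is a hit when it has at most
    ``max_mismatches`` mismatches overall and none within the primer's
    3'-terminal ``require_3prime_match`` bases (extension requires a
    perfectly paired 3' end). For a SuperSelective primer pass
    ``anchor + foot`` (the bridge never hybridizes); see
    :func:`ssp_scan_sequence`.
    """
    import numpy as np

    p = validate_dna(primer, "primer")
    if not references:
        raise InputError("references must be non-empty")
    k = len(p)
    if all(len(ref) < k for ref in references.values()):
        raise InputError("primer is longer than every reference sequence")
    n3 = min(require_3prime_match, k)
    p_arr = np.frombuffer(p.encode("ascii"), dtype=np.uint8)
    hits: list[SpecificityHit] = []
    for ref_id, ref_seq in references.items():
        ref = validate_dna(ref_seq, f"reference {ref_id}")
        if len(ref) < k:
            continue
        for strand, scan_seq in (("+", ref), ("-", reverse_complement(ref))):
            L = len(scan_seq)
            arr = np.frombuffer(scan_seq.encode("ascii"), dtype=np.uint8)
            windows = np.lib.stride_tricks.sliding_window_view(arr, k)
            neq = windows != p_arr
            # extension requires a perfectly paired 3'-terminal segment
            ok3 = ~neq[:, k - n3:].any(axis=1) if n3 else np.ones(len(windows), bool)
            mm = neq.sum(axis=1)
            for off in np.flatnonzero(ok3 & (mm <= max_mismatches)):
                top_offset = int(off) if strand == "+" else L - int(off) - k
                hits.append(SpecificityHit(ref_id, top_offset, strand, int(mm[off])))
    hits.sort(key=lambda h: (h.reference_id, h.offset, h.strand))
    return hits


def ssp_scan_sequence(ssp: SuperSelectivePrimer) -> str:
    """The hybridizing portion of an SSP for specificity scanning: anchor
    plus foot, bridge excluded."""
    return ssp.anchor + ssp.foot
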