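"""Packaged reference data: the seven characterized SP-ddPCR assays and
the prioritized variants they target, transcribed verbatim from the
source tables.

Some printed primer segments are internally inconsistent with their own
strategy notation (bridge lengths for ASNA1 and FABP4; a truncated
amplicon that cannot host the stated 28-nt anchor for NTRK2); they are
stored as printed, and :func:`spddpcr.assay_design.validate_assay` reports
the discrepancies rather than repairing them.  Table-extraction artifacts
also leave the predictor-vote counts fused with COSMIC identifiers for
some rows; votes are recorded only where unambiguous.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

from .assay_design import (
    AmpliconTemplate,
    Direction,
    SuperSelectivePrimer,
    VariantSpec,
)
from .errors import FormatError
from .strategy import StrategySpec, parse_strategy

AMPLICON_MARKER = re.compile(r"\(([ACGT])/([ACGT])\)")

#: Assays whose printed anchor/bridge/foot reconstruct exactly from the
#: printed amplicon and strategy notation.
INTERNALLY_CONSISTENT: frozenset[tuple[str, str]] = frozenset(
    {("APC", "c.4128T>A"), ("APC", "c.2626C>T"),
     ("LAMC3", "c.1241G>A"), ("NRXN3", "c.1421G>A")}
)


def split_marked_amplicon(marked: str) -> tuple[str, int, str, str]:
    """Split ``"...(R/A)..."`` into (plain sequence with the reference
    base, 0-based variant offset, ref, alt)."""
    m = AMPLICON_MARKER.search(marked)
    if m is None:
        raise FormatError(
            f"amplicon lacks a (ref/alt) marker: {marked[:30]}..."
        )
    ref, alt = m.group(1), m.group(2)
    seq = marked[: m.start()] + ref + marked[m.end():]
    return seq.upper(), m.start(), ref, alt


@dataclass(frozen=True)
class PublishedAssay:
    gene: str
    hgvs_c: str
    hgvs_c_alias: str | None
    chrom: str
    ref: str
    alt: str
    direction: Direction
    strategy: StrategySpec
    anchor: str
    bridge: str
    foot: str
    complementary_primer: str
    standard_primer: str
    amplicon_marked: str
    lod_percent: float
    lod_mean: float
    lod_sd: float
    lod_genomic_percent: float | None = None
    lod_genomic_mean: float | None = None
    lod_genomic_sd: float | None = None

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene, self.hgvs_c)

    @property
    def internally_consistent(self) -> bool:
        return self.key in INTERNALLY_CONSISTENT

    def template(self) -> AmpliconTemplate:
        seq, off, ref, alt = split_marked_amplicon(self.amplicon_marked)
        return AmpliconTemplate(
            seq, off,
            VariantSpec(self.gene, self.hgvs_c, ref, alt, chrom=self.chrom),
        )

    def ssp(self) -> SuperSelectivePrimer:
        """The printed SuperSelective primer, verbatim (invariants are not
        enforced; use validate_assay to audit)."""
        return SuperSelectivePrimer(
            self.anchor, self.bridge, self.foot, self.direction, self.strategy
        )

    def sheet_row(self):
        from .io import AssaySheetRow

        return AssaySheetRow(
            gene=self.gene,
            hgvs_c=self.hgvs_c,
            direction=self.direction.value,
            strategy=self.strategy.notation(),
            ssp_sequence=f"{self.anchor}-{self.bridge}-{self.foot}",
            complementary_primer=self.complementary_primer,
            standard_primer=self.standard_primer,
            amplicon=self.amplicon_marked,
        )


@dataclass(frozen=True)
class PublishedVariant:
    """One prioritized variant with its WES read counts and the ddPCR VAF
    measurements (mean +- SEM, %) in surrounding mucosa (sm), distal
    mucosa (dm), colonic lesion (cl) and peripheral blood (pbl)."""

    chrom: str
    ref: str
    alt: str
    annotation: str
    impact: str
    gene: str
    hgvs_c: str
    hgvs_c_alias: str | None
    group: str
    cosmic_raw: str
    cosmic_id: str | None
    votes: int | None
    wes_total_reads: int
    wes_variant_reads: int
    wes_vaf_percent: float
    sm_mean: float
    sm_sem: float
    dm_mean: float
    dm_sem: float
    cl_mean: float
    cl_sem: float
    pbl_mean: float
    pbl_sem: float


def _read_table(name: str) -> list[dict[str, str]]:
    with resources.files("spddpcr.data").joinpath(name).open(
        "r", encoding="utf-8"
    ) as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def _opt_float(s: str | None) -> float | None:
    return float(s) if s else None


@lru_cache(maxsize=1)
def published_assays() -> tuple[PublishedAssay, ...]:
    rows = _read_table("published_assays.tsv")
    out = []
    for r in rows:
        out.append(
            PublishedAssay(
                gene=r["gene"],
                hgvs_c=r["hgvs_c"],
                hgvs_c_alias=r["hgvs_c_alias"] or None,
                chrom=r["chrom"],
                ref=r["ref"],
                alt=r["alt"],
                direction=Direction(r["direction"]),
                strategy=parse_strategy(r["strategy"]),
                anchor=r["anchor"],
                bridge=r["bridge"],
                foot=r["foot"],
                complementary_primer=r["complementary_primer"],
                standard_primer=r["standard_primer"],
                amplicon_marked=r["amplicon"],
                lod_percent=float(r["lod_percent"]),
                lod_mean=float(r["lod_mean"]),
                lod_sd=float(r["lod_sd"]),
                lod_genomic_percent=_opt_float(r.get("lod_genomic_percent")),
                lod_genomic_mean=_opt_float(r.get("lod_genomic_mean")),
                lod_genomic_sd=_opt_float(r.get("lod_genomic_sd")),
            )
        )
    return tuple(out)


@lru_cache(maxsize=1)
def published_variants() -> tuple[PublishedVariant, ...]:
    rows = _read_table("published_variants.tsv")
    out = []
    for r in rows:
        out.append(
            PublishedVariant(
                chrom=r["chrom"], ref=r["ref"], alt=r["alt"],
                annotation=r["annotation"], impact=r["impact"],
                gene=r["gene"], hgvs_c=r["hgvs_c"],
                hgvs_c_alias=r["hgvs_c_alias"] or None,
                group=r["group"], cosmic_raw=r["cosmic_raw"],
                cosmic_id=r["cosmic_id"] or None,
                votes=int(r["votes"]) if r["votes"] else None,
                wes_total_reads=int(r["wes_total_reads"]),
                wes_variant_reads=int(r["wes_variant_reads"]),
                wes_vaf_percent=float(r["wes_vaf_percent"]),
                sm_mean=float(r["sm_mean"]), sm_sem=float(r["sm_sem"]),
                dm_mean=float(r["dm_mean"]), dm_sem=float(r["dm_sem"]),
                cl_mean=float(r["cl_mean"]), cl_sem=float(r["cl_sem"]),
                pbl_mean=float(r["pbl_mean"]), pbl_sem=float(r["pbl_sem"]),
            )
        )
    return tuple(out)


def assay_by_key(gene: str, hgvs_c: str) -> PublishedAssay:
    for a in published_assays():
        if a.gene == gene and a.hgvs_c == hgvs_c:
            return a
    raise KeyError(f"{gene} {hgvs_c}")
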