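"""File formats: FASTA templates, TSV assay sheets, CSV droplet counts,
TSV/VCF variant tables, results TSV, and the TOML run configuration.

Conventions: TSV (tab) for assay sheets, variant tables and results; CSV
(comma) for droplet well counts, mirroring instrument exports; UTF-8
throughout. All readers validate records and raise
:class:`~spddpcr.errors.FormatError` with row context on inconsistent
input.
"""

from __future__ import annotations

import csv
import tomllib
from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .assay_design import AmpliconTemplate, Direction, SuperSelectivePrimer
from .droplet_sim import Channel, PartitionConfig, ReplicateSet, SelectivityModel, WellCount
from .errors import FormatError, InputError
from .prioritize import AnnotatedVariant, PrioritizationConfig
from .published import split_marked_amplicon
from .strategy import parse_strategy
from .thermo import ThermoParams
from .quantify import VafMeasurement, LodEstimate


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """Named, upper-cased sequences; multi-record and line-wrap agnostic."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: dict[str, str], path, width: int = 70) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# Assay sheet (TSV)

ASSAY_SHEET_COLUMNS = (
    "gene", "hgvs_c", "direction", "strategy", "ssp_sequence",
    "complementary_primer", "standard_primer", "amplicon",
)


@dataclass(frozen=True)
class AssaySheetRow:
    """One assay: SuperSelective primer (segments joined by ``-``),
    companion primers, and the amplicon with its ``(ref/alt)`` marker."""

    gene: str
    hgvs_c: str
    direction: str
    strategy: str
    ssp_sequence: str
    complementary_primer: str
    standard_primer: str
    amplicon: str

    def segments(self) -> tuple[str, str, str]:
        parts = self.ssp_sequence.replace(" ", "").split("-")
        if len(parts) != 3:
            raise FormatError(
                f"ssp_sequence must be anchor-bridge-foot, got "
                f"{self.ssp_sequence!r}"
            )
        return (parts[0].upper(), parts[1].upper(), parts[2].upper())

    def template(self) -> AmpliconTemplate:
        from .assay_design import VariantSpec

        seq, off, ref, alt = split_marked_amplicon(self.amplicon)
        return AmpliconTemplate(
            seq, off, VariantSpec(self.gene, self.hgvs_c, ref, alt)
        )

    def ssp(self) -> SuperSelectivePrimer:
        anchor, bridge, foot = self.segments()
        return SuperSelectivePrimer(
            anchor, bridge, foot, Direction(self.direction),
            parse_strategy(self.strategy),
        )


def read_assay_sheet(path) -> list[AssaySheetRow]:
    """Parse an assay sheet; every row's strategy must parse and its
    amplicon must carry a (ref/alt) marker."""
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not set(ASSAY_SHEET_COLUMNS) <= set(
            reader.fieldnames
        ):
            missing = set(ASSAY_SHEET_COLUMNS) - set(reader.fieldnames or [])
            raise FormatError(f"assay sheet {path} missing columns {sorted(missing)}")
        rows = []
        for i, rec in enumerate(reader, start=2):
            row = AssaySheetRow(**{c: rec[c] for c in ASSAY_SHEET_COLUMNS})
            try:
                parse_strategy(row.strategy)
                row.template()
            except (FormatError, InputError, ValueError) as exc:
                raise FormatError(f"{path} row {i}: {exc}") from exc
            rows.append(row)
    if not rows:
        raise FormatError(f"assay sheet {path} has no rows")
    return rows


def write_assay_sheet(rows: Iterable[AssaySheetRow], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ASSAY_SHEET_COLUMNS)
        for row in rows:
            writer.writerow([getattr(row, c) for c in ASSAY_SHEET_COLUMNS])


# ---------------------------------------------------------------------------
# Well counts (CSV)

WELL_COLUMNS = ("well_id", "scenario", "channel", "positives", "accepted_droplets", "seed")

# Permissive mapping for instrument-style exports.
_WELL_ALIASES = {
    "well": "well_id",
    "well_id": "well_id",
    "sample": "scenario",
    "scenario": "scenario",
    "target": "channel",
    "channel": "channel",
    "positives": "positives",
    "accepteddroplets": "accepted_droplets",
    "accepted droplets": "accepted_droplets",
    "accepted_droplets": "accepted_droplets",
    "seed": "seed",
}

_CHANNEL_ALIASES = {
    "ssp": Channel.SSP,
    "superselective": Channel.SSP,
    "standard": Channel.STANDARD,
    "std": Channel.STANDARD,
}


@dataclass(frozen=True)
class WellRecord:
    scenario: str
    well: WellCount


def read_well_counts(path) -> list[WellRecord]:
    """Read a well-count CSV (simulator schema or a QuantaSoft-style
    export via column aliases), validated and ordered as on disk."""
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path} is empty")
        colmap: dict[str, str] = {}
        for name in reader.fieldnames:
            key = _WELL_ALIASES.get(name.strip().lower())
            if key is not None:
                colmap[key] = name
        for required in ("channel", "positives", "accepted_droplets"):
            if required not in colmap:
                raise FormatError(f"{path}: no column maps to {required!r}")
        records = []
        for i, rec in enumerate(reader, start=2):
            raw_channel = rec[colmap["channel"]].strip().lower()
            channel = _CHANNEL_ALIASES.get(raw_channel)
            if channel is None:
                raise FormatError(
                    f"{path} row {i}: unknown channel {rec[colmap['channel']]!r}"
                )
            try:
                positives = int(rec[colmap["positives"]])
                accepted = int(rec[colmap["accepted_droplets"]])
            except ValueError as exc:
                raise FormatError(f"{path} row {i}: non-integer count: {exc}") from exc
            try:
                well = WellCount(
                    positives, accepted, channel,
                    rec[colmap["well_id"]] if "well_id" in colmap else f"row{i}",
                )
            except InputError as exc:
                raise FormatError(f"{path} row {i}: {exc}") from exc
            scenario = rec[colmap["scenario"]] if "scenario" in colmap else ""
            records.append(WellRecord(scenario, well))
    if not records:
        raise FormatError(f"{path} contains no well counts")
    return records


def write_well_counts(series: Sequence[ReplicateSet], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(WELL_COLUMNS)
        for rs in series:
            for ssp_well, std_well in rs.pairs:
                for w in (ssp_well, std_well):
                    writer.writerow(
                        [w.well_id, rs.label, w.channel.value, w.positives,
                         w.accepted_droplets, rs.seed]
                    )


def pair_wells(records: Sequence[WellRecord]) -> dict[str, list[tuple[WellCount, WellCount]]]:
    """Group records by scenario and pair the i-th SSP well with the i-th
    STANDARD well of each scenario."""
    by_scenario: dict[str, dict[Channel, list[WellCount]]] = {}
    order: list[str] = []
    for rec in records:
        if rec.scenario not in by_scenario:
            by_scenario[rec.scenario] = {Channel.SSP: [], Channel.STANDARD: []}
            order.append(rec.scenario)
        by_scenario[rec.scenario][rec.well.channel].append(rec.well)
    out: dict[str, list[tuple[WellCount, WellCount]]] = {}
    for scenario in order:
        ssp = by_scenario[scenario][Channel.SSP]
        std = by_scenario[scenario][Channel.STANDARD]
        if len(ssp) != len(std):
            raise FormatError(
                f"scenario {scenario!r} has {len(ssp)} SSP wells but "
                f"{len(std)} STANDARD wells; cannot pair"
            )
        out[scenario] = list(zip(ssp, std))
    return out


# ---------------------------------------------------------------------------
# Variant tables

_VARIANT_REQUIRED = ("chrom", "pos", "ref", "alt", "gene_symbol", "hgvs_c",
                     "impact", "total_reads", "variant_reads")
_VARIANT_OPTIONAL_FLOATS = ("gnomad_max_af", "polyphen", "lrt", "sift", "cadd")


def _parse_variant_row(rec: dict[str, str], context: str) -> AnnotatedVariant:
    try:
        kwargs: dict = {
            "chrom": rec["chrom"],
            "pos": int(rec["pos"]),
            "ref": rec["ref"],
            "alt": rec["alt"],
            "gene_symbol": rec["gene_symbol"],
            "hgvs_c": rec["hgvs_c"],
            "impact": rec["impact"].upper(),
            "total_reads": int(rec["total_reads"]),
            "variant_reads": int(rec["variant_reads"]),
        }
        for col in _VARIANT_OPTIONAL_FLOATS:
            val = rec.get(col, "")
            kwargs[col] = float(val) if val not in ("", None, ".") else None
        mt = rec.get("mutation_taster", "")
        kwargs["mutation_taster"] = mt if mt not in ("", None, ".") else None
        cosmic = rec.get("cosmic_id", "")
        kwargs["cosmic_id"] = cosmic if cosmic not in ("", None, ".") else None
        both = rec.get("in_both_callers", "")
        if both in ("", None, "."):
            kwargs["in_both_callers"] = None
        else:
            kwargs["in_both_callers"] = str(both).strip().lower() in ("1", "true", "yes")
        return AnnotatedVariant(**kwargs)
    except (KeyError, ValueError, InputError) as exc:
        raise FormatError(f"{context}: {exc}") from exc


def read_variants_tsv(path) -> list[AnnotatedVariant]:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_VARIANT_REQUIRED) - set(reader.fieldnames or [])
        if missing:
            raise FormatError(f"{path} missing columns {sorted(missing)}")
        return [
            _parse_variant_row(rec, f"{path} row {i}")
            for i, rec in enumerate(reader, start=2)
        ]


#: INFO keys consumed from a minimal SNV-only VCF.
VCF_INFO_KEYS = {
    "GENE": "gene_symbol", "HGVSC": "hgvs_c", "IMPACT": "impact",
    "DP": "total_reads", "VD": "variant_reads", "GNOMAD_AF": "gnomad_max_af",
    "POLYPHEN": "polyphen", "LRT": "lrt", "SIFT": "sift", "CADD": "cadd",
    "MT": "mutation_taster", "COSMIC": "cosmic_id",
}


def read_variants_vcf(path) -> list[AnnotatedVariant]:
    """Minimal VCF reader (SNVs only) pulling annotations from INFO keys
    documented in :data:`VCF_INFO_KEYS`."""
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for i, rec in enumerate(vcf.fetch() if vcf.index else vcf, start=1):
            if rec.alts is None or len(rec.alts) != 1:
                raise FormatError(f"{path} record {i}: exactly one ALT required")
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                continue  # SNVs only
            info = rec.info
            row = {
                "chrom": rec.chrom,
                "pos": str(rec.pos),
                "ref": rec.ref,
                "alt": rec.alts[0],
            }
            for key, col in VCF_INFO_KEYS.items():
                if key in info:
                    val = info[key]
                    if isinstance(val, tuple):
                        val = val[0]
                    row[col] = str(val)
            for required in ("gene_symbol", "hgvs_c", "impact",
                             "total_reads", "variant_reads"):
                if required not in row:
                    raise FormatError(
                        f"{path} record {i}: missing INFO for {required}"
                    )
            out.append(_parse_variant_row(row, f"{path} record {i}"))
    return out


def write_variants_tsv(variants: Sequence[AnnotatedVariant], path) -> None:
    cols = [f.name for f in dc_fields(AnnotatedVariant)]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(cols)
        for v in variants:
            writer.writerow(
                ["" if getattr(v, c) is None else getattr(v, c) for c in cols]
            )


# ---------------------------------------------------------------------------
# Results TSV

RESULT_COLUMNS = ("assay", "sample", "vaf_mean", "vaf_sem", "n_replicates",
                  "lod", "call")


def write_results_tsv(
    rows: Sequence[dict], path, columns: Sequence[str] = RESULT_COLUMNS
) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(columns)
        for row in rows:
            writer.writerow([row.get(c, "") for c in columns])


def format_measurement(m: VafMeasurement, lod: LodEstimate | None = None) -> dict:
    """Report-layer rounding: VAF and LOD to 2 decimals."""
    out = {
        "vaf_mean": f"{m.mean:.2f}",
        "vaf_sem": f"{m.sem:.2f}",
        "n_replicates": m.n,
    }
    if lod is not None:
        from .quantify import classify_detection

        out["lod"] = f"{lod.lod_percent:.2f}"
        out["call"] = classify_detection(m, lod)
    return out


# ---------------------------------------------------------------------------
# Run configuration (TOML)


@dataclass(frozen=True)
class LodConfig:
    k: float = 3.0
    min_n: int = 9


@dataclass(frozen=True)
class RunConfig:
    thermo: ThermoParams = field(default_factory=ThermoParams)
    partition: PartitionConfig = field(default_factory=PartitionConfig)
    selectivity: SelectivityModel = field(default_factory=SelectivityModel)
    lod: LodConfig = field(default_factory=LodConfig)
    prioritize: PrioritizationConfig = field(default_factory=PrioritizationConfig)
    seed: int = 0
    log_level: str = "INFO"


_SECTION_TYPES = {
    "thermo": ThermoParams,
    "partition": PartitionConfig,
    "selectivity": SelectivityModel,
    "lod": LodConfig,
    "prioritize": PrioritizationConfig,
}


def load_config(path) -> RunConfig:
    """Load a TOML run configuration. Unknown sections or keys are
    rejected; absent keys keep their documented defaults."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    kwargs: dict = {}
    run = data.pop("run", {})
    if not isinstance(run, dict):
        raise FormatError("[run] must be a table")
    for key, value in run.items():
        if key not in ("seed", "log_level"):
            raise FormatError(f"unknown key run.{key}")
        kwargs[key] = value
    for section, cls in _SECTION_TYPES.items():
        if section not in data:
            continue
        table = data.pop(section)
        allowed = {f.name for f in dc_fields(cls)}
        unknown = set(table) - allowed
        if unknown:
            raise FormatError(
                f"unknown key(s) in [{section}]: {sorted(unknown)}"
            )
        if cls is PrioritizationConfig and "allowed_impacts" in table:
            table["allowed_impacts"] = frozenset(table["allowed_impacts"])
        try:
            kwargs[section] = cls(**table)
        except InputError as exc:
            raise FormatError(f"[{section}]: {exc}") from exc
    if data:
        raise FormatError(f"unknown config section(s): {sorted(data)}")
    return RunConfig(**kwargs)
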