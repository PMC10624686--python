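"""Droplet digital PCR partition simulator.

Emulates the plasmid-mixture experiments used to characterize
SuperSelective primer assays: a known number of mutant and wild-type
molecules is partitioned uniformly into droplets, each molecule renders
its droplet positive with a channel- and allele-dependent probability, and
the resulting positive/accepted counts feed the Poisson quantification in
:mod:`spddpcr.quantify`.

The model is deliberately simple: equal-probability multinomial
partitioning (no droplet-volume variation, no droplet loss — accepted
droplets equal the configured droplet count) and per-molecule activation.
Wild-type leak-through is modeled per wild-type molecule, so the 0%-VAF
background scales with input, matching the behavior of assay backgrounds
that sit near a fixed VAF rather than a fixed count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .errors import InputError


class Channel(str, Enum):
    SSP = "SSP"            # SuperSelective primer: mutant copies
    STANDARD = "STANDARD"  # standard primer pair: total copies


#: Dilution levels (% VAF) of the two characterization series.
LOW_SERIES: tuple[float, ...] = (1.00, 0.50, 0.25, 0.13, 0.00)
HIGH_SERIES: tuple[float, ...] = (100.0, 31.6, 10.0, 3.16, 1.00, 0.00)

DEFAULT_TOTAL_MOLECULES = 10_000
DEFAULT_REPLICATES = 3


@dataclass(frozen=True)
class PartitionConfig:
    """Droplet generation parameters (instrument conventions)."""

    n_droplets: int = 20_000
    droplet_volume_nl: float = 0.85
    reaction_volume_ul: float = 20.0

    def __post_init__(self) -> None:
        if self.n_droplets <= 0:
            raise InputError("n_droplets must be positive")
        if self.droplet_volume_nl <= 0 or self.reaction_volume_ul <= 0:
            raise InputError("volumes must be positive")
        if self.n_droplets * self.droplet_volume_nl > self.reaction_volume_ul * 1000:
            raise InputError("droplet volume total exceeds reaction volume")


@dataclass(frozen=True)
class MoleculeMix:
    mutant_copies: int
    wildtype_copies: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.mutant_copies < 0 or self.wildtype_copies < 0:
            raise InputError("molecule counts must be >= 0")

    @property
    def total(self) -> int:
        return self.mutant_copies + self.wildtype_copies


@dataclass(frozen=True)
class SelectivityModel:
    """Per-molecule activation probabilities.

    ``p_detect_mutant``: a mutant molecule renders its droplet positive in
    the SSP channel. ``p_leak_wildtype``: a wild-type molecule does so
    despite the foot mismatch (imperfect suppression). ``p_detect_standard``:
    any molecule renders its droplet positive in the standard channel.
    """

    p_detect_mutant: float = 0.95
    p_leak_wildtype: float = 0.001
    p_detect_standard: float = 0.95

    def __post_init__(self) -> None:
        for name in ("p_detect_mutant", "p_leak_wildtype", "p_detect_standard"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must be in [0, 1], got {v}")
        if self.p_leak_wildtype > self.p_detect_mutant:
            raise InputError("p_leak_wildtype must not exceed p_detect_mutant")


PERFECT_SELECTIVITY = SelectivityModel(1.0, 0.0, 1.0)


@dataclass(frozen=True)
class WellCount:
    positives: int
    accepted_droplets: int
    channel: Channel
    well_id: str = ""

    def __post_init__(self) -> None:
        if self.accepted_droplets <= 0:
            raise InputError("accepted_droplets must be > 0")
        if not 0 <= self.positives <= self.accepted_droplets:
            raise InputError("positives must be in [0, accepted_droplets]")


@dataclass(frozen=True)
class ReplicateSet:
    """Paired SSP/STANDARD wells for one scenario, with known truth."""

    label: str
    pairs: tuple[tuple[WellCount, WellCount], ...]
    true_vaf: float
    seed: int
    config: PartitionConfig = field(default_factory=PartitionConfig)

    def __post_init__(self) -> None:
        if not self.pairs:
            raise InputError("a ReplicateSet needs at least one well pair")


def _seed_sequence(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def partition_molecules(
    n_molecules: int,
    config: PartitionConfig = PartitionConfig(),
    seed=0,
) -> np.ndarray:
    """Multinomial allocation of molecules to droplets with equal
    probability. Counts always sum to ``n_molecules``."""
    if n_molecules < 0:
        raise InputError("n_molecules must be >= 0")
    rng = np.random.default_rng(_seed_sequence(seed))
    if n_molecules == 0:
        return np.zeros(config.n_droplets, dtype=np.int64)
    pvals = np.full(config.n_droplets, 1.0 / config.n_droplets)
    return rng.multinomial(n_molecules, pvals)


def simulate_well(
    mix: MoleculeMix,
    selectivity: SelectivityModel,
    channel: Channel | str,
    config: PartitionConfig = PartitionConfig(),
    seed=0,
    well_id: str = "",
) -> WellCount:
    """One droplet well: each molecule independently activates with the
    channel-appropriate probability; a droplet is positive iff it contains
    at least one activated molecule."""
    channel = Channel(channel)
    ss = _seed_sequence(seed)
    rng = np.random.default_rng(ss)
    if channel == Channel.SSP:
        activated = int(rng.binomial(mix.mutant_copies, selectivity.p_detect_mutant))
        activated += int(
            rng.binomial(mix.wildtype_copies, selectivity.p_leak_wildtype)
        )
    else:
        activated = int(rng.binomial(mix.total, selectivity.p_detect_standard))
    if activated == 0:
        positives = 0
    else:
        counts = rng.multinomial(
            activated, np.full(config.n_droplets, 1.0 / config.n_droplets)
        )
        positives = int(np.count_nonzero(counts))
    return WellCount(positives, config.n_droplets, channel, well_id)


def molecule_mix_for_vaf(true_vaf: float, total_molecules: int, label: str = "") -> MoleculeMix:
    """Mutant/wild-type split for a target VAF: mutant = round(total*vaf/100)."""
    if not 0.0 <= true_vaf <= 100.0:
        raise InputError(f"true_vaf must be in [0, 100], got {true_vaf}")
    if total_molecules < 0:
        raise InputError("total_molecules must be >= 0")
    mutant = round(total_molecules * true_vaf / 100.0)
    return MoleculeMix(mutant, total_molecules - mutant, label)


def simulate_assay_run(
    true_vaf: float,
    total_molecules: int = DEFAULT_TOTAL_MOLECULES,
    replicates: int = DEFAULT_REPLICATES,
    selectivity: SelectivityModel = SelectivityModel(),
    config: PartitionConfig = PartitionConfig(),
    seed=0,
    label: str | None = None,
) -> ReplicateSet:
    """Replicate SSP + STANDARD well pairs for one mixture.

    Per-replicate, per-channel random substreams are derived
    deterministically from the master seed.
    """
    if replicates < 1:
        raise InputError("replicates must be >= 1")
    label = label if label is not None else f"vaf_{true_vaf:g}"
    mix = molecule_mix_for_vaf(true_vaf, total_molecules, label)
    ss = _seed_sequence(seed)
    children = ss.spawn(2 * replicates)
    pairs = []
    for r in range(replicates):
        ssp = simulate_well(
            mix, selectivity, Channel.SSP, config, children[2 * r],
            well_id=f"{label}-r{r + 1}-ssp",
        )
        std = simulate_well(
            mix, selectivity, Channel.STANDARD, config, children[2 * r + 1],
            well_id=f"{label}-r{r + 1}-std",
        )
        pairs.append((ssp, std))
    master = int(ss.entropy) if isinstance(ss.entropy, int) else 0
    return ReplicateSet(label, tuple(pairs), true_vaf, master, config)


def simulate_dilution_series(
    vaf_levels: Sequence[float] = LOW_SERIES,
    total_molecules: int = DEFAULT_TOTAL_MOLECULES,
    replicates_per_level: int = DEFAULT_REPLICATES,
    selectivity: SelectivityModel = SelectivityModel(),
    config: PartitionConfig = PartitionConfig(),
    seed=0,
) -> list[ReplicateSet]:
    """One ReplicateSet per dilution level (defaults: the low series,
    triplicates, 10,000 molecules per reaction)."""
    if not vaf_levels:
        raise InputError("vaf_levels must be non-empty")
    ss = _seed_sequence(seed)
    children = ss.spawn(len(vaf_levels))
    return [
        simulate_assay_run(
            vaf, total_molecules, replicates_per_level, selectivity, config,
            children[i], label=f"vaf_{vaf:g}",
        )
        for i, vaf in enumerate(vaf_levels)
    ]


def make_fixture_suite(output_dir) -> list[str]:
    """Write the packaged assay sheet, wild-type templates (FASTA) and
    fixed-seed simulated dilution CSVs into ``output_dir``.

    Outputs are byte-stable across runs (fixed seeds).
    """
    from pathlib import Path

    from . import io as _io
    from . import published

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    assays = published.published_assays()
    sheet = out / "assay_sheet.tsv"
    _io.write_assay_sheet([a.sheet_row() for a in assays], sheet)
    written.append(str(sheet))

    fasta = out / "templates.fasta"
    _io.write_fasta(
        {f"{a.gene}_{a.hgvs_c}": a.template().sequence for a in assays}, fasta
    )
    written.append(str(fasta))

    for name, levels, fixture_seed in (
        ("dilution_low.csv", LOW_SERIES, 20001),
        ("dilution_high.csv", HIGH_SERIES, 20002),
    ):
        series = simulate_dilution_series(levels, seed=fixture_seed)
        path = out / name
        _io.write_well_counts(series, path)
        written.append(str(path))
    return written
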