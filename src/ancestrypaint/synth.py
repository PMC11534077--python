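"""Synthetic RFMIX2 output with known ground truth.

Haplotypes are tiled left-to-right with tracts whose lengths are
exponential (mean ``mean_tract_bp``, truncated at the chromosome end) and
whose ancestries are drawn independently from the configured proportions;
adjacent equal-code tracts are merged. Because draws are independent, the
expected genome-wide base-pair share of each ancestry equals the
configured proportions, which is what recovery tests check.

Windowed msp codes are the majority-by-bp ancestry within each window;
genetic positions are mapped at 1 cM per Mb.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .model import (
    AncestryCodebook,
    AncestryTract,
    GlobalAncestryTable,
    MspTable,
    MspWindow,
)
from . import rfmix2_io

DiploidTracts = dict[str, tuple[tuple[AncestryTract, ...], tuple[AncestryTract, ...]]]

DEFAULT_ANCESTRIES = ("MiddleEast", "Europe", "Africa")
DEFAULT_PROPORTIONS = (0.55, 0.30, 0.15)
DEFAULT_GENOME = tuple((str(i), 100_000_000) for i in range(1, 23))


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters for the fixture generator."""

    codebook: AncestryCodebook = field(
        default_factory=lambda: AncestryCodebook.from_names(DEFAULT_ANCESTRIES)
    )
    proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    mean_tract_bp: int = 5_000_000
    genome: tuple[tuple[str, int], ...] = DEFAULT_GENOME
    n_samples: int = 30
    window_bp: int = 500_000
    snps_per_window: int = 300
    seed: int = 1729

    def __post_init__(self) -> None:
        if len(self.proportions) != self.codebook.size:
            raise ValidationError(
                f"{len(self.proportions)} proportions for "
                f"{self.codebook.size} ancestries"
            )
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValidationError(
                f"proportions sum to {sum(self.proportions)!r}, expected 1"
            )
        if any(p < 0 for p in self.proportions):
            raise ValidationError("proportions must be non-negative")
        if self.mean_tract_bp <= 0 or self.window_bp <= 0:
            raise ValidationError("mean_tract_bp and window_bp must be positive")
        if any(length <= 0 for _, length in self.genome):
            raise ValidationError("chromosome lengths must be positive")
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if self.snps_per_window < 1:
            raise ValidationError("snps_per_window must be >= 1")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(f"S{i + 1:03d}" for i in range(self.n_samples))

    def chromosome_length(self, chromosome: str) -> int:
        for label, length in self.genome:
            if label == chromosome:
                return length
        raise ValidationError(f"chromosome {chromosome!r} not in genome layout")


def simulate_haplotype(
    config: SimulationConfig,
    chromosome: str,
    rng: np.random.Generator,
    sample_id: str = "",
    haplotype: int = 0,
) -> tuple[AncestryTract, ...]:
    """One haplotype's tracts fully covering ``[0, length_bp)``."""
    length = config.chromosome_length(chromosome)
    props = np.asarray(config.proportions)
    tracts: list[tuple[int, int, int]] = []  # (start, end, code)
    pos = 0
    while pos < length:
        draw = max(1, int(round(rng.exponential(config.mean_tract_bp))))
        end = min(pos + draw, length)
        code = int(rng.choice(config.codebook.size, p=props))
        if tracts and tracts[-1][2] == code:
            tracts[-1] = (tracts[-1][0], end, code)
        else:
            tracts.append((pos, end, code))
        pos = end
    return tuple(
        AncestryTract(chromosome, s, e, c, haplotype, sample_id)
        for s, e, c in tracts
    )


def simulate_cohort(config: SimulationConfig) -> DiploidTracts:
    """Diploid tract sets for all samples and all chromosomes, seeded."""
    rng = np.random.default_rng(config.seed)
    cohort: DiploidTracts = {}
    for sample_id in config.sample_ids:
        haps: list[tuple[AncestryTract, ...]] = []
        for hap in (0, 1):
            per_chrom: list[AncestryTract] = []
            for chrom, _ in config.genome:
                per_chrom.extend(
                    simulate_haplotype(config, chrom, rng, sample_id, hap)
                )
            haps.append(tuple(per_chrom))
        cohort[sample_id] = (haps[0], haps[1])
    return cohort


def _window_codes(
    tracts: Sequence[AncestryTract],
    chromosome: str,
    n_windows: int,
    window_bp: int,
    length: int,
    k: int,
) -> np.ndarray:
    """Majority-by-bp ancestry code per window for one haplotype."""
    bp = np.zeros((n_windows, k))
    for t in tracts:
        if t.chromosome != chromosome:
            continue
        w0 = t.start_bp // window_bp
        w1 = (t.end_bp - 1) // window_bp
        for w in range(w0, w1 + 1):
            ws = w * window_bp
            we = min(ws + window_bp, length)
            ov = min(t.end_bp, we) - max(t.start_bp, ws)
            if ov > 0:
                bp[w, t.code] += ov
    return bp.argmax(axis=1)  # argmax resolves ties toward the lower code


def tracts_to_msp(cohort: DiploidTracts, config: SimulationConfig) -> MspTable:
    """Window the cohort's tracts into a multi-chromosome msp table."""
    samples = tuple(cohort)
    k = config.codebook.size
    windows: list[MspWindow] = []
    for chrom, length in config.genome:
        n_win = math.ceil(length / config.window_bp)
        codes = np.empty((n_win, 2 * len(samples)), dtype=int)
        for j, sample_id in enumerate(samples):
            for hap in (0, 1):
                codes[:, 2 * j + hap] = _window_codes(
                    cohort[sample_id][hap], chrom, n_win, config.window_bp,
                    length, k,
                )
        for w in range(n_win):
            start = w * config.window_bp
            end = min(start + config.window_bp, length)
            windows.append(
                MspWindow(
                    chromosome=chrom,
                    start_bp=start,
                    end_bp=end,
                    start_cM=start / 1e6,
                    end_cM=end / 1e6,
                    n_snps=config.snps_per_window,
                    codes=tuple(int(c) for c in codes[w]),
                )
            )
    return MspTable(codebook=config.codebook, samples=samples, windows=tuple(windows))


def realized_q(
    cohort: DiploidTracts, config: SimulationConfig
) -> list[GlobalAncestryTable]:
    """Per-chromosome realized global-ancestry fractions (exact bp shares)."""
    samples = tuple(cohort)
    k = config.codebook.size
    tables: list[GlobalAncestryTable] = []
    for chrom, length in config.genome:
        fractions = np.zeros((len(samples), k))
        for j, sample_id in enumerate(samples):
            for hap in (0, 1):
                for t in cohort[sample_id][hap]:
                    if t.chromosome == chrom:
                        fractions[j, t.code] += t.length_bp
        fractions /= 2 * length
        tables.append(
            GlobalAncestryTable(
                chromosome=chrom,
                codebook=config.codebook,
                samples=samples,
                fractions=fractions,
            )
        )
    return tables


def genome_wide_fractions(
    cohort: DiploidTracts, config: SimulationConfig
) -> dict[str, np.ndarray]:
    """Per-sample ancestry bp shares over the whole diploid genome."""
    total = 2 * sum(length for _, length in config.genome)
    out: dict[str, np.ndarray] = {}
    for sample_id, haps in cohort.items():
        bp = np.zeros(config.codebook.size)
        for hap_tracts in haps:
            for t in hap_tracts:
                bp[t.code] += t.length_bp
        out[sample_id] = bp / total
    return out


@dataclass(frozen=True)
class FixtureResult:
    config: SimulationConfig
    cohort: DiploidTracts
    q_paths: tuple[Path, ...]
    msp_paths: tuple[Path, ...]
    manifest_path: Path
    prefix: str


def write_fixture(
    config: SimulationConfig,
    out_dir: str | os.PathLike,
    prefix: str = "fixture",
) -> FixtureResult:
    """Write ``<prefix>.chr<N>.rfmix.Q`` / ``.msp.tsv`` per chromosome plus
    a ground-truth manifest (seed, config, per-sample realized fractions)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(config)
    q_tables = realized_q(cohort, config)
    msp = tracts_to_msp(cohort, config)

    q_paths: list[Path] = []
    for table in q_tables:
        path = out_dir / f"{prefix}.chr{table.chromosome}.rfmix.Q"
        rfmix2_io.write_q(table, path)
        q_paths.append(path)

    msp_paths: list[Path] = []
    for chrom, _ in config.genome:
        sub = MspTable(
            codebook=msp.codebook,
            samples=msp.samples,
            windows=tuple(msp.windows_on(chrom)),
        )
        path = out_dir / f"{prefix}.chr{chrom}.msp.tsv"
        rfmix2_io.write_msp(sub, path)
        msp_paths.append(path)

    manifest_path = out_dir / f"{prefix}.manifest.tsv"
    realized = genome_wide_fractions(cohort, config)
    with manifest_path.open("w") as fh:
        fh.write(f"#seed\t{config.seed}\n")
        fh.write(f"#config\t{json.dumps(config_to_dict(config), sort_keys=True)}\n")
        fh.write("#sample\t" + "\t".join(config.codebook.names) + "\n")
        for sample_id in config.sample_ids:
            fh.write(
                sample_id + "\t"
                + "\t".join(f"{x:.6f}" for x in realized[sample_id]) + "\n"
            )
    return FixtureResult(
        config=config,
        cohort=cohort,
        q_paths=tuple(q_paths),
        msp_paths=tuple(msp_paths),
        manifest_path=manifest_path,
        prefix=prefix,
    )


# ---------------------------------------------------------------------------
# plain-text configuration

def config_to_dict(config: SimulationConfig) -> dict:
    return {
        "ancestries": list(config.codebook.names),
        "proportions": list(config.proportions),
        "mean_tract_bp": config.mean_tract_bp,
        "chromosomes": [[label, length] for label, length in config.genome],
        "n_samples": config.n_samples,
        "window_bp": config.window_bp,
        "snps_per_window": config.snps_per_window,
        "seed": config.seed,
    }


def config_from_dict(data: Mapping) -> SimulationConfig:
    kwargs: dict = {}
    if "ancestries" in data:
        kwargs["codebook"] = AncestryCodebook.from_names(data["ancestries"])
    if "proportions" in data:
        kwargs["proportions"] = tuple(float(p) for p in data["proportions"])
    if "chromosomes" in data:
        kwargs["genome"] = tuple(
            (str(label), int(length)) for label, length in data["chromosomes"]
        )
    for key in ("mean_tract_bp", "n_samples", "window_bp", "snps_per_window", "seed"):
        if key in data:
            kwargs[key] = int(data[key])
    return SimulationConfig(**kwargs)


def load_config(path: str | os.PathLike, seed: int | None = None) -> SimulationConfig:
    """Load a YAML simulation config; ``seed`` overrides the file's seed."""
    import yaml

    with Path(path).open() as fh:
        data = yaml.safe_load(fh) or {}
    config = config_from_dict(data)
    if seed is not None:
        config = replace(config, seed=seed)
    return config
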