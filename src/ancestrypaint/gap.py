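"""Global Ancestry Painting: combine per-chromosome Q tables, average per
individual, sort, and render the stacked bar plot."""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import FormatError, ValidationError
from .model import (
    AncestryCodebook,
    GlobalAncestryTable,
    MeanAncestryRecord,
    MeanAncestryTable,
    Palette,
)
from .rfmix2_io import merge_codebooks

logger = logging.getLogger(__name__)

MAX_DISPLAY_COMPONENTS = 10


def combine_and_average(
    tables: Sequence[GlobalAncestryTable],
    weight_by_snps: Sequence[float] | None = None,
) -> MeanAncestryTable:
    """Average each sample's ancestry fractions across chromosomes.

    The mean is unweighted by default: every chromosome where a sample
    appears counts equally. ``weight_by_snps`` optionally supplies one
    positive weight per table for a weighted mean.

    Samples missing from some chromosomes are averaged over the
    chromosomes where they do appear; the count is recorded per sample.
    """
    if not tables:
        raise ValidationError("combine_and_average requires at least one table")
    codebook = merge_codebooks(
        [t.codebook for t in tables], labels=[t.chromosome for t in tables]
    )
    if weight_by_snps is not None:
        if len(weight_by_snps) != len(tables):
            raise ValidationError(
                f"{len(weight_by_snps)} weights for {len(tables)} tables"
            )
        if any(w <= 0 for w in weight_by_snps):
            raise ValidationError("chromosome weights must be positive")
        weights = list(weight_by_snps)
    else:
        weights = [1.0] * len(tables)

    order: list[str] = []
    acc: dict[str, np.ndarray] = {}
    wsum: dict[str, float] = {}
    nchrom: dict[str, int] = {}
    full = {s for t in tables for s in t.samples}
    for table, w in zip(tables, weights):
        for sample, row in zip(table.samples, table.fractions):
            if sample not in acc:
                order.append(sample)
                acc[sample] = np.zeros(codebook.size)
                wsum[sample] = 0.0
                nchrom[sample] = 0
            acc[sample] += w * row
            wsum[sample] += w
            nchrom[sample] += 1
    for sample in order:
        if nchrom[sample] < len(tables):
            logger.warning(
                "sample %s appears on %d of %d chromosomes; averaging over "
                "those only",
                sample,
                nchrom[sample],
                len(tables),
            )
    assert full == set(order)
    records = tuple(
        MeanAncestryRecord(
            sample_id=s,
            mean_fractions=tuple(acc[s] / wsum[s]),
            n_chromosomes_used=nchrom[s],
        )
        for s in order
    )
    return MeanAncestryTable(codebook=codebook, records=records)


def sort_by_ancestry(table: MeanAncestryTable, ancestry_name: str) -> MeanAncestryTable:
    """Reorder records by one mean component, largest first.

    Ties are broken by sample id, ascending lexicographic. The input table
    is left unmodified.
    """
    k = table.codebook.code_of(ancestry_name)
    ordered = sorted(
        table.records, key=lambda r: (-r.mean_fractions[k], r.sample_id)
    )
    return MeanAncestryTable(codebook=table.codebook, records=tuple(ordered))


# ---------------------------------------------------------------------------
# intermediate table file

def write_gap_table(table: MeanAncestryTable, path: str | os.PathLike) -> None:
    """TSV with header ``#sample <anc1> ... <ancK> n_chroms``."""
    if not table.records:
        raise ValidationError("mean ancestry table is empty; nothing to write")
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            "#sample\t" + "\t".join(table.codebook.names) + "\tn_chroms\n"
        )
        for r in table.records:
            fh.write(
                r.sample_id
                + "\t"
                + "\t".join(f"{x:.6f}" for x in r.mean_fractions)
                + f"\t{r.n_chromosomes_used}\n"
            )


def read_gap_table(path: str | os.PathLike) -> MeanAncestryTable:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#sample\t") or not header.endswith("\tn_chroms"):
            raise FormatError(
                f"{path}: header must be '#sample <ancestries> n_chroms', got "
                f"{header[:80]!r}"
            )
        names = header.split("\t")[1:-1]
        if not names:
            raise FormatError(f"{path}: header names no ancestries")
        codebook = AncestryCodebook.from_names(names)
        records: list[MeanAncestryRecord] = []
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != len(names) + 2:
                raise FormatError(
                    f"{path}: line {lineno}: {len(fields)} fields, expected "
                    f"{len(names) + 2}"
                )
            records.append(
                MeanAncestryRecord(
                    sample_id=fields[0],
                    mean_fractions=tuple(float(x) for x in fields[1:-1]),
                    n_chromosomes_used=int(fields[-1]),
                )
            )
    if not records:
        raise FormatError(f"{path}: no records (nothing to plot)")
    return MeanAncestryTable(codebook=codebook, records=tuple(records))


# ---------------------------------------------------------------------------
# rendering

@dataclass(frozen=True)
class GapRenderInfo:
    """What was drawn: bar and legend counts for structural checks."""

    n_bars: int
    legend_names: tuple[str, ...]
    undisplayed_names: tuple[str, ...]
    out_path: Path


def render_gap(
    table: MeanAncestryTable,
    palette: Palette,
    out_path: str | os.PathLike,
    fmt: str = "pdf",
) -> GapRenderInfo:
    """Render one stacked bar per individual, in table order.

    Segment heights are proportional to mean fractions; a legend lists one
    entry per displayed ancestry; components beyond the 10th are not drawn
    and their mass is omitted (logged, not renormalized).
    """
    from ._figutils import SUPPORTED_FORMATS_GAP, save_figure
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    if fmt not in SUPPORTED_FORMATS_GAP:
        raise ValidationError(
            f"unsupported format {fmt!r} for global ancestry plot; expected "
            f"one of {SUPPORTED_FORMATS_GAP}"
        )
    if not table.records:
        raise ValidationError("mean ancestry table is empty; nothing to plot")
    k = table.codebook.size
    shown = min(k, MAX_DISPLAY_COMPONENTS)
    if len(palette.entries) < shown:
        raise ValidationError(
            f"palette covers {len(palette.entries)} components, need {shown}"
        )
    undisplayed = table.codebook.names[MAX_DISPLAY_COMPONENTS:]
    if undisplayed:
        logger.warning(
            "%d ancestry components beyond the 10th are not displayed: %s",
            len(undisplayed),
            ", ".join(undisplayed),
        )

    n = len(table.records)
    width_units = max(800, 40 * n)
    fig, ax = plt.subplots(figsize=(width_units / 100, 6.0), dpi=100)
    x = np.arange(n)
    fractions = np.array([r.mean_fractions for r in table.records])
    bottoms = np.zeros(n)
    legend_names: list[str] = []
    for comp in range(shown):
        name, color = palette.entries[comp]
        bars = ax.bar(
            x, fractions[:, comp], bottom=bottoms, width=0.85, color=color,
            label=name,
        )
        for i, patch in enumerate(bars.patches):
            patch.set_gid(f"gapbar_{i}_{comp}")
        bottoms += fractions[:, comp]
        legend_names.append(name)
    ax.set_xticks(x)
    ax.set_xticklabels([r.sample_id for r in table.records], rotation=90, fontsize=7)
    ax.set_ylabel("mean ancestry fraction")
    ax.set_ylim(0, 1)
    ax.set_xlim(-0.75, n - 0.25)
    handles = [
        Rectangle((0, 0), 1, 1, color=palette.entries[i][1]) for i in range(shown)
    ]
    leg = ax.legend(
        handles, legend_names, loc="center left", bbox_to_anchor=(1.01, 0.5),
        frameon=False,
    )
    for patch, name in zip(leg.get_patches(), legend_names):
        patch.set_gid(f"legendentry_{name}")
    fig.subplots_adjust(left=0.06, right=0.84, bottom=0.22, top=0.95)
    written = save_figure(fig, out_path, fmt)
    return GapRenderInfo(
        n_bars=n,
        legend_names=tuple(legend_names),
        undisplayed_names=tuple(undisplayed),
        out_path=written,
    )
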