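"""Local Ancestry Painting: window-to-tract conversion, color assignment,
and diploid karyogram rendering at 4k resolution (4210 x 1663)."""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .errors import ValidationError
from .model import (
    AncestryCodebook,
    AncestryTract,
    MspTable,
    Palette,
    RegionHighlight,
    chrom_sort_key,
)
from .rfmix2_io import merge_codebooks

logger = logging.getLogger(__name__)

#: Canvas size of the karyogram, in pixels for raster output.
CANVAS_WIDTH = 4210
CANVAS_HEIGHT = 1663

#: Default color sequence assigned to ancestry components in codebook order.
#: The first three (orange, purple, blue) follow the toolkit's conventional
#: Middle East / Europe / sub-Saharan Africa scheme.
DEFAULT_COLORS = (
    "#FF8C00",  # orange
    "#800080",  # purple
    "#1E90FF",  # blue
    "#228B22",
    "#DC143C",
    "#8B4513",
    "#20B2AA",
    "#FF69B4",
    "#708090",
    "#BDB76B",
)

MAX_COLORS = 10


def windows_to_tracts(
    msp: MspTable, sample_id: str, haplotype: int
) -> tuple[AncestryTract, ...]:
    """Merge consecutive equal-code abutting windows into maximal tracts.

    A coordinate gap between windows starts a new tract even when the code
    is unchanged, so missing-data regions stay uncovered. The output
    exactly covers the union of the haplotype's window intervals.
    """
    col = msp.haplotype_column(sample_id, haplotype)
    tracts: list[AncestryTract] = []
    cur_chrom: str | None = None
    cur_start = cur_end = cur_code = 0
    for w in msp.windows:
        code = w.codes[col]
        if (
            cur_chrom == w.chromosome
            and cur_end == w.start_bp
            and cur_code == code
        ):
            cur_end = w.end_bp
            continue
        if cur_chrom is not None:
            tracts.append(
                AncestryTract(cur_chrom, cur_start, cur_end, cur_code,
                              haplotype, sample_id)
            )
        cur_chrom, cur_start, cur_end, cur_code = (
            w.chromosome, w.start_bp, w.end_bp, code,
        )
    if cur_chrom is not None:
        tracts.append(
            AncestryTract(cur_chrom, cur_start, cur_end, cur_code,
                          haplotype, sample_id)
        )
    return tuple(tracts)


def combine_msp(tables: Sequence[MspTable]) -> MspTable:
    """Concatenate per-chromosome msp tables into one multi-chromosome table.

    All tables must share the codebook and the sample list (same order).
    """
    if not tables:
        raise ValidationError("combine_msp requires at least one table")
    labels = [",".join(t.chromosomes) or "?" for t in tables]
    codebook = merge_codebooks([t.codebook for t in tables], labels=labels)
    samples = tables[0].samples
    for t, label in zip(tables[1:], labels[1:]):
        if t.samples != samples:
            raise ValidationError(
                f"sample list mismatch between chromosome files {labels[0]} "
                f"and {label}"
            )
    ordered = sorted(
        tables, key=lambda t: chrom_sort_key(t.windows[0].chromosome) if t.windows else (2, 0, "")
    )
    windows = tuple(w for t in ordered for w in t.windows)
    return MspTable(codebook=codebook, samples=samples, windows=windows)


def build_palette(
    codebook: AncestryCodebook,
    user_colors: Sequence[str] | None = None,
    background_color: str = "#FFFFFF",
) -> Palette:
    """Assign colors to ancestry components in codebook order.

    At most 10 components receive a color; any beyond the 10th are logged
    as undisplayed. User-supplied colors must number exactly
    ``min(K, 10)`` and be distinct.
    """
    shown = min(codebook.size, MAX_COLORS)
    undisplayed = codebook.names[MAX_COLORS:]
    if undisplayed:
        logger.warning(
            "%d ancestry components beyond the 10th will not be displayed: %s",
            len(undisplayed),
            ", ".join(undisplayed),
        )
    if user_colors is not None:
        if len(user_colors) != shown:
            raise ValidationError(
                f"{len(user_colors)} colors supplied for {shown} displayable "
                f"ancestry components; supply exactly {shown}"
            )
        colors = tuple(user_colors)
    else:
        colors = DEFAULT_COLORS[:shown]
    entries = tuple(zip(codebook.names[:shown], colors))
    return Palette(entries=entries, background_color=background_color)


def chromosome_lengths(
    msp_tables: Sequence[MspTable],
    override: str | os.PathLike | None = None,
) -> dict[str, int]:
    """Per-chromosome length: max observed window end, or a larger override.

    ``override`` is a 2-column TSV (chrom, length). An override smaller
    than the observed maximum end is an error.
    """
    if not msp_tables:
        raise ValidationError("chromosome_lengths requires at least one table")
    observed: dict[str, int] = {}
    for table in msp_tables:
        for w in table.windows:
            observed[w.chromosome] = max(observed.get(w.chromosome, 0), w.end_bp)
    if override is not None:
        sizes = _read_chrom_sizes(override)
        for chrom, obs in observed.items():
            if chrom in sizes:
                if sizes[chrom] < obs:
                    raise ValidationError(
                        f"chrom-sizes length {sizes[chrom]} for chromosome "
                        f"{chrom} is smaller than observed window end {obs}"
                    )
                observed[chrom] = sizes[chrom]
    return dict(sorted(observed.items(), key=lambda kv: chrom_sort_key(kv[0])))


def _read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValidationError(
                    f"{path}: line {lineno}: expected 'chrom<TAB>length'"
                )
            chrom = fields[0][3:] if fields[0].lower().startswith("chr") else fields[0]
            sizes[chrom] = int(fields[1])
    return sizes


def parse_highlight(spec: str) -> RegionHighlight:
    """Parse ``CHR:START-END:LABEL`` (e.g. ``2:136545000-136594750:MCM6``)."""
    parts = spec.split(":")
    if len(parts) != 3 or "-" not in parts[1]:
        raise ValidationError(
            f"malformed highlight {spec!r}; expected CHR:START-END:LABEL"
        )
    start, _, end = parts[1].partition("-")
    try:
        return RegionHighlight(
            chromosome=parts[0], start_bp=int(start), end_bp=int(end),
            label=parts[2],
        )
    except ValueError:
        raise ValidationError(
            f"non-integer coordinates in highlight {spec!r}"
        ) from None


# ---------------------------------------------------------------------------
# rendering

@dataclass(frozen=True)
class LapRenderInfo:
    """Structural summary of a rendered karyogram, for checks and tests."""

    sample_id: str
    chromosome_rows: tuple[str, ...]
    bands_per_row: int
    legend_names: tuple[str, ...]
    covered_fraction: dict[tuple[str, int], float]  # (chrom, hap) -> fraction
    out_path: Path


def render_lap(
    tracts: tuple[Sequence[AncestryTract], Sequence[AncestryTract]],
    palette: Palette,
    lengths: Mapping[str, int],
    out_path: str | os.PathLike,
    fmt: str = "png",
    highlight: RegionHighlight | None = None,
    sample_id: str | None = None,
) -> LapRenderInfo:
    """Render a diploid karyogram for one individual.

    One row per chromosome in ascending natural order, two parallel bands
    per row (haplotype 0 above haplotype 1). Intervals within
    ``[0, length)`` not covered by any tract keep the palette background
    color (unknown ancestry). The canvas is exactly 4210 x 1663 units
    (pixels for PNG output).
    """
    from ._figutils import SUPPORTED_FORMATS_LAP, save_figure
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    if fmt not in SUPPORTED_FORMATS_LAP:
        raise ValidationError(
            f"unsupported format {fmt!r} for karyogram; expected one of "
            f"{SUPPORTED_FORMATS_LAP}"
        )
    hap0, hap1 = tracts
    if sample_id is None:
        for t in list(hap0) + list(hap1):
            if t.sample_id:
                sample_id = t.sample_id
                break
        else:
            sample_id = ""
    chroms = sorted(lengths, key=chrom_sort_key)
    if not chroms:
        raise ValidationError("no chromosomes to draw")
    if highlight is not None and highlight.chromosome not in chroms:
        raise ValidationError(
            f"highlight chromosome {highlight.chromosome!r} absent from data "
            f"(have: {', '.join(chroms)})"
        )
    for t in list(hap0) + list(hap1):
        if t.chromosome not in lengths:
            raise ValidationError(
                f"tract on chromosome {t.chromosome!r} has no known length"
            )
        if t.end_bp > lengths[t.chromosome]:
            raise ValidationError(
                f"tract end {t.end_bp} exceeds chromosome {t.chromosome} "
                f"length {lengths[t.chromosome]}"
            )

    dropped_codes: set[int] = set()

    max_len = max(lengths.values())
    n_rows = len(chroms)
    dpi = 100.0
    fig = plt.figure(figsize=(CANVAS_WIDTH / dpi, CANVAS_HEIGHT / dpi), dpi=dpi)
    ax = fig.add_axes([0.045, 0.02, 0.80, 0.93])
    ax.set_xlim(0, max_len)
    ax.set_ylim(0, n_rows)
    ax.axis("off")

    band_h = 0.30
    band_y = {0: 0.56, 1: 0.14}  # offsets within a row slot; hap0 above hap1
    covered: dict[tuple[str, int], float] = {}
    for row, chrom in enumerate(chroms):
        ybase = n_rows - 1 - row
        length = lengths[chrom]
        for hap, tract_list in ((0, hap0), (1, hap1)):
            bg = Rectangle(
                (0, ybase + band_y[hap]), length, band_h,
                facecolor=palette.background_color, edgecolor="#888888",
                linewidth=0.6, zorder=1,
            )
            bg.set_gid(f"band_{chrom}_{hap}")
            ax.add_patch(bg)
            covered_bp = 0
            for t in tract_list:
                if t.chromosome != chrom:
                    continue
                covered_bp += t.length_bp
                if t.code >= len(palette.entries):
                    dropped_codes.add(t.code)
                    continue
                # palette entries follow codebook order: entry index == code
                _, color = palette.entries[t.code]
                seg = Rectangle(
                    (t.start_bp, ybase + band_y[hap]), t.length_bp, band_h,
                    facecolor=color, edgecolor="none", zorder=2,
                )
                seg.set_gid(f"tract_{chrom}_{hap}_{t.start_bp}")
                ax.add_patch(seg)
            covered[(chrom, hap)] = covered_bp / length
        ax.text(
            -0.006 * max_len, ybase + 0.5, str(chrom), ha="right", va="center",
            fontsize=16,
        )
    if dropped_codes:
        logger.warning(
            "tracts with ancestry codes %s have no palette entry and are "
            "rendered as background",
            sorted(dropped_codes),
        )

    if highlight is not None:
        row = chroms.index(highlight.chromosome)
        ybase = n_rows - 1 - row
        width = highlight.end_bp - highlight.start_bp
        marker = Rectangle(
            (highlight.start_bp, ybase + band_y[1] - 0.04),
            width, band_y[0] + band_h - band_y[1] + 0.08,
            facecolor="none", edgecolor="#000000", linewidth=2.0, zorder=3,
        )
        marker.set_gid("highlight")
        ax.add_patch(marker)
        ax.text(
            (highlight.start_bp + highlight.end_bp) / 2, ybase + 1.0,
            highlight.label, ha="center", va="bottom", fontsize=14, zorder=3,
        )

    legend_names = [name for name, _ in palette.entries]
    handles = [
        Rectangle((0, 0), 1, 1, facecolor=color, edgecolor="#555555",
                  linewidth=0.5)
        for _, color in palette.entries
    ]
    leg = fig.legend(
        handles, legend_names, loc="center right", bbox_to_anchor=(0.995, 0.5),
        frameon=False, fontsize=18, title=sample_id or None,
        title_fontsize=20,
    )
    for patch, name in zip(leg.get_patches(), legend_names):
        patch.set_gid(f"legendentry_{name}")

    written = save_figure(fig, out_path, fmt, dpi=dpi)
    return LapRenderInfo(
        sample_id=sample_id,
        chromosome_rows=tuple(chroms),
        bands_per_row=2,
        legend_names=tuple(legend_names),
        covered_fraction=covered,
        out_path=written,
    )

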