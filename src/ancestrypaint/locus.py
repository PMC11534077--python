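"""Locus-level ancestry composition across all haplotypes of a cohort.

Each haplotype is assigned the ancestry with the largest base-pair overlap
with the query interval (ties go to the lower code; zero overlap counts as
``unknown``). Percentages are rounded to one decimal, half-up. A per-base
mode apportions each haplotype fractionally by overlap instead.
"""

from __future__ import annotations

import os
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

from .errors import ValidationError
from .model import LocusComposition, MspTable
from .rfmix2_io import merge_codebooks

UNKNOWN = "unknown"


def round_percent(value: Decimal | float) -> float:
    """One-decimal percentage rounding, half-up (matches printed precision)."""
    return float(Decimal(value).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def locus_composition(
    msp_tables: Sequence[MspTable],
    interval: tuple[str, int, int],
    per_base: bool = False,
) -> LocusComposition:
    """Summarize the ancestry of ``interval`` over every haplotype.

    ``interval`` is (chromosome, start_bp, end_bp), 0-based half-open.
    All supplied tables must share codebook and sample list; the interval's
    chromosome must be present in at least one of them.
    """
    chrom, start, end = interval
    if start >= end:
        raise ValidationError(f"interval {chrom}:{start}-{end} has start >= end")
    if not msp_tables:
        raise ValidationError("locus_composition requires at least one msp table")
    codebook = merge_codebooks([t.codebook for t in msp_tables])
    samples = msp_tables[0].samples
    for t in msp_tables[1:]:
        if t.samples != samples:
            raise ValidationError("sample list mismatch between msp tables")
    relevant = [w for t in msp_tables for w in t.windows_on(chrom)]
    if not relevant:
        present = sorted({c for t in msp_tables for c in t.chromosomes})
        raise ValidationError(
            f"chromosome {chrom!r} absent from input; present: "
            f"{', '.join(present)}"
        )

    n_hap = 2 * len(samples)
    k = codebook.size
    # overlap[h][c] = bp of ancestry c overlapping the interval on haplotype h
    overlap = [[0] * k for _ in range(n_hap)]
    for w in relevant:
        bp = min(end, w.end_bp) - max(start, w.start_bp)
        if bp <= 0:
            continue
        for h in range(n_hap):
            overlap[h][w.codes[h]] += bp

    names = list(codebook.names) + [UNKNOWN]
    if per_base:
        interval_len = end - start
        counts = {name: 0.0 for name in names}
        for h in range(n_hap):
            covered = sum(overlap[h])
            for c in range(k):
                counts[codebook.names[c]] += overlap[h][c] / interval_len
            counts[UNKNOWN] += (interval_len - covered) / interval_len
        percents = {
            name: round_percent(Decimal(counts[name]) * 100 / Decimal(n_hap))
            for name in names
        }
    else:
        tallies = {name: 0 for name in names}
        for h in range(n_hap):
            best_code, best_bp = None, 0
            for c in range(k):
                if overlap[h][c] > best_bp:
                    best_code, best_bp = c, overlap[h][c]
            if best_code is None:
                tallies[UNKNOWN] += 1
            else:
                tallies[codebook.names[best_code]] += 1
        counts = {name: float(v) for name, v in tallies.items()}
        percents = {
            name: round_percent(Decimal(tallies[name]) * 100 / Decimal(n_hap))
            for name in names
        }
    return LocusComposition(
        chromosome=chrom,
        start_bp=start,
        end_bp=end,
        counts=counts,
        percents=percents,
        n_haplotypes=n_hap,
    )


def parse_region(spec: str) -> tuple[str, int, int]:
    """Parse ``CHR:START-END`` into an interval tuple."""
    chrom, sep, coords = spec.partition(":")
    start, sep2, end = coords.partition("-")
    if not sep or not sep2:
        raise ValidationError(f"malformed region {spec!r}; expected CHR:START-END")
    try:
        return chrom, int(start), int(end)
    except ValueError:
        raise ValidationError(f"non-integer coordinates in region {spec!r}") from None


def write_locus_report(comp: LocusComposition, path: str | os.PathLike) -> None:
    """TSV report: ancestry_name, haplotype_count, percent."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#region\t{comp.chromosome}:{comp.start_bp}-{comp.end_bp}\n")
        fh.write("#ancestry\thaplotype_count\tpercent\n")
        for name, count in comp.counts.items():
            count_repr = f"{count:.4f}" if count != int(count) else str(int(count))
            fh.write(f"{name}\t{count_repr}\t{comp.percents[name]:.1f}\n")
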