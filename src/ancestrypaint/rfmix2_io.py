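"""Readers and writers for RFMIX2 output files and derived BED tracts.

Dialects
--------
``.rfmix.Q``
    Lines starting ``#`` are comments; the last comment line is the column
    header whose first token is ``sample`` followed by the K ancestry names.
    Data rows are tab-separated: sample id then K decimal fractions.

``.msp.tsv``
    Line 1: ``#Subpopulation order/codes:`` followed by ``NAME=code`` pairs.
    Line 2: ``#chm  spos  epos  sgpos  egpos  n snps`` followed by paired
    ``<sample>.0`` / ``<sample>.1`` column names. Data rows are
    tab-separated with integer ancestry codes, one column per haplotype.
    ``spos``/``epos`` are treated as 0-based half-open coordinates.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import FormatError, ValidationError
from .model import (
    AncestryCodebook,
    AncestryTract,
    GlobalAncestryTable,
    MspTable,
    MspWindow,
)

logger = logging.getLogger(__name__)

MSP_FIXED_COLUMNS = ("#chm", "spos", "epos", "sgpos", "egpos", "n snps")


# ---------------------------------------------------------------------------
# .rfmix.Q

def read_q(path: str | os.PathLike, chromosome: str | None = None) -> GlobalAncestryTable:
    """Parse a per-chromosome ``.rfmix.Q`` global-ancestry table.

    The chromosome label defaults to the file name's ``.chr<N>.`` component
    when present, else the stem of the file name.
    """
    path = Path(path)
    header: list[str] | None = None
    samples: list[str] = []
    rows: list[list[float]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                header = line.lstrip("#").split("\t")
                continue
            if header is None:
                raise FormatError(
                    f"{path}: line {lineno}: data row before the "
                    "'#sample <ancestries>' header line"
                )
            fields = line.split("\t")
            if len(fields) != len(header):
                raise FormatError(
                    f"{path}: line {lineno}: {len(fields)} fields, header "
                    f"declares {len(header)}"
                )
            samples.append(fields[0])
            try:
                rows.append([float(x) for x in fields[1:]])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
    if header is None:
        raise FormatError(f"{path}: missing '#sample <ancestries>' header line")
    if header[0].strip().lower() != "sample":
        raise FormatError(
            f"{path}: header must start with 'sample', got {header[0]!r}"
        )
    names = [h.strip() for h in header[1:]]
    codebook = AncestryCodebook.from_names(names)
    if chromosome is None:
        chromosome = _chromosome_from_filename(path)
    fractions = np.array(rows, dtype=float).reshape(len(samples), codebook.size)
    return GlobalAncestryTable(
        chromosome=chromosome,
        codebook=codebook,
        samples=tuple(samples),
        fractions=fractions,
    )


def write_q(table: GlobalAncestryTable, path: str | os.PathLike) -> None:
    """Write a ``.rfmix.Q`` table (6-decimal fractions, tab-separated)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#sample\t" + "\t".join(table.codebook.names) + "\n")
        for sample, row in zip(table.samples, table.fractions):
            fh.write(sample + "\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")


def _chromosome_from_filename(path: Path) -> str:
    for part in path.name.split("."):
        if part.startswith("chr") and len(part) > 3:
            return part[3:]
    return path.stem


# ---------------------------------------------------------------------------
# .msp.tsv

def read_msp(path: str | os.PathLike) -> MspTable:
    """Parse an ``.msp.tsv`` local-ancestry table (one or more chromosomes)."""
    path = Path(path)
    with path.open() as fh:
        codes_line = fh.readline().rstrip("\n")
        header_line = fh.readline().rstrip("\n")
        codebook = _parse_subpopulation_line(path, codes_line)
        samples = _parse_msp_header(path, header_line)
        windows: list[MspWindow] = []
        width = 2 * len(samples)
        for lineno, raw in enumerate(fh, start=3):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 6 + width:
                raise FormatError(
                    f"{path}: line {lineno}: {len(fields)} fields, expected "
                    f"{6 + width}"
                )
            try:
                windows.append(
                    MspWindow(
                        chromosome=fields[0],
                        start_bp=int(fields[1]),
                        end_bp=int(fields[2]),
                        start_cM=float(fields[3]),
                        end_cM=float(fields[4]),
                        n_snps=int(fields[5]),
                        codes=tuple(int(x) for x in fields[6:]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
    return MspTable(codebook=codebook, samples=samples, windows=tuple(windows))


def _parse_subpopulation_line(path: Path, line: str) -> AncestryCodebook:
    prefix = "#Subpopulation order/codes:"
    if not line.startswith(prefix):
        raise FormatError(
            f"{path}: line 1 must start with {prefix!r}, got {line[:60]!r}"
        )
    pairs = line[len(prefix):].replace("\t", " ").split()
    if not pairs:
        raise FormatError(f"{path}: line 1 contains no NAME=code pairs")
    entries: list[tuple[str, int]] = []
    for token in pairs:
        if "=" not in token:
            raise FormatError(f"{path}: malformed subpopulation token {token!r}")
        name, _, code = token.partition("=")
        try:
            entries.append((name, int(code)))
        except ValueError:
            raise FormatError(
                f"{path}: non-integer subpopulation code in {token!r}"
            ) from None
    entries.sort(key=lambda e: e[1])
    return AncestryCodebook(tuple(entries))


def _parse_msp_header(path: Path, line: str) -> tuple[str, ...]:
    fields = line.split("\t")
    if tuple(fields[:6]) != MSP_FIXED_COLUMNS:
        raise FormatError(
            f"{path}: line 2 must begin with {MSP_FIXED_COLUMNS}, got "
            f"{tuple(fields[:6])}"
        )
    hap_cols = fields[6:]
    if not hap_cols or len(hap_cols) % 2:
        raise FormatError(
            f"{path}: {len(hap_cols)} haplotype columns; expected a non-empty "
            "even number of paired '<sample>.0'/'<sample>.1' columns"
        )
    samples: list[str] = []
    for i in range(0, len(hap_cols), 2):
        a, b = hap_cols[i], hap_cols[i + 1]
        if not (a.endswith(".0") and b.endswith(".1") and a[:-2] == b[:-2]):
            raise FormatError(
                f"{path}: unpaired haplotype columns {a!r}, {b!r}; expected "
                "'<sample>.0' followed by '<sample>.1'"
            )
        samples.append(a[:-2])
    return tuple(samples)


def write_msp(msp: MspTable, path: str | os.PathLike) -> None:
    """Write an ``.msp.tsv`` file (single- or multi-chromosome)."""
    path = Path(path)
    with path.open("w") as fh:
        pairs = "\t".join(f"{name}={code}" for name, code in msp.codebook.entries)
        fh.write(f"#Subpopulation order/codes: {pairs}\n")
        hap_cols = "\t".join(f"{s}.{h}" for s in msp.samples for h in (0, 1))
        fh.write("\t".join(MSP_FIXED_COLUMNS) + "\t" + hap_cols + "\n")
        for w in msp.windows:
            fh.write(
                f"{w.chromosome}\t{w.start_bp}\t{w.end_bp}\t{w.start_cM:.6f}\t"
                f"{w.end_cM:.6f}\t{w.n_snps}\t"
                + "\t".join(str(c) for c in w.codes)
                + "\n"
            )


# ---------------------------------------------------------------------------
# codebooks and per-chromosome file discovery

def merge_codebooks(
    codebooks: Sequence[AncestryCodebook],
    labels: Sequence[str] | None = None,
) -> AncestryCodebook:
    """Return the shared codebook iff all inputs are identical.

    ``labels`` (e.g. chromosome names) is used only to name the offending
    inputs in the mismatch error.
    """
    if not codebooks:
        raise ValidationError("merge_codebooks requires at least one codebook")
    if labels is None:
        labels = [str(i) for i in range(len(codebooks))]
    first = codebooks[0]
    for cb, label in zip(codebooks[1:], labels[1:]):
        if cb.entries != first.entries:
            raise ValidationError(
                f"codebook mismatch between {labels[0]} ({first.entries}) and "
                f"{label} ({cb.entries})"
            )
    return first


def discover_chromosome_files(
    prefix: str | os.PathLike,
    chromosomes: Sequence[str],
    suffix: str,
) -> list[tuple[str, Path]]:
    """Resolve ``<prefix>.chr<N>.<suffix>`` paths, skipping missing ones.

    Missing chromosomes are skipped with a logged warning; an empty result
    is an error.
    """
    found: list[tuple[str, Path]] = []
    for chrom in chromosomes:
        path = Path(f"{prefix}.chr{chrom}.{suffix}")
        if path.exists():
            found.append((chrom, path))
        else:
            logger.warning("no %s file for chromosome %s (looked for %s)", suffix, chrom, path)
    if not found:
        raise ValidationError(
            f"no {suffix} files found for prefix {prefix!r} and chromosomes "
            f"{list(chromosomes)}"
        )
    return found


# ---------------------------------------------------------------------------
# BED emission

def write_hap_beds(
    msp: MspTable,
    tracts_by_sample: Mapping[str, tuple[Sequence[AncestryTract], Sequence[AncestryTract]]],
    out_dir: str | os.PathLike,
) -> dict[str, tuple[Path, Path]]:
    """Write ``<sample>_hap1.bed`` / ``<sample>_hap2.bed`` per sample.

    Records are 4-column BED (chrom, start, end, ancestry name), 0-based
    half-open, in tract order. Returns the written file pair per sample.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, tuple[Path, Path]] = {}
    for sample_id, (hap0, hap1) in tracts_by_sample.items():
        paths = (
            out_dir / f"{sample_id}_hap1.bed",
            out_dir / f"{sample_id}_hap2.bed",
        )
        for tracts, path in zip((hap0, hap1), paths):
            with path.open("w") as fh:
                for t in tracts:
                    name = msp.codebook.name_of(t.code)
                    fh.write(f"{t.chromosome}\t{t.start_bp}\t{t.end_bp}\t{name}\n")
        written[sample_id] = paths
    return written


def read_bed(
    path: str | os.PathLike,
    codebook: AncestryCodebook,
    sample_id: str = "",
    haplotype: int = 0,
) -> tuple[AncestryTract, ...]:
    """Read a 4-column ancestry BED back into tracts (round-trip helper)."""
    path = Path(path)
    tracts: list[AncestryTract] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise FormatError(
                    f"{path}: line {lineno}: expected 4 BED columns, got "
                    f"{len(fields)}"
                )
            chrom, start, end, name = fields
            tracts.append(
                AncestryTract(
                    chromosome=chrom,
                    start_bp=int(start),
                    end_bp=int(end),
                    code=codebook.code_of(name),
                    haplotype=haplotype,
                    sample_id=sample_id,
                )
            )
    return tuple(tracts)
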