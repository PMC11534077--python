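"""Core domain types shared by the I/O, painting and summary modules.

All containers are plain dataclasses that validate their invariants on
construction, so a successfully built object is always internally
consistent and downstream code never re-checks.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "AncestryCodebook",
    "GlobalAncestryTable",
    "MspWindow",
    "MspTable",
    "MeanAncestryRecord",
    "MeanAncestryTable",
    "AncestryTract",
    "Palette",
    "RegionHighlight",
    "LocusComposition",
    "chrom_sort_key",
]

_HEX_COLOR = re.compile(r"^#[0-9A-Fa-f]{6}$")


def chrom_sort_key(label: str) -> tuple[int, int, str]:
    """Natural ordering for chromosome labels: 1 < 2 < ... < 22 < X < Y."""
    s = label[3:] if label.lower().startswith("chr") else label
    if s.isdigit():
        return (0, int(s), "")
    return (1, 0, s)


@dataclass(frozen=True)
class AncestryCodebook:
    """Ordered ancestry-name <-> integer-code mapping shared by a whole run.

    Codes are exactly ``0..K-1`` in entry order; names are unique and
    non-empty.
    """

    entries: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError("codebook must contain at least one ancestry")
        names = [name for name, _ in self.entries]
        codes = [code for _, code in self.entries]
        if codes != list(range(len(codes))):
            raise ValidationError(
                f"ancestry codes must be exactly 0..{len(codes) - 1} in order, got {codes}"
            )
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate ancestry names: {names}")
        if any(not name for name in names):
            raise ValidationError("ancestry names must be non-empty")

    @classmethod
    def from_names(cls, names: Iterable[str]) -> "AncestryCodebook":
        return cls(tuple((name, code) for code, name in enumerate(names)))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.entries)

    @property
    def size(self) -> int:
        return len(self.entries)

    def name_of(self, code: int) -> str:
        if not 0 <= code < self.size:
            raise ValidationError(f"ancestry code {code} outside 0..{self.size - 1}")
        return self.entries[code][0]

    def code_of(self, name: str) -> int:
        for entry_name, code in self.entries:
            if entry_name == name:
                return code
        raise ValidationError(
            f"unknown ancestry {name!r}; valid names: {', '.join(self.names)}"
        )


@dataclass
class GlobalAncestryTable:
    """One chromosome's worth of per-sample global ancestry fractions."""

    chromosome: str
    codebook: AncestryCodebook
    samples: tuple[str, ...]
    fractions: np.ndarray  # shape (n_samples, K), rows sum to 1 +/- 1e-4

    ROW_SUM_TOL = 1e-4

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        n, k = len(self.samples), self.codebook.size
        if self.fractions.shape != (n, k):
            raise ValidationError(
                f"fractions shape {self.fractions.shape} != ({n}, {k})"
            )
        if np.any(self.fractions < 0) or np.any(self.fractions > 1):
            raise ValidationError("ancestry fractions must lie in [0, 1]")
        sums = self.fractions.sum(axis=1)
        bad = np.nonzero(np.abs(sums - 1.0) > self.ROW_SUM_TOL)[0]
        if bad.size:
            i = int(bad[0])
            raise ValidationError(
                f"ancestry fractions for sample {self.samples[i]!r} sum to "
                f"{sums[i]:.6f}, expected 1 within {self.ROW_SUM_TOL}"
            )


@dataclass(frozen=True)
class MspWindow:
    """One local-ancestry window: coordinates plus one code per haplotype.

    ``codes`` is ordered sample1-hap0, sample1-hap1, sample2-hap0, ...
    Physical coordinates are 0-based half-open ``[start_bp, end_bp)``.
    """

    chromosome: str
    start_bp: int
    end_bp: int
    start_cM: float
    end_cM: float
    n_snps: int
    codes: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.start_bp >= self.end_bp:
            raise ValidationError(
                f"window {self.chromosome}:{self.start_bp}-{self.end_bp} "
                "has start_bp >= end_bp"
            )
        if self.start_cM > self.end_cM:
            raise ValidationError(
                f"window {self.chromosome}:{self.start_bp}-{self.end_bp} "
                "has start_cM > end_cM"
            )
        if self.n_snps < 1:
            raise ValidationError(
                f"window {self.chromosome}:{self.start_bp}-{self.end_bp} "
                f"has n_snps={self.n_snps} < 1"
            )

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class MspTable:
    """Validated per-window local-ancestry codes for a set of samples.

    Windows are sorted by (chromosome, start_bp) with natural chromosome
    order, non-overlapping within a chromosome, and every code vector has
    length ``2 * len(samples)``.
    """

    codebook: AncestryCodebook
    samples: tuple[str, ...]
    windows: tuple[MspWindow, ...]

    def __post_init__(self) -> None:
        self.samples = tuple(self.samples)
        self.windows = tuple(self.windows)
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample identifiers")
        width = 2 * len(self.samples)
        k = self.codebook.size
        seen_chroms: list[str] = []
        prev: MspWindow | None = None
        for w in self.windows:
            if len(w.codes) != width:
                raise ValidationError(
                    f"window {w.chromosome}:{w.start_bp}-{w.end_bp} has "
                    f"{len(w.codes)} codes, expected {width}"
                )
            for c in w.codes:
                if not 0 <= c < k:
                    raise ValidationError(
                        f"ancestry code {c} outside 0..{k - 1} in window "
                        f"{w.chromosome}:{w.start_bp}-{w.end_bp}"
                    )
            if prev is not None and prev.chromosome == w.chromosome:
                if w.start_bp < prev.end_bp:
                    raise ValidationError(
                        f"windows out of order or overlapping on chromosome "
                        f"{w.chromosome}: {prev.start_bp}-{prev.end_bp} then "
                        f"{w.start_bp}-{w.end_bp}"
                    )
            elif prev is not None:
                if w.chromosome in seen_chroms:
                    raise ValidationError(
                        f"chromosome {w.chromosome} appears in two separate blocks"
                    )
                if chrom_sort_key(w.chromosome) < chrom_sort_key(prev.chromosome):
                    raise ValidationError(
                        f"chromosome blocks out of order: {prev.chromosome} "
                        f"before {w.chromosome}"
                    )
                seen_chroms.append(prev.chromosome)
            prev = w

    @property
    def chromosomes(self) -> tuple[str, ...]:
        out: list[str] = []
        for w in self.windows:
            if not out or out[-1] != w.chromosome:
                out.append(w.chromosome)
        return tuple(out)

    def haplotype_column(self, sample_id: str, haplotype: int) -> int:
        if haplotype not in (0, 1):
            raise ValidationError(f"haplotype must be 0 or 1, got {haplotype}")
        try:
            i = self.samples.index(sample_id)
        except ValueError:
            raise ValidationError(
                f"unknown sample {sample_id!r}; known samples: "
                f"{', '.join(self.samples)}"
            ) from None
        return 2 * i + haplotype

    def windows_on(self, chromosome: str) -> Iterator[MspWindow]:
        return (w for w in self.windows if w.chromosome == chromosome)


@dataclass(frozen=True)
class MeanAncestryRecord:
    sample_id: str
    mean_fractions: tuple[float, ...]
    n_chromosomes_used: int

    def __post_init__(self) -> None:
        if self.n_chromosomes_used < 1:
            raise ValidationError(
                f"sample {self.sample_id!r}: n_chromosomes_used must be >= 1"
            )
        total = sum(self.mean_fractions)
        if abs(total - 1.0) > 1e-4:
            raise ValidationError(
                f"sample {self.sample_id!r}: mean fractions sum to {total:.6f}"
            )


@dataclass
class MeanAncestryTable:
    """Per-individual mean ancestry fractions across chromosomes."""

    codebook: AncestryCodebook
    records: tuple[MeanAncestryRecord, ...]

    def __post_init__(self) -> None:
        self.records = tuple(self.records)
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample identifiers in mean table")
        for r in self.records:
            if len(r.mean_fractions) != self.codebook.size:
                raise ValidationError(
                    f"sample {r.sample_id!r}: {len(r.mean_fractions)} fractions "
                    f"for {self.codebook.size} ancestries"
                )


@dataclass(frozen=True)
class AncestryTract:
    """Maximal run of constant ancestry on one haplotype, half-open in bp."""

    chromosome: str
    start_bp: int
    end_bp: int
    code: int
    haplotype: int = 0
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.start_bp >= self.end_bp:
            raise ValidationError(
                f"tract {self.chromosome}:{self.start_bp}-{self.end_bp} "
                "has start_bp >= end_bp"
            )
        if self.haplotype not in (0, 1):
            raise ValidationError(f"haplotype must be 0 or 1, got {self.haplotype}")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass(frozen=True)
class Palette:
    """Ancestry -> color assignment; at most 10 entries, distinct colors."""

    entries: tuple[tuple[str, str], ...]
    background_color: str = "#FFFFFF"

    MAX_COLORS = 10

    def __post_init__(self) -> None:
        if len(self.entries) > self.MAX_COLORS:
            raise ValidationError(
                f"palette has {len(self.entries)} entries; maximum is "
                f"{self.MAX_COLORS}"
            )
        colors = [c for _, c in self.entries]
        for c in colors + [self.background_color]:
            if not _HEX_COLOR.match(c):
                raise ValidationError(f"invalid hex color {c!r}")
        lowered = [c.lower() for c in colors]
        if len(set(lowered)) != len(lowered):
            raise ValidationError(f"palette colors must be pairwise distinct: {colors}")

    def color_of(self, name: str) -> str:
        for entry_name, color in self.entries:
            if entry_name == name:
                return color
        raise ValidationError(f"no palette entry for ancestry {name!r}")


@dataclass(frozen=True)
class RegionHighlight:
    """A labelled genomic interval to mark on a karyogram."""

    chromosome: str
    start_bp: int
    end_bp: int
    label: str

    def __post_init__(self) -> None:
        if self.start_bp >= self.end_bp:
            raise ValidationError(
                f"highlight {self.chromosome}:{self.start_bp}-{self.end_bp} "
                "has start_bp >= end_bp"
            )


@dataclass
class LocusComposition:
    """Ancestry composition of one genomic interval across all haplotypes.

    ``counts`` maps ancestry name (plus ``"unknown"``) to the number of
    haplotypes assigned to it; ``percents`` holds the same keys as
    percentages rounded to one decimal (half-up).
    """

    chromosome: str
    start_bp: int
    end_bp: int
    counts: dict[str, float]
    percents: dict[str, float]
    n_haplotypes: int = field(default=0)

    def __post_init__(self) -> None:
        if self.n_haplotypes == 0:
            self.n_haplotypes = int(round(sum(self.counts.values())))
        total = sum(self.counts.values())
        if abs(total - self.n_haplotypes) > 1e-6:
            raise ValidationError(
                f"counts sum to {total}, expected {self.n_haplotypes} haplotypes"
            )
        if abs(sum(self.percents.values()) - 100.0) > 0.1 + 1e-9:
            raise ValidationError(
                f"percentages sum to {sum(self.percents.values()):.3f}, "
                "expected 100 within 0.1"
            )


def sequence_of_tracts(tracts: Sequence[AncestryTract]) -> tuple[AncestryTract, ...]:
    return tuple(tracts)
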