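"""Deterministic figure saving and SVG structure introspection.

SVG output is made reproducible by fixing the element-id hash salt and
stripping the creation date, so identical inputs yield byte-identical
files. Structural checks (legend entries, chromosome rows) read back the
``id`` attributes that the renderers attach to their artists.
"""

from __future__ import annotations

import os
import xml.etree.ElementTree as ET
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # noqa: E402  -- headless rendering only

import matplotlib.pyplot as plt  # noqa: E402

from .errors import ValidationError

_HASHSALT = "ancestrypaint"

SUPPORTED_FORMATS_GAP = ("pdf", "svg")
SUPPORTED_FORMATS_LAP = ("pdf", "svg", "png")


def save_figure(fig, out_path: str | os.PathLike, fmt: str, dpi: float | None = None) -> Path:
    out_path = Path(out_path)
    if out_path.suffix.lower() != f".{fmt}":
        out_path = out_path.with_suffix(f".{fmt}")
    out_path.parent.mkdir(parents=True, exist_ok=True)
    with matplotlib.rc_context({"svg.hashsalt": _HASHSALT}):
        if fmt == "svg":
            fig.savefig(out_path, format="svg", metadata={"Date": None})
        elif fmt == "pdf":
            fig.savefig(out_path, format="pdf", metadata={"CreationDate": None})
        elif fmt == "png":
            fig.savefig(out_path, format="png", dpi=dpi or fig.dpi)
        else:
            raise ValidationError(
                f"unsupported output format {fmt!r}; expected one of pdf, svg, png"
            )
    plt.close(fig)
    return out_path


def svg_element_ids(path: str | os.PathLike) -> list[str]:
    """All ``id`` attributes present in an SVG document, in document order."""
    tree = ET.parse(path)
    return [
        el.attrib["id"]
        for el in tree.iter()
        if "id" in el.attrib
    ]


def svg_ids_with_prefix(path: str | os.PathLike, prefix: str) -> list[str]:
    return [i for i in svg_element_ids(path) if i.startswith(prefix)]


def count_legend_entries(path: str | os.PathLike) -> int:
    """Number of distinct legend swatches in a rendered SVG."""
    return len(set(svg_ids_with_prefix(path, "legendentry_")))


def count_chromosome_rows(path: str | os.PathLike) -> int:
    """Number of distinct chromosome rows in a rendered karyogram SVG."""
    chroms = {
        i.split("_")[1]
        for i in svg_ids_with_prefix(path, "band_")
    }
    return len(chroms)


def count_bands_per_row(path: str | os.PathLike) -> dict[str, int]:
    """Haplotype band count per chromosome row in a karyogram SVG."""
    out: dict[str, set[str]] = {}
    for i in svg_ids_with_prefix(path, "band_"):
        _, chrom, hap = i.split("_")
        out.setdefault(chrom, set()).add(hap)
    return {c: len(h) for c, h in out.items()}
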