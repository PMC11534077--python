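"""Shared test helpers: quick table builders and independent oracles."""

from __future__ import annotations

import numpy as np

from ancestrypaint.model import AncestryCodebook, MspTable, MspWindow


def make_msp(
    codes_rows,
    chromosome="1",
    window_bp=100,
    start=0,
    n_ancestries=None,
    samples=None,
    gaps=(),
):
    """Build an MspTable from a list of per-window code vectors.

    ``codes_rows[i]`` is the code vector of window i (length 2 x samples).
    ``gaps`` lists window indices before which a coordinate gap is inserted.
    """
    width = len(codes_rows[0])
    assert width % 2 == 0
    n_samples = width // 2
    if samples is None:
        samples = tuple(f"S{i + 1}" for i in range(n_samples))
    if n_ancestries is None:
        n_ancestries = max(max(r) for r in codes_rows) + 1
    codebook = AncestryCodebook.from_names(
        tuple(f"ANC{k}" for k in range(n_ancestries))
    )
    windows = []
    pos = start
    for i, row in enumerate(codes_rows):
        if i in gaps:
            pos += window_bp  # skip one window's worth of coordinates
        windows.append(
            MspWindow(
                chromosome=chromosome,
                start_bp=pos,
                end_bp=pos + window_bp,
                start_cM=pos / 1e6,
                end_cM=(pos + window_bp) / 1e6,
                n_snps=10,
                codes=tuple(row),
            )
        )
        pos += window_bp
    return MspTable(codebook=codebook, samples=samples, windows=tuple(windows))


def random_msp(rng, n_windows=20, n_samples=3, n_ancestries=3, chromosome="1",
               window_bp=1000, gap_prob=0.0):
    """Seeded random MspTable, optionally with coordinate gaps."""
    gaps = tuple(
        i for i in range(1, n_windows) if rng.random() < gap_prob
    )
    codes_rows = rng.integers(
        0, n_ancestries, size=(n_windows, 2 * n_samples)
    ).tolist()
    return make_msp(
        codes_rows, chromosome=chromosome, window_bp=window_bp,
        n_ancestries=n_ancestries, gaps=gaps,
    )


# ---------------------------------------------------------------------------
# independent oracles

def oracle_tracts(msp, sample_id, haplotype):
    """Linear scan over windows comparing neighbours i and i+1.

    Independent re-derivation of tract merging: emits (chrom, start, end,
    code) whenever the chromosome, coordinate continuity, or code changes.
    """
    col = 2 * list(msp.samples).index(sample_id) + haplotype
    ws = list(msp.windows)
    out = []
    i = 0
    while i < len(ws):
        j = i
        while (
            j + 1 < len(ws)
            and ws[j + 1].chromosome == ws[i].chromosome
            and ws[j + 1].start_bp == ws[j].end_bp
            and ws[j + 1].codes[col] == ws[i].codes[col]
        ):
            j += 1
        out.append(
            (ws[i].chromosome, ws[i].start_bp, ws[j].end_bp, ws[i].codes[col])
        )
        i = j + 1
    return out


def oracle_mean_fractions(tables):
    """Brute-force sum-then-divide accumulation per sample."""
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for t in tables:
        for sample, row in zip(t.samples, t.fractions):
            if sample not in sums:
                sums[sample] = np.zeros(len(row))
                counts[sample] = 0
            sums[sample] = sums[sample] + row
            counts[sample] += 1
    return {s: sums[s] / counts[s] for s in sums}


def oracle_locus_counts(msp_tables, interval):
    """Per-haplotype overlap accumulation, majority with lower-code ties."""
    chrom, start, end = interval
    samples = msp_tables[0].samples
    k = msp_tables[0].codebook.size
    n_hap = 2 * len(samples)
    acc = np.zeros((n_hap, k), dtype=np.int64)
    for t in msp_tables:
        for w in t.windows:
            if w.chromosome != chrom:
                continue
            ov = min(end, w.end_bp) - max(start, w.start_bp)
            if ov <= 0:
                continue
            for h in range(n_hap):
                acc[h, w.codes[h]] += ov
    counts = {name: 0 for name in msp_tables[0].codebook.names}
    unknown = 0
    for h in range(n_hap):
        if acc[h].sum() == 0:
            unknown += 1
        else:
            counts[msp_tables[0].codebook.names[int(acc[h].argmax())]] += 1
    counts["unknown"] = unknown
    return counts
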