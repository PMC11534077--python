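# ancestrypaint

Visual summaries of [RFMIX2](https://github.com/slowkoni/rfmix) local-ancestry
output:

- **GAP** (Global Ancestry Painting): combine per-chromosome `.rfmix.Q`
  tables, compute each individual's mean ancestry components across
  chromosomes, optionally sort by one component, and render a stacked bar
  plot with a legend (PDF/SVG).
- **LAP** (Local Ancestry Painting): combine per-chromosome `.msp.tsv`
  tables, emit per-haplotype BED tracts (`<sample>_hap1.bed` /
  `<sample>_hap2.bed`), and render a diploid karyogram — one row per
  chromosome, two bands per row, colored by ancestry — at 4k resolution
  (4210 × 1663; PDF/SVG/PNG). Uncovered regions stay white (unknown
  ancestry). A gene/region of interest can be highlighted.
- **locus**: the ancestry composition of a query interval across all
  haplotypes of a cohort (majority-by-overlap per haplotype, or
  fractional per-base accounting).
- **simulate**: a synthetic RFMIX2-output generator with known
  ground-truth ancestry proportions and tract structure, so the whole
  pipeline is testable without external data.

At most **10 ancestry components** are assigned colors; components beyond
the 10th are not drawn and a warning is logged.

## CLI

One executable, `ancestrypaint`, with combine → plot stages per pipeline:

```bash
# generate a synthetic fixture (defaults: 30 samples, 22 x 100 Mb
# chromosomes, proportions 0.55/0.30/0.15, seed 1729)
ancestrypaint simulate -o fixtures/                # or --config cfg.yaml --seed N

# global ancestry: combine + average, then plot
ancestrypaint gap combine --input-prefix fixtures/fixture \
    --chromosomes 1-22 --sort-ancestry MiddleEast -o gap.tsv
ancestrypaint gap plot --input gap.tsv --format svg -o gap_plot

# local ancestry: combine (optionally emit BEDs), then paint one individual
ancestrypaint lap combine --input-prefix fixtures/fixture \
    --chromosomes 1-22 -o combined.msp.tsv --bed-out beds/
ancestrypaint lap plot --input combined.msp.tsv --sample S001 \
    --highlight 2:136545000-136594750:MCM6 --format png -o karyogram

# locus-level composition across all haplotypes
ancestrypaint locus summarize --input-prefix fixtures/fixture \
    --region 2:136545000-136594750 -o report.tsv
```

Per-chromosome inputs are discovered as `<prefix>.chr<N>.rfmix.Q` /
`<prefix>.chr<N>.msp.tsv`; missing chromosomes are skipped with a warning.
Custom colors: `--colors '#FF8C00,#800080,#1E90FF'` (one hex color per
displayed ancestry, max 10). Exit codes: 0 success, 1 validation error,
2 usage error.

## File dialects

- `.rfmix.Q`: `#`-comment lines, the last being the header
  `#sample <anc1> ... <ancK>`; tab-separated rows of sample id + K
  fractions (rows must sum to 1 ± 1e-4).
- `.msp.tsv`: line 1 `#Subpopulation order/codes: NAME=0 NAME=1 ...`;
  line 2 `#chm spos epos sgpos egpos n snps` plus paired `<sample>.0` /
  `<sample>.1` columns; integer ancestry codes per haplotype.
  `spos`/`epos` are treated as 0-based half-open, and emitted BED uses
  the same convention.

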