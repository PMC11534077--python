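import logging

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ancestrypaint.errors import ValidationError
from ancestrypaint.model import AncestryCodebook, RegionHighlight
from ancestrypaint import lap, rfmix2_io
from ancestrypaint._figutils import (
    count_bands_per_row,
    count_chromosome_rows,
    count_legend_entries,
    svg_ids_with_prefix,
)

from helpers import make_msp, oracle_tracts, random_msp


class TestWindowsToTracts:
    def test_merge_abutting_equal_codes(self):
        msp = make_msp([[0, 0], [0, 1]], window_bp=100, start=100)
        tracts = lap.windows_to_tracts(msp, "S1", 0)
        assert len(tracts) == 1
        assert (tracts[0].start_bp, tracts[0].end_bp, tracts[0].code) == (100, 300, 0)

    def test_code_change_splits(self):
        msp = make_msp([[0, 0], [1, 0]], window_bp=100, start=100)
        tracts = lap.windows_to_tracts(msp, "S1", 0)
        assert [(t.start_bp, t.end_bp, t.code) for t in tracts] == [
            (100, 200, 0), (200, 300, 1),
        ]

    def test_gap_breaks_tract_despite_equal_code(self):
        msp = make_msp([[0, 0], [0, 0]], window_bp=100, gaps=(1,))
        tracts = lap.windows_to_tracts(msp, "S1", 0)
        assert [(t.start_bp, t.end_bp) for t in tracts] == [(0, 100), (200, 300)]
        assert all(t.code == 0 for t in tracts)

    def test_unknown_sample(self):
        msp = make_msp([[0, 0]])
        with pytest.raises(ValidationError, match="unknown sample"):
            lap.windows_to_tracts(msp, "nope", 0)

    def test_thousand_window_oracle(self, rng):
        msp = random_msp(rng, n_windows=1000, n_samples=2, n_ancestries=4,
                         gap_prob=0.05)
        for sample in msp.samples:
            for hap in (0, 1):
                got = [
                    (t.chromosome, t.start_bp, t.end_bp, t.code)
                    for t in lap.windows_to_tracts(msp, sample, hap)
                ]
                assert got == oracle_tracts(msp, sample, hap)

    def test_conserves_covered_length(self, rng):
        msp = random_msp(rng, n_windows=200, gap_prob=0.1)
        total_windows = sum(w.length_bp for w in msp.windows)
        for hap in (0, 1):
            tracts = lap.windows_to_tracts(msp, "S1", hap)
            assert sum(t.length_bp for t in tracts) == total_windows

    def test_maximality(self, rng):
        msp = random_msp(rng, n_windows=300, n_ancestries=2)
        tracts = lap.windows_to_tracts(msp, "S2", 1)
        for a, b in zip(tracts, tracts[1:]):
            if a.chromosome == b.chromosome and a.end_bp == b.start_bp:
                assert a.code != b.code


class TestBuildPalette:
    def test_default_first_three_orange_purple_blue(self):
        cb = AncestryCodebook.from_names(("MiddleEast", "Europe", "Africa"))
        palette = lap.build_palette(cb)
        assert palette.entries == (
            ("MiddleEast", "#FF8C00"),
            ("Europe", "#800080"),
            ("Africa", "#1E90FF"),
        )
        assert palette.background_color == "#FFFFFF"

    def test_twelve_ancestries_capped_at_ten(self, caplog):
        cb = AncestryCodebook.from_names(tuple(f"P{i}" for i in range(12)))
        with caplog.at_level(logging.WARNING):
            palette = lap.build_palette(cb)
        assert len(palette.entries) == 10
        assert "P10, P11" in caplog.text

    def test_user_color_arity_error(self):
        cb = AncestryCodebook.from_names(("A", "B", "C"))
        with pytest.raises(ValidationError, match="colors"):
            lap.build_palette(cb, user_colors=["#FF0000", "#00FF00"])

    def test_duplicate_user_colors(self):
        cb = AncestryCodebook.from_names(("A", "B"))
        with pytest.raises(ValidationError, match="distinct"):
            lap.build_palette(cb, user_colors=["#FF0000", "#ff0000"])

    def test_invalid_hex(self):
        cb = AncestryCodebook.from_names(("A",))
        with pytest.raises(ValidationError, match="hex"):
            lap.build_palette(cb, user_colors=["red"])


class TestChromosomeLengths:
    def test_observed_maximum(self):
        msp = make_msp([[0, 0]], window_bp=249_000_000)
        assert lap.chromosome_lengths([msp]) == {"1": 249_000_000}

    def test_override_smaller_rejected(self, tmp_path):
        msp = make_msp([[0, 0]], window_bp=249_000_000)
        sizes = tmp_path / "sizes.tsv"
        sizes.write_text("1\t248956422\n")
        with pytest.raises(ValidationError, match="smaller"):
            lap.chromosome_lengths([msp], override=sizes)

    def test_override_larger_applies(self, tmp_path):
        msp = make_msp([[0, 0]], window_bp=1000)
        sizes = tmp_path / "sizes.tsv"
        sizes.write_text("chr1\t5000\n")
        assert lap.chromosome_lengths([msp], override=sizes) == {"1": 5000}

    def test_lengths_bound_every_tract(self, rng):
        tables = [random_msp(rng, chromosome=str(c), gap_prob=0.1)
                  for c in (1, 2, 3)]
        lengths = lap.chromosome_lengths(tables)
        for t in tables:
            for sample in t.samples:
                for hap in (0, 1):
                    for tract in lap.windows_to_tracts(t, sample, hap):
                        assert tract.end_bp <= lengths[tract.chromosome]


class TestParseHighlight:
    def test_parse(self):
        h = lap.parse_highlight("2:136545000-136594750:MCM6")
        assert h == RegionHighlight("2", 136545000, 136594750, "MCM6")

    @pytest.mark.parametrize("bad", ["2:136545000-136594750", "2:x-y:G", "2"])
    def test_malformed(self, bad):
        with pytest.raises(ValidationError):
            lap.parse_highlight(bad)


@pytest.fixture(scope="module")
def combined22(genome22_fixture):
    tables = [rfmix2_io.read_msp(p) for p in genome22_fixture.msp_paths]
    return lap.combine_msp(tables)


def _tract_pair(msp, sample):
    return (
        lap.windows_to_tracts(msp, sample, 0),
        lap.windows_to_tracts(msp, sample, 1),
    )


class TestRenderLap:
    def test_22_rows_two_bands(self, combined22, tmp_path):
        sample = combined22.samples[0]
        palette = lap.build_palette(combined22.codebook)
        lengths = lap.chromosome_lengths([combined22])
        info = lap.render_lap(
            _tract_pair(combined22, sample), palette, lengths,
            tmp_path / "k.svg", fmt="svg", sample_id=sample,
        )
        assert len(info.chromosome_rows) == 22
        assert count_chromosome_rows(info.out_path) == 22
        assert set(count_bands_per_row(info.out_path).values()) == {2}
        assert count_legend_entries(info.out_path) == 3

    def test_png_canvas_4210_by_1663(self, combined22, tmp_path):
        from PIL import Image

        sample = combined22.samples[0]
        palette = lap.build_palette(combined22.codebook)
        lengths = lap.chromosome_lengths([combined22])
        info = lap.render_lap(
            _tract_pair(combined22, sample), palette, lengths,
            tmp_path / "k.png", fmt="png", sample_id=sample,
        )
        with Image.open(info.out_path) as im:
            assert im.size == (4210, 1663)

    def test_uncovered_region_is_background(self, tmp_path):
        # windows cover only the first half of the chromosome
        msp = make_msp([[0, 0], [0, 0]], window_bp=250)
        palette = lap.build_palette(msp.codebook)
        lengths = {"1": 1000}
        info = lap.render_lap(
            _tract_pair(msp, "S1"), palette, lengths, tmp_path / "k.svg",
            fmt="svg", sample_id="S1",
        )
        assert info.covered_fraction[("1", 0)] == pytest.approx(0.5)
        assert info.covered_fraction[("1", 1)] == pytest.approx(0.5)

    def test_covered_extent_matches_tracts(self, combined22, tmp_path):
        sample = combined22.samples[1]
        palette = lap.build_palette(combined22.codebook)
        lengths = lap.chromosome_lengths([combined22])
        tracts = _tract_pair(combined22, sample)
        info = lap.render_lap(
            tracts, palette, lengths, tmp_path / "k.svg", fmt="svg",
            sample_id=sample,
        )
        for (chrom, hap), frac in info.covered_fraction.items():
            expect = sum(
                t.length_bp for t in tracts[hap] if t.chromosome == chrom
            ) / lengths[chrom]
            assert frac == pytest.approx(expect)

    def test_highlight_drawn(self, combined22, tmp_path):
        sample = combined22.samples[0]
        palette = lap.build_palette(combined22.codebook)
        lengths = lap.chromosome_lengths([combined22])
        info = lap.render_lap(
            _tract_pair(combined22, sample), palette, lengths,
            tmp_path / "k.svg", fmt="svg",
            highlight=RegionHighlight("2", 1_000_000, 2_000_000, "GENE"),
            sample_id=sample,
        )
        assert svg_ids_with_prefix(info.out_path, "highlight")

    def test_highlight_absent_chromosome(self, combined22, tmp_path):
        sample = combined22.samples[0]
        palette = lap.build_palette(combined22.codebook)
        lengths = lap.chromosome_lengths([combined22])
        with pytest.raises(ValidationError, match="absent"):
            lap.render_lap(
                _tract_pair(combined22, sample), palette, lengths,
                tmp_path / "k.svg", fmt="svg",
                highlight=RegionHighlight("99", 0, 10, "X"),
            )

    def test_unsupported_format(self, combined22, tmp_path):
        sample = combined22.samples[0]
        palette = lap.build_palette(combined22.codebook)
        lengths = lap.chromosome_lengths([combined22])
        with pytest.raises(ValidationError, match="format"):
            lap.render_lap(
                _tract_pair(combined22, sample), palette, lengths,
                tmp_path / "k.bmp", fmt="bmp",
            )

    def test_svg_byte_identical(self, tmp_path):
        msp = make_msp([[0, 1], [1, 1], [0, 0]], window_bp=1000)
        palette = lap.build_palette(msp.codebook)
        lengths = lap.chromosome_lengths([msp])
        pair = _tract_pair(msp, "S1")
        a = lap.render_lap(pair, palette, lengths, tmp_path / "a.svg",
                           fmt="svg", sample_id="S1").out_path
        b = lap.render_lap(pair, palette, lengths, tmp_path / "b.svg",
                           fmt="svg", sample_id="S1").out_path
        assert a.read_bytes() == b.read_bytes()


class TestCombineMsp:
    def test_orders_chromosome_blocks(self, rng):
        t2 = random_msp(rng, chromosome="2", n_windows=5)
        t1 = random_msp(rng, chromosome="1", n_windows=5)
        combined = lap.combine_msp([t2, t1])
        assert combined.chromosomes == ("1", "2")

    def test_sample_mismatch(self, rng):
        t1 = random_msp(rng, chromosome="1", n_samples=2)
        t2 = random_msp(rng, chromosome="2", n_samples=3)
        with pytest.raises(ValidationError, match="sample list mismatch"):
            lap.combine_msp([t1, t2])


@settings(max_examples=30, deadline=None)
@given(
    codes=st.lists(st.integers(0, 2), min_size=1, max_size=40),
    gap_at=st.integers(0, 39),
)
def test_tract_conservation_property(codes, gap_at):
    """Property: merging conserves covered bp and keeps maximality."""
    msp = make_msp([[c, c] for c in codes], window_bp=100,
                   n_ancestries=3, gaps=(gap_at,) if 0 < gap_at < len(codes) else ())
    tracts = lap.windows_to_tracts(msp, "S1", 0)
    assert sum(t.length_bp for t in tracts) == 100 * len(codes)
    for a, b in zip(tracts, tracts[1:]):
        assert not (a.end_bp == b.start_bp and a.code == b.code)
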