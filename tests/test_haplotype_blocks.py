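"""Window/block calling checked against a brute-force per-position oracle,
plus the dialect boundary conventions (strict >50 per 150 kb; >=100 per
250 kb) and the half-open coordinate rules."""

import numpy as np
import pandas as pd
import pytest

from nbgcloner import haplotype_blocks as hb
from nbgcloner import synthetic_data as sd


def brute_force_windows(positions, region, window_bp):
    """O(n_positions * n_windows) recount: assign every position to every
    window by explicit interval membership."""
    chrom, start, end = region
    windows = []
    w_start = start
    while w_start < end:
        w_end = min(w_start + window_bp, end)
        count = sum(1 for p in positions if w_start <= p < w_end)
        windows.append((w_start, w_end, count))
        w_start = w_end
    return windows


class TestDiscordantPositions:
    def _catalog(self, rows):
        return pd.DataFrame(rows, columns=["chromosome", "position_bp", "ref", "C3H", "NZO"])

    def test_identical_calls_empty(self):
        cat = self._catalog([("15", 10, "A", "G", "G"), ("15", 20, "C", "C", "C")])
        assert len(hb.discordant_positions(cat)) == 0

    def test_two_of_three_differ(self):
        cat = self._catalog([
            ("15", 10, "A", "G", "A"), ("15", 20, "C", "C", "C"), ("15", 30, "T", "T", "A"),
        ])
        assert list(hb.discordant_positions(cat)) == [10, 30]

    def test_missing_call_excluded(self):
        cat = self._catalog([("15", 10, "A", ".", "G"), ("15", 20, "C", "C", "T")])
        assert list(hb.discordant_positions(cat)) == [20]

    def test_unknown_strain_rejected(self):
        cat = self._catalog([("15", 10, "A", "G", "G")])
        with pytest.raises(ValueError):
            hb.discordant_positions(cat, "C3H", "129P2")


class TestWindowCounts:
    REGION = ("15", 1000, 2000)

    def test_no_positions_all_zero(self):
        ws = hb.window_counts([], self.REGION, 100)
        assert len(ws.df) == 10 and (ws.df["snp_count"] == 0).all()

    def test_boundary_position_goes_right(self):
        ws = hb.window_counts([1100], self.REGION, 100)
        assert ws.df.loc[0, "snp_count"] == 0 and ws.df.loc[1, "snp_count"] == 1

    def test_last_window_truncated(self):
        ws = hb.window_counts([], ("15", 0, 250), 100)
        assert list(ws.df["end_bp"]) == [100, 200, 250]

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            hb.window_counts([], ("15", 100, 100), 10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        region = ("15", 10_000, 10_000 + int(rng.integers(1, 20)) * 1000)
        positions = np.unique(rng.integers(region[1] - 500, region[2] + 500, size=300))
        ws = hb.window_counts(positions, region, 1000)
        oracle = brute_force_windows(list(positions), region, 1000)
        assert [(r.start_bp, r.end_bp, r.snp_count) for r in ws.df.itertuples()] == oracle

    def test_counts_partition_the_region(self):
        rng = np.random.default_rng(3)
        region = ("15", 0, 100_000)
        positions = np.unique(rng.integers(0, 100_000, size=2000))
        ws = hb.window_counts(positions, region, 7000)
        assert ws.df["snp_count"].sum() == hb.interval_snp_count(positions, (0, 100_000))


class TestClassification:
    def _ws(self, counts, window_bp):
        n = len(counts)
        df = pd.DataFrame({
            "chromosome": "15",
            "start_bp": np.arange(n) * window_bp,
            "end_bp": (np.arange(n) + 1) * window_bp,
            "snp_count": counts,
        })
        return hb.WindowSet(df, window_bp, ("15", 0, n * window_bp))

    @pytest.mark.parametrize("count,expected", [(0, "IBD"), (50, "IBD"), (51, "POLYMORPHIC")])
    def test_150kb_boundary_strict(self, count, expected):
        classified = hb.classify_windows(self._ws([count], 150_000), "150kb")
        assert classified.df.loc[0, "cls"] == expected

    @pytest.mark.parametrize("count,expected", [(99, "IBD"), (100, "POLYMORPHIC")])
    def test_250kb_boundary_inclusive(self, count, expected):
        classified = hb.classify_windows(self._ws([count], 250_000), "250kb")
        assert classified.df.loc[0, "cls"] == expected

    def test_window_dialect_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hb.classify_windows(self._ws([10], 100_000), "150kb")

    def test_monotone_in_count(self):
        d = hb.DIALECTS["150kb"]
        for c in range(0, 200):
            if d.is_polymorphic(c):
                assert d.is_polymorphic(c + 1)


class TestMergeBlocks:
    def _classified(self, classes, counts=None, window_bp=100):
        n = len(classes)
        counts = counts or [60] * n
        df = pd.DataFrame({
            "chromosome": "15",
            "start_bp": np.arange(n) * window_bp,
            "end_bp": (np.arange(n) + 1) * window_bp,
            "snp_count": counts,
            "cls": classes,
        })
        return hb.WindowSet(df, window_bp, ("15", 0, n * window_bp), "150kb")

    def test_two_runs(self):
        blocks = hb.merge_blocks(self._classified(
            ["POLYMORPHIC", "POLYMORPHIC", "IBD", "POLYMORPHIC"], [10, 20, 0, 5]
        ))
        assert len(blocks) == 2
        assert blocks.loc[0, ["start_bp", "end_bp", "total_snps", "n_windows"]].tolist() == [0, 200, 30, 2]
        assert blocks.loc[1, ["start_bp", "end_bp", "total_snps", "n_windows"]].tolist() == [300, 400, 5, 1]

    def test_all_ibd_empty(self):
        assert len(hb.merge_blocks(self._classified(["IBD", "IBD"]))) == 0

    def test_snp_conservation(self):
        rng = np.random.default_rng(2)
        classes = rng.choice(["IBD", "POLYMORPHIC"], size=30).tolist()
        counts = rng.integers(0, 100, size=30).tolist()
        ws = self._classified(classes, counts)
        blocks = hb.merge_blocks(ws)
        poly_total = sum(c for c, cl in zip(counts, classes) if cl == "POLYMORPHIC")
        assert (blocks["total_snps"].sum() if len(blocks) else 0) == poly_total


class TestIntervalCount:
    def test_empty_interval(self):
        assert hb.interval_snp_count([1, 2, 3], (5, 5)) == 0

    def test_half_open(self):
        assert hb.interval_snp_count([10, 20, 30], (10, 30)) == 2

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_linear_scan(self, seed):
        rng = np.random.default_rng(seed)
        pos = np.unique(rng.integers(0, 10_000, size=500))
        start, end = sorted(rng.integers(0, 10_000, size=2))
        assert hb.interval_snp_count(pos, (start, end)) == sum(
            1 for p in pos if start <= p < end
        )


class TestVcfRoundTrip:
    def test_catalog_survives_vcf_round_trip(self, tmp_path):
        cat = sd.simulate_snp_catalog(("15", 100_000, 400_000),
                                      [(150_000, 300_000, 0.5)], seed=4)
        vcf = tmp_path / "cat.vcf"
        sd.write_snp_catalog_vcf(cat, vcf)
        back = hb.read_snp_catalog_vcf(vcf)
        assert list(back["position_bp"]) == list(cat["position_bp"])
        pd.testing.assert_series_equal(back["C3H"], cat["C3H"], check_names=False)
        pd.testing.assert_series_equal(back["NZO"], cat["NZO"], check_names=False)
        # discordance is preserved exactly
        np.testing.assert_array_equal(
            hb.discordant_positions(back), hb.discordant_positions(cat)
        )


def test_reclassifying_a_merged_block_is_idempotent():
    """Re-windowing an already-polymorphic block at the same dialect keeps
    every full window polymorphic."""
    rng = np.random.default_rng(9)
    region = ("15", 0, 1_500_000)
    # dense block: ~1 SNP/kb over 10 windows of 150 kb
    positions = np.unique(rng.integers(0, 1_500_000, size=1500))
    ws = hb.classify_windows(hb.window_counts(positions, region, 150_000), "150kb")
    blocks = hb.merge_blocks(ws)
    for block in blocks.itertuples(index=False):
        sub = hb.window_counts(
            positions, ("15", block.start_bp, block.end_bp), 150_000
        )
        reclassified = hb.classify_windows(sub, "150kb")
        full = reclassified.df[
            reclassified.df["end_bp"] - reclassified.df["start_bp"] == 150_000
        ]
        assert (full["cls"] == "POLYMORPHIC").all()
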