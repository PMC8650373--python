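"""CIS caller: calibration against a brute-force null, scan semantics, ranking."""

import numpy as np
import pytest

from cisscout.catalog import dedup_sites
from cisscout.ciscall import (
    CISCall,
    ScanParams,
    calibrate_thresholds,
    call_cis,
    rank_cis,
    scan_windows,
)
from cisscout.readproc import MappedSite
from cisscout.simgen import Genome

from .oracles import brute_force_null_max, exhaustive_scan, threshold_from_null


def _catalog(positions, tumors, chrom="chr1"):
    sites = [
        MappedSite(f"r{i}", chrom, int(p), "+", tumor_id=t, specimen_id=f"{t}S1")
        for i, (p, t) in enumerate(zip(positions, tumors))
    ]
    return dedup_sites(sites, tolerance=0)


class TestCalibration:
    def test_empty_null_gives_floor_everywhere(self, coord_genome_10mb):
        params = ScanParams(mc_iterations=120, seed=1)
        table = calibrate_thresholds(0, coord_genome_10mb, params)
        assert all(table.k[w] == 5 for w in params.window_sizes)

    def test_defaults_echo_screen_definition(self):
        p = ScanParams()
        assert p.alpha == 0.05
        assert p.window_sizes == (10_000, 20_000, 30_000, 40_000)
        assert p.min_insertions_floor == 5 and p.per_tumor_cap == 2

    def test_matches_brute_force_resimulation_sharing_stream(self):
        """Independent O(n^2) Monte Carlo with the same random stream must
        reproduce the null maxima and hence the thresholds exactly."""
        genome = Genome.from_chrom_sizes({"chr1": 1_000_000})
        windows = (10_000, 25_000)
        params = ScanParams(
            window_sizes=windows, mc_iterations=150, seed=5, min_insertions_floor=1
        )
        table = calibrate_thresholds(300, genome, params)

        rng = np.random.default_rng(5)
        oracle = brute_force_null_max(rng, 300, 1_000_000, windows, 150)
        for w in windows:
            assert table.null_max[w].tolist() == oracle[w]
            assert table.k[w] == threshold_from_null(oracle[w], 0.05, 1)

    def test_threshold_monotone_in_window_size(self, coord_genome_10mb):
        params = ScanParams(mc_iterations=300, seed=3, min_insertions_floor=1)
        table = calibrate_thresholds(2_000, coord_genome_10mb, params)
        ks = [table.k[w] for w in params.window_sizes]
        assert ks == sorted(ks)

    def test_small_iteration_count_warns(self, coord_genome_10mb):
        with pytest.warns(UserWarning, match="unstable"):
            calibrate_thresholds(10, coord_genome_10mb, ScanParams(mc_iterations=99, seed=0))

    def test_motif_constrained_null_stays_near_motifs(self, small_genome):
        params = ScanParams(
            mc_iterations=120, seed=2, null_model="motif", motif_max_flank=50
        )
        table = calibrate_thresholds(200, small_genome, params)
        assert table.n_insertions == 200  # smoke: calibration runs on the restricted space

    def test_pvalues_smoothed_into_unit_interval(self, coord_genome_10mb):
        table = calibrate_thresholds(500, coord_genome_10mb, ScanParams(mc_iterations=200, seed=4))
        for w in table.window_sizes:
            assert 0 < table.pvalue(w, 1) <= 1
            assert 0 < table.pvalue(w, 10_000) <= 1


class TestScan:
    def test_sparse_positions_yield_nothing(self):
        cat = _catalog([0, 50_000, 120_000], ["A", "B", "C"])
        assert scan_windows(cat, 10_000, 2, per_tumor_cap=2) == []

    def test_five_insertions_spanning_under_window(self):
        cat = _catalog([1_000, 2_000, 3_000, 9_000, 10_500], list("ABCDE"))
        (region,) = scan_windows(cat, 10_000, 5, per_tumor_cap=2)
        assert (region.start, region.end) == (1_000, 10_501)
        assert region.counted == 5 and region.n_insertions == 5

    def test_per_tumor_cap_blocks_clonal_cluster(self):
        # 6 clustered insertions, 4 from tumor A: capped tally 2+1+1 = 4 < 5
        cat = _catalog([1_000, 1_200, 1_400, 1_600, 1_800, 2_000], list("AAAABC"))
        assert scan_windows(cat, 10_000, 5, per_tumor_cap=2) == []

    def test_capped_tally_never_exceeds_cap_per_tumor(self):
        cat = _catalog([1_000, 1_100, 1_200, 1_300, 2_000, 2_100, 2_200], list("AABBCDE"))
        (region,) = scan_windows(cat, 10_000, 5, per_tumor_cap=2)
        assert region.counted == sum(min(c, 2) for c in region.tumor_counts.values())

    def test_disqualify_mode_drops_clonal_window(self):
        cat = _catalog([1_000, 1_200, 1_400, 1_600, 1_800, 2_000], list("AAABCD"))
        assert scan_windows(cat, 10_000, 4, per_tumor_cap=2, disqualify_clonal=True) == []
        cat2 = _catalog([1_000, 1_200, 1_400, 1_600, 1_800], list("ABCDE"))
        assert len(scan_windows(cat2, 10_000, 4, per_tumor_cap=2, disqualify_clonal=True)) == 1

    def test_matches_exhaustive_enumeration_on_random_catalogs(self, rng):
        """Spot-sample of the consecutive-subset oracle (the acceptance suite
        runs the full 200-catalog comparison)."""
        for _ in range(40):
            n = int(rng.integers(2, 50))
            pos = np.sort(rng.integers(0, 60_000, size=n))
            tumors = [f"T{rng.integers(1, 8)}" for _ in range(n)]
            w = int(rng.choice([5_000, 10_000]))
            k = int(rng.integers(3, 6))
            cat = _catalog(pos, tumors)
            cpos, ctum, _ = cat.per_chrom()["chr1"]
            got = [
                (r.start, r.end, r.counted, r.n_insertions)
                for r in scan_windows(cat, w, k, per_tumor_cap=2)
            ]
            assert got == exhaustive_scan(list(cpos), list(ctum), w, k, 2)


class TestCallAndRank:
    def test_empty_catalog_empty_calls(self, coord_genome_10mb):
        assert call_cis(dedup_sites([], tolerance=5), coord_genome_10mb) == []

    def test_spike_recovered_at_smallest_window(self, coord_genome_10mb):
        positions = [5_000_000 + 1_500 * i for i in range(7)]
        cat = _catalog(positions, [f"T{i}" for i in range(7)])
        params = ScanParams(mc_iterations=200, seed=7)
        calls = call_cis(cat, coord_genome_10mb, params)
        assert len(calls) == 1
        c = calls[0]
        assert c.window == 10_000 and c.start >= 5_000_000 and c.end <= 5_000_000 + 9_001 + 1
        assert c.counted >= 5 and 0 < c.pvalue <= 1
        assert c.end - c.start <= c.window

    def test_deterministic_for_fixed_seed(self, coord_genome_10mb):
        positions = list(range(1_000, 1_000 + 7 * 1_200, 1_200)) + [9_000_000]
        cat = _catalog(positions, [f"T{i}" for i in range(8)])
        params = ScanParams(mc_iterations=150, seed=42)
        a = call_cis(cat, coord_genome_10mb, params)
        b = call_cis(cat, coord_genome_10mb, params)
        assert a == b

    def test_rank_tie_break_by_pvalue(self):
        def mk(n, p, start):
            return CISCall(
                chrom="chr1", start=start, end=start + 5_000, window=10_000, counted=min(n, 7),
                n_insertions=n, tumor_counts={}, positions=(), strands=(), tumors=(),
                pvalue=p,
            )

        calls = [mk(5, 0.02, 30_000), mk(8, 0.001, 10_000), mk(8, 0.01, 20_000)]
        ranked = rank_cis(calls)
        assert [(c.rank, c.n_insertions, c.pvalue) for c in ranked] == [
            (1, 8, 0.001),
            (2, 8, 0.01),
            (3, 5, 0.02),
        ]
        assert [c.cis_id for c in ranked] == ["CIS001", "CIS002", "CIS003"]

    def test_rank_matches_independent_sort_oracle(self, rng):
        calls = []
        for i in range(100):
            start = int(rng.integers(0, 1_000_000))
            calls.append(
                CISCall(
                    chrom=f"chr{rng.integers(1, 4)}", start=start,
                    end=start + int(rng.integers(1_000, 40_000)), window=10_000,
                    counted=5, n_insertions=int(rng.integers(5, 12)), tumor_counts={},
                    positions=(), strands=(), tumors=(),
                    pvalue=float(rng.choice([0.001, 0.01, 0.02])),
                )
            )
        chroms = ["chr1", "chr2", "chr3"]
        ranked = rank_cis(calls, chrom_order=chroms)
        oracle = sorted(
            calls,
            key=lambda c: (-c.n_insertions, c.pvalue, c.end - c.start, chroms.index(c.chrom), c.start),
        )
        assert [(c.chrom, c.start, c.end) for c in ranked] == [
            (c.chrom, c.start, c.end) for c in oracle
        ]
        assert [c.rank for c in ranked] == list(range(1, 101))

    def test_empty_rank(self):
        assert rank_cis([]) == []
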