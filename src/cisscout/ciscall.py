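"""Common-insertion-site (CIS) calling by Monte Carlo scan statistics.

A CIS is the minimal genomic region in which at least k unique insertions
cluster, where k is calibrated so that the *genome-wide* chance of such a
cluster arising from random integration is below alpha — a family-wise
criterion controlled through the Monte Carlo null distribution of the
maximum window count.  Windows are anchored at observed insertion positions
(every insertion opens a candidate window of width w), the standard scan
reduction: a set of insertions qualifies through its span, not through a
fixed genomic grid.  A per-tumor cap (default 2) limits how much any single
tumor — e.g. a clonally expanded one with local re-integration — can
contribute to the qualifying tally.

Span convention: positions p_a..p_b fit a window of size w iff
``p_b - p_a + 1 <= w``; reported intervals are 0-based half-open with
``end = p_b + 1``, so ``end - start <= w`` always holds.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import InsertionCatalog
from .simgen import Genome

DEFAULT_WINDOWS = (10_000, 20_000, 30_000, 40_000)


@dataclass(frozen=True)
class ScanParams:
    """CIS-scan configuration.

    Defaults mirror the screen's published definition: windows of 10-40 kb,
    genome-wide alpha 0.05, at least 5 insertions, and at most 2 insertions
    counted per tumor.
    """

    window_sizes: tuple = DEFAULT_WINDOWS
    alpha: float = 0.05
    mc_iterations: int = 1000
    min_insertions_floor: int = 5
    per_tumor_cap: int = 2
    seed: int = 0
    null_model: str = "uniform"  # "uniform" | "motif"
    motif_max_flank: int = 2000
    disqualify_clonal: bool = False

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        ws = tuple(self.window_sizes)
        if not ws or any(w <= 0 for w in ws) or list(ws) != sorted(ws):
            raise ValueError("window_sizes must be positive and sorted ascending")
        if self.min_insertions_floor < 1 or self.per_tumor_cap < 1:
            raise ValueError("floor and per_tumor_cap must be >= 1")
        if self.null_model not in {"uniform", "motif"}:
            raise ValueError("null_model must be 'uniform' or 'motif'")


@dataclass
class ThresholdTable:
    """Per-window-size minimum counts for genome-wide significance.

    ``k[w]`` is the smallest count whose empirical null probability of being
    reached by the genome-wide maximum window count is below alpha, floored
    at ``min_insertions_floor``.  ``null_max[w]`` keeps the full null
    distribution of the per-iteration maximum, from which empirical p-values
    are computed with (b+1)/(M+1) smoothing.
    """

    window_sizes: tuple
    k: dict
    null_max: dict
    alpha: float
    n_insertions: int
    mc_iterations: int
    seed: int
    floor: int

    def pvalue(self, w: int, count: int) -> float:
        null = self.null_max[w]
        return float((1 + int((null >= count).sum())) / (len(null) + 1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_size": list(self.window_sizes),
                "k_min": [self.k[w] for w in self.window_sizes],
                "alpha": self.alpha,
                "n_insertions": self.n_insertions,
                "mc_iterations": self.mc_iterations,
                "seed": self.seed,
            }
        )

    def to_tsv(self, path, null_path=None) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
        if null_path is not None:
            pd.DataFrame({str(w): self.null_max[w] for w in self.window_sizes}).to_csv(
                null_path, sep="\t", index=False
            )


def _allowed_intervals(genome: Genome, max_flank: int):
    """Merged global-coordinate intervals within max_flank of any motif."""
    if genome.motif_index is None:
        raise ValueError("motif-constrained null needs a genome with a motif index")
    pieces = []
    for ci, chrom in enumerate(genome.names):
        off, length = genome.offsets[ci], genome.lengths[chrom]
        occ = np.sort(
            np.concatenate([genome.motif_index[m][chrom] for m in genome.motif_index])
        )
        for m in occ:
            pieces.append((off + max(0, m - max_flank), off + min(length, m + max_flank)))
    pieces.sort()
    merged = []
    for s, e in pieces:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    starts = np.array([s for s, _ in merged], dtype=np.int64)
    lengths = np.array([e - s for s, e in merged], dtype=np.int64)
    return starts, lengths, np.concatenate([[0], np.cumsum(lengths)])


def _draw_null(rng, n, genome, params, allowed):
    """One null cohort of n global positions.

    Contract: exactly one ``rng.integers`` block of size n is consumed per
    call, so an independent re-simulation can share the random stream.
    """
    if params.null_model == "uniform":
        return rng.integers(0, genome.total_length, size=n)
    starts, lengths, cum = allowed
    u = rng.integers(0, cum[-1], size=n)
    idx = np.searchsorted(cum, u, side="right") - 1
    return starts[idx] + (u - cum[idx])


def _max_window_counts(sorted_global: np.ndarray, offsets: np.ndarray, windows):
    """Genome-wide max anchored-window count for each window size."""
    maxima = [0] * len(windows)
    bounds = np.searchsorted(sorted_global, offsets)
    for ci in range(len(offsets) - 1):
        sub = sorted_global[bounds[ci] : bounds[ci + 1]]
        if len(sub) == 0:
            continue
        idx = np.arange(len(sub))
        for wi, w in enumerate(windows):
            counts = np.searchsorted(sub, sub + w, side="left") - idx
            m = int(counts.max())
            if m > maxima[wi]:
                maxima[wi] = m
    return maxima


def calibrate_thresholds(n_insertions: int, genome: Genome, params: ScanParams) -> ThresholdTable:
    """Monte Carlo calibration of per-window minimum counts.

    Each iteration places ``n_insertions`` random positions under the null
    model and records the genome-wide maximum count over windows anchored at
    placed positions.  ``k_w`` is the smallest k with empirical
    P(max >= k) < alpha, floored at ``min_insertions_floor``.  Deterministic
    for a fixed seed.
    """
    if n_insertions < 0:
        raise ValueError("n_insertions must be >= 0")
    if params.mc_iterations < 100:
        warnings.warn("mc_iterations < 100: threshold tail estimates are unstable")
    windows = tuple(params.window_sizes)
    M = params.mc_iterations
    null_max = {w: np.zeros(M, dtype=np.int64) for w in windows}
    if n_insertions > 0:
        rng = np.random.default_rng(params.seed)
        allowed = (
            _allowed_intervals(genome, params.motif_max_flank)
            if params.null_model == "motif"
            else None
        )
        for it in range(M):
            g = np.sort(_draw_null(rng, n_insertions, genome, params, allowed))
            maxima = _max_window_counts(g, genome.offsets, windows)
            for wi, w in enumerate(windows):
                null_max[w][it] = maxima[wi]
    k = {}
    for w in windows:
        arr = null_max[w]
        kk = 1
        while (arr >= kk).mean() >= params.alpha:
            kk += 1
        k[w] = max(kk, params.min_insertions_floor)
    return ThresholdTable(
        windows, k, null_max, params.alpha, n_insertions, M, params.seed, params.min_insertions_floor
    )


# ---------------------------------------------------------------------------
# scanning


@dataclass
class Region:
    """A qualifying candidate region from a single-window scan.

    The interval is the minimal span reaching the qualifying tally;
    ``counted``/``tumor_counts``/members describe its insertions, while
    ``n_insertions`` is the raw unique-insertion count of the whole
    overlapping cluster the interval was drawn from — the locus's insertion
    frequency, used for ranking.
    """

    chrom: str
    start: int
    end: int  # half-open
    counted: int  # per-tumor-capped tally of the reported interval
    n_insertions: int  # raw unique insertions across the supporting cluster
    tumor_counts: dict
    positions: tuple
    strands: tuple
    tumors: tuple

    @property
    def span(self) -> int:
        return self.end - self.start


def _capped(tumors, cap: int) -> int:
    return sum(min(c, cap) for c in Counter(tumors).values())


def scan_windows(
    catalog: InsertionCatalog,
    w: int,
    k: int,
    per_tumor_cap: int = 2,
    disqualify_clonal: bool = False,
) -> list[Region]:
    """Emit minimal qualifying regions for one window size.

    Every maximal run of insertions whose span fits the window and whose
    per-tumor-capped unique count reaches ``k`` yields a region; overlapping
    qualifying runs collapse into one region, reported as the minimal-span
    sub-window that still reaches ``k`` (ties: more insertions, then
    leftmost).  With ``disqualify_clonal`` a window containing more than
    ``cap`` insertions from one tumor is discarded outright instead of
    being down-weighted.
    """
    regions = []
    for chrom, (pos, tumors, strands) in catalog.per_chrom().items():
        n = len(pos)
        if n == 0:
            continue
        j_excl = np.searchsorted(pos, pos + w, side="left")
        runs = []
        for i in range(n):
            if i > 0 and j_excl[i] == j_excl[i - 1]:
                continue  # contained in the previous run
            j = int(j_excl[i])
            if j - i < k:
                continue
            if disqualify_clonal:
                counts = Counter(tumors[i:j])
                if max(counts.values()) > per_tumor_cap:
                    continue
                qualifies = j - i >= k
            else:
                qualifies = _capped(tumors[i:j], per_tumor_cap) >= k
            if qualifies:
                runs.append((i, j))
        if not runs:
            continue
        # group overlapping qualifying runs
        groups = [[runs[0]]]
        for run in runs[1:]:
            if run[0] < groups[-1][-1][1]:
                groups[-1].append(run)
            else:
                groups.append([run])
        for group in groups:
            gi, gj = group[0][0], max(r[1] for r in group)
            best = _minimal_subwindow(
                pos, tumors, gi, gj, w, k, per_tumor_cap, disqualify_clonal
            )
            if best is None:
                continue
            a, b = best
            members = slice(a, b + 1)
            counts = dict(Counter(tumors[members]))
            counted = (
                b - a + 1 if disqualify_clonal else sum(min(c, per_tumor_cap) for c in counts.values())
            )
            regions.append(
                Region(
                    chrom=chrom,
                    start=int(pos[a]),
                    end=int(pos[b]) + 1,
                    counted=counted,
                    n_insertions=gj - gi,
                    tumor_counts=counts,
                    positions=tuple(int(p) for p in pos[members]),
                    strands=tuple(strands[members]),
                    tumors=tuple(tumors[members]),
                )
            )
    return regions


def _minimal_subwindow(pos, tumors, gi, gj, w, k, cap, disqualify_clonal):
    """Best qualifying index window [a, b] within the group [gi, gj).

    Minimises ``(span, -raw_count, a)`` over every consecutive subset whose
    span fits the window and whose tally reaches k — smallest region first,
    then the best-supported, then the leftmost.  Groups are small (a dense
    cluster plus its shoulders), so plain enumeration is both the clearest
    and a faithful mirror of the exhaustive definition.  Returns None when
    no sub-window qualifies (possible only in disqualify mode).
    """
    best = None
    for a in range(gi, gj):
        counts: Counter = Counter()
        capped = 0
        for b in range(a, gj):
            span = int(pos[b] - pos[a] + 1)
            if span > w:
                break
            counts[tumors[b]] += 1
            if counts[tumors[b]] <= cap:
                capped += 1
            if disqualify_clonal:
                if counts[tumors[b]] > cap:
                    break
                ok = b - a + 1 >= k
            else:
                ok = capped >= k
            if ok:
                cand = (span, -(b - a + 1), a, b)
                if best is None or cand < best:
                    best = cand
    return None if best is None else (best[2], best[3])


# ---------------------------------------------------------------------------
# calling and ranking


@dataclass
class CISCall:
    """A called common insertion site.

    The interval is the minimal span whose capped tally reached the
    calibrated threshold; ``n_insertions`` counts the full supporting
    cluster and drives the frequency ranking.
    """

    chrom: str
    start: int
    end: int
    window: int
    counted: int
    n_insertions: int
    tumor_counts: dict
    positions: tuple
    strands: tuple
    tumors: tuple
    pvalue: float
    rank: int | None = None
    cis_id: str = ""

    @property
    def span(self) -> int:
        return self.end - self.start


def call_cis(
    catalog: InsertionCatalog,
    genome: Genome,
    params: ScanParams = ScanParams(),
    thresholds: ThresholdTable | None = None,
) -> list[CISCall]:
    """Scan every window size at its calibrated threshold and emit ranked CIS.

    A locus significant at several window sizes is reported once, at the
    smallest window (tie: larger counted tally).  Each call carries the
    smoothed empirical p-value P(null genome-wide max at that window >= its
    counted tally).
    """
    if len(catalog) == 0:
        return []
    if thresholds is None:
        thresholds = calibrate_thresholds(len(catalog), genome, params)
    candidates = []  # (window, Region)
    for w in params.window_sizes:
        for region in scan_windows(
            catalog, w, thresholds.k[w], params.per_tumor_cap, params.disqualify_clonal
        ):
            candidates.append((w, region))
    if not candidates:
        return []

    chrom_rank = {name: i for i, name in enumerate(genome.names)}
    candidates.sort(key=lambda c: (chrom_rank.get(c[1].chrom, 0), c[1].start, c[1].end))
    groups: list[list] = []
    for cand in candidates:
        if groups and _overlaps(groups[-1], cand, chrom_rank):
            groups[-1].append(cand)
        else:
            groups.append([cand])

    calls = []
    for group in groups:
        w, region = min(
            group, key=lambda c: (c[0], -c[1].counted, c[1].span, c[1].start)
        )
        calls.append(
            CISCall(
                chrom=region.chrom,
                start=region.start,
                end=region.end,
                window=w,
                counted=region.counted,
                n_insertions=region.n_insertions,
                tumor_counts=region.tumor_counts,
                positions=region.positions,
                strands=region.strands,
                tumors=region.tumors,
                pvalue=thresholds.pvalue(w, region.counted),
            )
        )
    return rank_cis(calls, chrom_order=genome.names)


def _overlaps(group, cand, chrom_rank) -> bool:
    _, r = cand
    return any(
        g.chrom == r.chrom and g.start < r.end and r.start < g.end for _, g in group
    )


def rank_cis(calls: Sequence[CISCall], chrom_order=None) -> list[CISCall]:
    """Dense 1..N ranking by raw insertion frequency.

    Descending raw unique-insertion count; ties broken by smaller empirical
    p-value, then smaller interval, then genomic order.
    """
    rank_of_chrom = {c: i for i, c in enumerate(chrom_order)} if chrom_order else {}
    ordered = sorted(
        calls,
        key=lambda c: (
            -c.n_insertions,
            c.pvalue,
            c.span,
            rank_of_chrom.get(c.chrom, c.chrom),
            c.start,
        ),
    )
    out = []
    for i, c in enumerate(ordered, start=1):
        out.append(replace(c, rank=i, cis_id=f"CIS{i:03d}"))
    return out


# ---------------------------------------------------------------------------
# export


def calls_to_frame(calls: Sequence[CISCall]) -> pd.DataFrame:
    rows = [
        {
            "cis_id": c.cis_id,
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "window": c.window,
            "counted": c.counted,
            "n_insertions": c.n_insertions,
            "n_tumors": len(c.tumor_counts),
            "tumors": ",".join(f"{t}:{n}" for t, n in sorted(c.tumor_counts.items())),
            "pvalue": c.pvalue,
            "rank": c.rank,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "cis_id",
            "chrom",
            "start",
            "end",
            "window",
            "counted",
            "n_insertions",
            "n_tumors",
            "tumors",
            "pvalue",
            "rank",
        ],
    )


def calls_to_bed(calls: Sequence[CISCall], path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.cis_id}\t{c.counted}\t.\n")
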