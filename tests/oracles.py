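"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — O(n^2) loops, exhaustive
enumeration, closed forms — and shares no code with the implementation
paths it checks.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
from scipy import stats


def naive_motif_scan(seq: str, motif: str) -> list[int]:
    """Sliding str.find scan, overlaps included."""
    out, i = [], seq.find(motif)
    while i != -1:
        out.append(i)
        i = seq.find(motif, i + 1)
    return out


def brute_force_null_max(rng, n, total_len, windows, iterations):
    """O(n^2) re-simulation of the calibration null, sharing the stream.

    Draws the same one block of n uniform integers per iteration that the
    calibration draws, then counts window contents by pairwise comparison.
    Single-chromosome genomes only.  Returns {w: list of per-iteration max}.
    """
    out = {w: [] for w in windows}
    for _ in range(iterations):
        pts = sorted(int(x) for x in rng.integers(0, total_len, size=n))
        for w in windows:
            best = 0
            for x in pts:
                c = sum(1 for p in pts if x <= p <= x + w - 1)
                best = max(best, c)
            out[w].append(best)
    return out


def threshold_from_null(null_max, alpha, floor):
    k = 1
    m = len(null_max)
    while sum(1 for x in null_max if x >= k) / m >= alpha:
        k += 1
    return max(k, floor)


def exhaustive_scan(pos, tumors, w, k, cap):
    """Exhaustive consecutive-subset enumeration of qualifying regions.

    Considers every index pair (a, b); a pair qualifies when its span fits
    the window and its per-tumor-capped unique count reaches k.  Qualifying
    pairs are grouped transitively by index overlap; each group reports the
    pair minimising (span, -raw, a).  Returns a list of
    (start, end, counted, raw) tuples in genomic order.
    """
    n = len(pos)
    qual = []
    for a in range(n):
        for b in range(a, n):
            if pos[b] - pos[a] + 1 > w:
                break
            capped = sum(min(c, cap) for c in Counter(tumors[a : b + 1]).values())
            if capped >= k:
                qual.append((a, b))
    if not qual:
        return []
    # transitive grouping by index overlap
    qual.sort()
    groups = [[qual[0]]]
    for pair in qual[1:]:
        if any(pair[0] <= b and a <= pair[1] for a, b in groups[-1]):
            groups[-1].append(pair)
        else:
            groups.append([pair])
    regions = []
    for group in groups:
        best = min(
            group, key=lambda ab: (pos[ab[1]] - pos[ab[0]] + 1, -(ab[1] - ab[0] + 1), ab[0])
        )
        a, b = best
        counted = sum(min(c, cap) for c in Counter(tumors[a : b + 1]).values())
        cluster = max(p[1] for p in group) - min(p[0] for p in group) + 1
        regions.append((int(pos[a]), int(pos[b]) + 1, counted, cluster))
    return regions


def logrank_power_exponential(hr, n_per_group, baseline_hazard, censoring_rate, alpha=0.05):
    """Schoenfeld closed-form power of the two-group log-rank test.

    Exponential event times, independent exponential censoring calibrated so
    a baseline-hazard subject is censored with probability censoring_rate;
    one group at baseline hazard, the other at baseline * hr.
    """
    lam_c = (
        baseline_hazard * censoring_rate / (1 - censoring_rate) if censoring_rate > 0 else 0.0
    )
    p_event_hi = baseline_hazard * hr / (baseline_hazard * hr + lam_c)
    p_event_lo = baseline_hazard / (baseline_hazard + lam_c)
    d = n_per_group * (p_event_hi + p_event_lo)
    z = np.sqrt(d * 0.25) * abs(np.log(hr)) - stats.norm.ppf(1 - alpha / 2)
    return float(stats.norm.cdf(z))
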