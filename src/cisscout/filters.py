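"""Survival-association and dependency triage ("Filter 1").

Candidate genes predicted to be upregulated by proviral insertion are
screened for (a) an association between high expression and inferior
patient survival — the top and bottom expression quartiles compared by a
two-group log-rank test, with the hazard ratio estimated from the log-rank
observed/expected tables as (O_a/E_a)/(O_b/E_b) — and (b) functional
essentiality, as a median cell-line dependency score at or below a
threshold (more negative = more essential).  Both screens operate on plain
tabular input: simulated tables or exports from patient-outcome /
dependency portals.

Literature novelty and wet-lab knockdown (the screen's Filters 2 and 3) are
not computable and appear only as pass-through annotation columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def quartile_split(table: pd.DataFrame, gene: str):
    """Top- and bottom-quartile patient IDs by expression of one gene.

    Patients are ordered by expression with ties broken by patient ID (so
    the split is deterministic even for constant expression); the bottom and
    top floor(N/4) are returned as ``(top_ids, bottom_ids)``.  Requires at
    least 8 patients with an expression value for the gene.
    """
    if gene not in table.columns:
        raise KeyError(f"gene {gene!r} not in expression table")
    col = table[gene].dropna()
    n = len(col)
    if n < 8:
        raise ValueError(f"quartile split needs >= 8 patients, got {n}")
    order = sorted(col.index, key=lambda pid: (col[pid], str(pid)))
    q = n // 4
    bottom = order[:q]
    top = order[-q:]
    return list(top), list(bottom)


@dataclass
class LogrankResult:
    statistic: float
    pvalue: float
    hazard_ratio: float
    observed_a: float
    expected_a: float
    observed_b: float
    expected_b: float
    degenerate: bool = False  # no events at all


def logrank_hr(group_a, group_b, survival: pd.DataFrame) -> LogrankResult:
    """Two-group log-rank test with an O/E hazard-ratio estimate.

    ``survival`` is indexed by patient ID with ``time`` and ``event``
    columns (event 1 = death, 0 = censored).  The statistic is
    (O_a - E_a)^2 / V over the pooled distinct event times, with the usual
    hypergeometric variance; p comes from chi-square with 1 df; the hazard
    ratio is (O_a/E_a)/(O_b/E_b).  With zero events the result is flagged
    degenerate (p = 1, HR undefined).
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    sub = survival.loc[list(group_a) + list(group_b)]
    time = sub["time"].to_numpy(dtype=float)
    event = sub["event"].to_numpy(dtype=int)
    in_a = np.zeros(len(sub), dtype=bool)
    in_a[: len(group_a)] = True

    event_times = np.unique(time[event == 1])
    if len(event_times) == 0:
        return LogrankResult(0.0, 1.0, float("nan"), 0, 0.0, 0, 0.0, degenerate=True)

    o_a = e_a = var = 0.0
    o_b = e_b = 0.0
    for t in event_times:
        at_risk = time >= t
        n = at_risk.sum()
        n_a = (at_risk & in_a).sum()
        dying = (time == t) & (event == 1)
        d = dying.sum()
        d_a = (dying & in_a).sum()
        o_a += d_a
        o_b += d - d_a
        e_a += d * n_a / n
        e_b += d * (n - n_a) / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)

    if var == 0:
        stat, p = 0.0, 1.0
    else:
        stat = (o_a - e_a) ** 2 / var
        p = float(stats.chi2.sf(stat, df=1))
    if e_a > 0 and e_b > 0 and o_b > 0:
        hr = (o_a / e_a) / (o_b / e_b)
    else:
        hr = float("inf") if o_a > 0 and o_b == 0 else float("nan")
    return LogrankResult(float(stat), p, float(hr), o_a, e_a, o_b, e_b)


def dependency_pass(genes, table: pd.DataFrame, threshold: float = -0.5) -> dict:
    """Per-gene essentiality flag: median score across cell lines <= threshold.

    A gene absent from the table fails with a warning.  Returns
    ``{gene: (passed, median_score)}``.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    out = {}
    for gene in genes:
        if gene not in table.index:
            warnings.warn(f"gene {gene!r} absent from dependency table; flagged fail")
            out[gene] = (False, float("nan"))
            continue
        med = float(table.loc[gene].median())
        out[gene] = (med <= threshold, med)
    return out


def run_filter1(
    candidates,
    expression: pd.DataFrame,
    dependency: pd.DataFrame,
    alpha: float = 0.05,
    dependency_threshold: float = -0.5,
    survival: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Filter-1 triage over candidate genes.

    ``candidates`` is a DataFrame with ``gene`` and ``effect`` columns (or
    anything :func:`cisscout.annotate.candidates_to_frame` emits);
    ``expression`` holds per-patient expression (patients x genes) and
    ``survival`` the matching ``time``/``event`` table.  Survival pass
    requires log-rank p < alpha *and* direction consistency with the
    predicted effect (increased -> HR > 1, decreased -> HR < 1, ambiguous ->
    either).  Overall pass = survival pass AND dependency pass.  Returns one
    row per gene with columns for both screens plus empty ``filter2_note`` /
    ``filter3_note`` pass-through columns.
    """
    if survival is None:
        raise ValueError("a survival table is required")
    if isinstance(candidates, pd.DataFrame):
        cand = candidates[["gene", "effect"]].copy()
    else:
        cand = pd.DataFrame(
            [(c.gene.gene_id if c.gene else "", c.effect) for c in candidates],
            columns=["gene", "effect"],
        )
    cand = cand[cand["gene"] != ""].drop_duplicates(subset="gene", keep="first")
    genes = cand["gene"].tolist()
    dep = dependency_pass(genes, dependency, dependency_threshold)

    rows = []
    for gene, effect in cand.itertuples(index=False):
        if gene in expression.columns:
            top, bottom = quartile_split(expression, gene)
            res = logrank_hr(top, bottom, survival)
            if effect == "increased":
                consistent = res.hazard_ratio > 1
            elif effect == "decreased":
                consistent = res.hazard_ratio < 1
            else:
                consistent = True
            surv_pass = bool(res.pvalue < alpha and consistent and not res.degenerate)
            hr, statv, p = res.hazard_ratio, res.statistic, res.pvalue
        else:
            warnings.warn(f"gene {gene!r} absent from expression table; survival fail")
            surv_pass, hr, statv, p = False, float("nan"), float("nan"), float("nan")
        dpass, dmed = dep[gene]
        rows.append(
            {
                "gene": gene,
                "effect": effect,
                "hazard_ratio": hr,
                "logrank_statistic": statv,
                "logrank_p": p,
                "survival_pass": surv_pass,
                "dependency_median": dmed,
                "dependency_pass": dpass,
                "filter1_pass": surv_pass and dpass,
                "filter2_note": "",
                "filter3_note": "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "effect",
            "hazard_ratio",
            "logrank_statistic",
            "logrank_p",
            "survival_pass",
            "dependency_median",
            "dependency_pass",
            "filter1_pass",
            "filter2_note",
            "filter3_note",
        ],
    )
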