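"""G-test differential expression on stranded read counts.

Each contrast compares a treated sample group against its 0 h baseline of the
same tissue.  Replicate counts are pooled (summed, together with their
library sizes) into one 2x2 table per transcript and strand class::

    [[c_treated, c_baseline], [N_treated - c_treated, N_baseline - c_baseline]]

and tested with the log-likelihood-ratio (G) test, G = 2 * sum O*ln(O/E),
chi-square with 1 df under the null.  P-values are adjusted per (contrast,
strand class) family with the Benjamini-Hochberg step-up procedure.  Fold
changes are pseudocounted ratios of replicate-mean RPKM, fc = (rpkm_t + c) /
(rpkm_0 + c) with c = 1 by default — the convention under which a locus
silent at 0 h and at RPKM x after treatment prints fc = x + 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quantify import StrandedCountTable

__all__ = [
    "g_test",
    "bh_fdr",
    "fold_change",
    "replicate_qc",
    "run_contrasts",
    "call_responsive",
    "summarize_calls",
]

DEFAULT_ALPHA = 0.01  # figure-caption threshold; 0.001 (Methods wording) available via parameter
DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_FC_FLOOR = 1.0


def g_test(c1: int, n1: int, c2: int, n2: int) -> tuple[float, float]:
    """Log-likelihood-ratio test of equal proportions c1/n1 vs c2/n2.

    Returns (G, p) with p from chi-square (1 df).  A degenerate table (any
    zero margin) carries no information and returns (0.0, 1.0).  Terms with
    O = 0 contribute 0 to the sum.
    """
    if c1 < 0 or c2 < 0 or n1 < c1 or n2 < c2:
        raise ValueError(f"invalid table: c1={c1}, n1={n1}, c2={c2}, n2={n2}")
    if n1 + n2 <= 0:
        raise ValueError("n1 + n2 must be > 0")
    observed = np.array([[c1, c2], [n1 - c1, n2 - c2]], dtype=float)
    row = observed.sum(axis=1, keepdims=True)
    col = observed.sum(axis=0, keepdims=True)
    total = observed.sum()
    if (row == 0).any() or (col == 0).any():
        return 0.0, 1.0
    expected = row * col / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(observed > 0, observed * np.log(observed / expected), 0.0)
    g = max(2.0 * float(terms.sum()), 0.0)
    return g, float(stats.chi2.sf(g, df=1))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(rpkm_t, rpkm_0, pseudocount: float = DEFAULT_PSEUDOCOUNT):
    """Pseudocounted RPKM ratio (rpkm_t + pseudocount) / (rpkm_0 + pseudocount).

    Accepts scalars or arrays; strictly increasing in rpkm_t and strictly
    decreasing in rpkm_0.
    """
    if pseudocount < 0:
        raise ValueError(f"pseudocount must be >= 0, got {pseudocount}")
    t = np.asarray(rpkm_t, dtype=float)
    b = np.asarray(rpkm_0, dtype=float)
    if (t < 0).any() or (b < 0).any():
        raise ValueError("RPKM inputs must be >= 0")
    fc = (t + pseudocount) / (b + pseudocount)
    return float(fc) if fc.ndim == 0 else fc


def replicate_qc(
    expr: pd.DataFrame, design: pd.DataFrame, r_threshold: float = 0.9
) -> pd.DataFrame:
    """Pearson correlation between replicate RPKM vectors per sample group.

    For every (tissue, condition, time) group the RPKM vectors over all
    (transcript, strand class) cells are compared pairwise between
    replicates; the reported ``r`` is the minimum pairwise correlation and
    the group passes if r > ``r_threshold``.  A zero-variance replicate
    leaves r undefined (NaN) and fails the group.  Groups are flagged, never
    dropped.
    """
    wide = expr.pivot_table(
        index=["transcript_id", "strand_class"], columns="sample_id", values="rpkm"
    )
    rows = []
    for (tissue, cond, t), grp in design.groupby(["tissue", "condition", "time"]):
        samples = sorted(grp["sample_id"])
        r_min = math.inf
        defined = True
        if len(samples) < 2:
            rows.append(
                {"tissue": tissue, "condition": cond, "time": t,
                 "n_replicates": len(samples), "r": np.nan, "pass": False}
            )
            continue
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                x = wide[samples[i]].to_numpy(float)
                y = wide[samples[j]].to_numpy(float)
                if np.std(x) == 0 or np.std(y) == 0:
                    defined = False
                    continue
                r = float(stats.pearsonr(x, y).statistic)
                r_min = min(r_min, r)
        r_val = np.nan if (not defined or math.isinf(r_min)) else r_min
        rows.append(
            {"tissue": tissue, "condition": cond, "time": t,
             "n_replicates": len(samples), "r": r_val,
             "pass": bool(defined and r_min > r_threshold)}
        )
    return pd.DataFrame(rows)


def _pool(counts: pd.DataFrame, library_sizes: dict[str, int], samples: list[str]):
    """Sum counts per (transcript, strand class) and library sizes over samples."""
    sub = counts[counts["sample_id"].isin(samples)]
    pooled = sub.groupby(["transcript_id", "strand_class"])["count"].sum()
    n = int(sum(library_sizes[s] for s in samples))
    return pooled, n


def run_contrasts(
    table: StrandedCountTable,
    expr: pd.DataFrame,
    design: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    fc_floor: float = DEFAULT_FC_FLOOR,
    baseline_condition: str | None = None,
) -> pd.DataFrame:
    """Test every (tissue, condition, time > 0 h) group against its baseline.

    The baseline is the 0 h group of the same tissue and condition (the
    untreated-sample convention); passing ``baseline_condition`` switches to
    a time-matched control instead.  Replicates are pooled before testing;
    BH adjustment is applied within each (tissue, condition, time,
    strand class) family.  Returns the long DiffCall table with columns
    tissue, condition, time, transcript_id, strand_class, G, p, q, fc, call.
    """
    counts = table.counts
    mean_rpkm = expr.groupby(["transcript_id", "strand_class", "sample_id"])["rpkm"].first()

    frames = []
    t0 = design["time"].min()
    for (tissue, cond, t), grp in design.groupby(["tissue", "condition", "time"]):
        if baseline_condition is None:
            if t == t0:
                continue
            base = design[
                (design["tissue"] == tissue)
                & (design["condition"] == cond)
                & (design["time"] == t0)
            ]
        else:
            if cond == baseline_condition:
                continue
            base = design[
                (design["tissue"] == tissue)
                & (design["condition"] == baseline_condition)
                & (design["time"] == t)
            ]
        if base.empty:
            raise ValueError(f"no baseline samples for contrast ({tissue}, {cond}, {t})")
        treated_samples = sorted(grp["sample_id"])
        base_samples = sorted(base["sample_id"])
        pooled_t, n_t = _pool(counts, table.library_sizes, treated_samples)
        pooled_0, n_0 = _pool(counts, table.library_sizes, base_samples)

        keys = pooled_t.index.union(pooled_0.index)
        recs = []
        for tx, cls in keys:
            c_t = int(pooled_t.get((tx, cls), 0))
            c_0 = int(pooled_0.get((tx, cls), 0))
            g, p = g_test(c_t, n_t, c_0, n_0)
            rpkm_t = float(np.mean([mean_rpkm.get((tx, cls, s), 0.0) for s in treated_samples]))
            rpkm_0 = float(np.mean([mean_rpkm.get((tx, cls, s), 0.0) for s in base_samples]))
            fc = fold_change(rpkm_t, rpkm_0, pseudocount)
            recs.append((tissue, cond, t, tx, cls, g, p, fc))
        df = pd.DataFrame(
            recs,
            columns=["tissue", "condition", "time", "transcript_id", "strand_class",
                     "G", "p", "fc"],
        )
        df["q"] = np.nan
        for cls in df["strand_class"].unique():
            mask = df["strand_class"] == cls
            df.loc[mask, "q"] = bh_fdr(df.loc[mask, "p"].to_numpy())
        frames.append(df)
    calls = pd.concat(frames, ignore_index=True)
    return call_responsive(calls, alpha=alpha, fc_floor=fc_floor)


def call_responsive(
    diff: pd.DataFrame, alpha: float = DEFAULT_ALPHA, fc_floor: float = DEFAULT_FC_FLOOR
) -> pd.DataFrame:
    """Assign up / down / ns calls from q-values and fold changes.

    up iff q < alpha and fc > fc_floor; down iff q < alpha and fc <
    1/fc_floor; otherwise ns.  ``fc_floor`` defaults to 1 (significance-
    driven calls); a floor of 5 reproduces the ">5-fold" reporting filter.
    """
    if fc_floor < 1:
        raise ValueError(f"fc_floor must be >= 1, got {fc_floor}")
    out = diff.copy()
    sig = out["q"] < alpha
    out["call"] = "ns"
    out.loc[sig & (out["fc"] > fc_floor), "call"] = "up"
    out.loc[sig & (out["fc"] < 1.0 / fc_floor), "call"] = "down"
    return out


def summarize_calls(diff: pd.DataFrame) -> pd.DataFrame:
    """Up/down counts per (tissue, condition, time, strand class)."""
    sub = diff[diff["call"] != "ns"]
    summary = (
        sub.groupby(["tissue", "condition", "time", "strand_class", "call"])
        .size()
        .rename("n_transcripts")
        .reset_index()
        .sort_values(["tissue", "condition", "time", "strand_class", "call"])
        .reset_index(drop=True)
    )
    return summary
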