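"""Per-genotype LPS responsiveness calling and Venn partitioning.

A gene is LPS-responsive within a genotype when its expression after LPS
differs from the shared untreated baseline of that genotype by a two-sample
pooled-variance Student's t-test at p < alpha.  No multiple-testing
correction is applied by default — this reproduces the analysis being
re-implemented, where raw p < 0.05 is used throughout; a Benjamini-Hochberg
flag is available but off by default.
"""
from __future__ import annotations

import itertools
import logging
import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import GeneMatrix, select_samples

log = logging.getLogger(__name__)


def students_t_test(x: Iterable[float], y: Iterable[float]) -> tuple[float, float]:
    """Two-sided pooled-variance Student's t-test, df = |x| + |y| - 2.

    Degenerate inputs where both groups have zero variance are resolved by
    convention: equal means give p = 1, unequal means give p = 0 (logged).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need at least 2 observations")
    if np.var(x) == 0 and np.var(y) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        log.debug("degenerate t-test: zero variance, unequal means -> p=0")
        return float("inf") if x.mean() > y.mean() else float("-inf"), 0.0
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Precision loss occurred")
        t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def _vectorized_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise pooled-variance t-test p-values with the degenerate-row
    conventions of :func:`students_t_test`."""
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # zero-variance rows trigger a precision warning; they are resolved
        # below by the stated convention
        warnings.filterwarnings("ignore", message="Precision loss occurred")
        p = stats.ttest_ind(a, b, axis=1, equal_var=True).pvalue
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    if degenerate.any():
        equal = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p = np.where(degenerate, np.where(equal, 1.0, 0.0), p)
        n_deg = int(degenerate.sum())
        log.debug("%d genes with zero variance in both conditions resolved by convention", n_deg)
    return np.asarray(p, dtype=float)


def call_responsive(
    gm: GeneMatrix,
    genotype: str,
    timepoint: int,
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Call LPS-responsive genes for one genotype and timepoint.

    Returns one row per gene: fold_change (mean LPS / mean untreated on the
    normalized ratio scale), direction, p_value and the responsive flag
    (p < alpha).  With ``fdr=True`` the flag uses BH-adjusted p-values
    instead.
    """
    lps_cols = select_samples(gm.samples, genotype, "LPS", timepoint)
    untr_cols = select_samples(gm.samples, genotype, "untreated")
    if len(lps_cols) < 2 or len(untr_cols) < 2:
        raise ValueError(f"need >=2 LPS and untreated replicates for {genotype} at t={timepoint}")
    lps = gm.values[lps_cols].to_numpy(dtype=float)
    untr = gm.values[untr_cols].to_numpy(dtype=float)
    fold = lps.mean(axis=1) / untr.mean(axis=1)
    p = _vectorized_t(lps, untr)
    p_eff = multipletests(p, method="fdr_bh")[1] if fdr else p
    calls = pd.DataFrame(
        {
            "gene": gm.genes,
            "genotype": genotype,
            "time_min": timepoint,
            "fold_change": fold,
            "direction": np.where(fold >= 1.0, "up", "down"),
            "p_value": p,
            "responsive": p_eff < alpha,
        }
    ).reset_index(drop=True)
    log.info(
        "responsiveness %s t=%d: %d/%d genes responsive (alpha=%g%s)",
        genotype, timepoint, int(calls["responsive"].sum()), len(calls), alpha,
        ", BH-FDR" if fdr else "",
    )
    return calls


def responsive_gene_set(calls: pd.DataFrame) -> set[str]:
    return set(calls.loc[calls["responsive"], "gene"])


def legacy_threshold_filter(
    gm: GeneMatrix,
    genotype: str,
    timepoint: int,
    min_fold: float = 2.0,
    min_abs_diff: float = 500.0,
    require_reproducible: bool = True,
) -> set[str]:
    """Legacy spreadsheet-style screen on raw-scale (pre-gene-normalization)
    intensities: per independent experiment (replicate index), require a
    fold change >= min_fold (or <= 1/min_fold) AND an absolute difference
    >= min_abs_diff between LPS and untreated; with ``require_reproducible``
    the thresholds must hold in every experiment, otherwise in any one.

    Kept separate from the t-test path; it is an optional pre-screen, not
    part of the six-group classification chain.
    """
    sheet = gm.samples
    reps = sorted(sheet.loc[(sheet["genotype"] == genotype) & (sheet["treatment"] == "LPS")
                            & (sheet["time_min"] == timepoint), "replicate"])
    per_experiment = []
    for rep in reps:
        lps_id = sheet.loc[(sheet["genotype"] == genotype) & (sheet["treatment"] == "LPS")
                           & (sheet["time_min"] == timepoint) & (sheet["replicate"] == rep), "sample_id"]
        untr_id = sheet.loc[(sheet["genotype"] == genotype) & (sheet["treatment"] == "untreated")
                            & (sheet["replicate"] == rep), "sample_id"]
        if len(lps_id) != 1 or len(untr_id) != 1:
            raise ValueError(f"experiment {rep} lacks a paired LPS/untreated sample for {genotype}")
        lps = gm.values[lps_id.iloc[0]]
        untr = gm.values[untr_id.iloc[0]]
        fold = lps / untr
        meets = ((fold >= min_fold) | (fold <= 1.0 / min_fold)) & ((lps - untr).abs() >= min_abs_diff)
        per_experiment.append(meets)
    stacked = pd.concat(per_experiment, axis=1)
    kept = stacked.all(axis=1) if require_reproducible else stacked.any(axis=1)
    return set(gm.genes[kept.to_numpy()])


def wt_upregulated_min4(
    gm: GeneMatrix,
    timepoint: int,
    alpha: float = 0.05,
    min_fold: float = 4.0,
) -> set[str]:
    """Genes significantly LPS-upregulated in wild-type by at least
    ``min_fold`` (inclusive) — the entry gate to dependence classification."""
    calls = call_responsive(gm, "wt", timepoint, alpha=alpha)
    keep = calls["responsive"] & (calls["direction"] == "up") & (calls["fold_change"] >= min_fold)
    return set(calls.loc[keep, "gene"])


VENN_REGIONS = (
    "wt_only", "MK2KO_only", "MK23KO_only",
    "wt_MK2KO", "wt_MK23KO", "MK2KO_MK23KO",
    "all_three",
)


def venn_partition(wt: set, mk2ko: set, mk23ko: set) -> dict[str, int]:
    """Exact 3-set Venn region counts over the genotype responsive sets,
    plus the union and per-genotype totals."""
    wt, mk2ko, mk23ko = set(wt), set(mk2ko), set(mk23ko)
    counts = {
        "wt_only": len(wt - mk2ko - mk23ko),
        "MK2KO_only": len(mk2ko - wt - mk23ko),
        "MK23KO_only": len(mk23ko - wt - mk2ko),
        "wt_MK2KO": len((wt & mk2ko) - mk23ko),
        "wt_MK23KO": len((wt & mk23ko) - mk2ko),
        "MK2KO_MK23KO": len((mk2ko & mk23ko) - wt),
        "all_three": len(wt & mk2ko & mk23ko),
    }
    counts["union"] = len(wt | mk2ko | mk23ko)
    counts["wt_total"] = len(wt)
    counts["MK2KO_total"] = len(mk2ko)
    counts["MK23KO_total"] = len(mk23ko)
    return counts


def knockout_only_responsive(wt: set, mk2ko: set, mk23ko: set) -> set:
    """Genes LPS-responsive only when MK2 (or MK2 and MK3) is deleted:
    (MK2KO union MK23KO) minus wt."""
    return (set(mk2ko) | set(mk23ko)) - set(wt)


def call_all(
    gm: GeneMatrix,
    timepoints: Iterable[int] = (120, 360),
    genotypes: Iterable[str] = ("wt", "MK2KO", "MK23KO"),
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Responsiveness calls for every genotype x timepoint, concatenated."""
    frames = [
        call_responsive(gm, g, t, alpha=alpha, fdr=fdr)
        for g, t in itertools.product(genotypes, timepoints)
    ]
    return pd.concat(frames, ignore_index=True)


def venn_by_timepoint(calls: pd.DataFrame) -> Mapping[int, dict[str, int]]:
    """Venn partitions of the responsive sets per timepoint."""
    out = {}
    for t, sub in calls.groupby("time_min"):
        sets = {
            g: responsive_gene_set(sub[sub["genotype"] == g])
            for g in ("wt", "MK2KO", "MK23KO")
        }
        out[int(t)] = venn_partition(sets["wt"], sets["MK2KO"], sets["MK23KO"])
    return out
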