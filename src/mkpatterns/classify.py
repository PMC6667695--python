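"""Genotype comparisons, the 20% relation rule, and six-group allocation.

Wild-type-upregulated genes (>= 4-fold, p < alpha) that differ significantly
in at least one of the three pairwise genotype comparisons are "MK2- and/or
MK2/3-dependently regulated".  Each such gene is then placed by the relation
triple of its LPS-treated genotype means:

    R_wm = relation(wt,     MK2KO)   R_dm = relation(MK23KO, MK2KO)
    R_dw = relation(MK23KO, wt)

with relation(a, b) = GT / LT / EQ at a strict 20% relative difference of
the means ((a-b)/b).  The decision tree over the triple yields the six
groups (exemplars Il10, Il12b, Ifnb1, Cxcl3, Hdc, Cxcl9):

    R_wm=GT:  R_dm=GT -> III, else -> I
    R_wm=LT:  R_dw=GT -> II,  else -> IV
    R_wm=EQ:  R_dw=LT -> V, R_dw=GT -> VI, R_dw=EQ -> unclassified

Statistical stars annotate the comparisons but do not gate the group
assignment beyond the upstream dependence filter.
"""
from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .containers import GROUP_EXEMPLAR, GeneMatrix, select_samples
from .responsiveness import _vectorized_t, wt_upregulated_min4

log = logging.getLogger(__name__)

PAIRS = ("wt_vs_MK2KO", "wt_vs_MK23KO", "MK2KO_vs_MK23KO")
_PAIR_GENOTYPES = {
    "wt_vs_MK2KO": ("wt", "MK2KO"),
    "wt_vs_MK23KO": ("wt", "MK23KO"),
    "MK2KO_vs_MK23KO": ("MK2KO", "MK23KO"),
}


def star_label(p: float) -> str:
    """Significance star bands: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_genotypes(
    gm: GeneMatrix,
    timepoint: int,
    pair: str,
    alpha: float = 0.05,
    level: str = "treated",
) -> pd.DataFrame:
    """Pairwise genotype comparison for all genes at one timepoint.

    ``relative_level`` is the ratio of LPS-treated normalized means
    (first / second genotype of the pair); with ``level="induction"`` each
    genotype's LPS mean is first divided by its own untreated mean, i.e.
    the ratio of fold inductions.  p-values come from the pooled-variance
    t-test on the LPS replicate vectors.
    """
    if pair not in _PAIR_GENOTYPES:
        raise ValueError(f"unknown pair {pair!r}; expected one of {PAIRS}")
    if level not in ("treated", "induction"):
        raise ValueError("level must be 'treated' or 'induction'")
    g1, g2 = _PAIR_GENOTYPES[pair]
    a_cols = select_samples(gm.samples, g1, "LPS", timepoint)
    b_cols = select_samples(gm.samples, g2, "LPS", timepoint)
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError(f"need >=2 LPS replicates for {g1} and {g2} at t={timepoint}")
    a = gm.values[a_cols].to_numpy(dtype=float)
    b = gm.values[b_cols].to_numpy(dtype=float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    if level == "induction":
        for g, means in ((g1, "a"), (g2, "b")):
            untr = gm.values[select_samples(gm.samples, g, "untreated")].mean(axis=1).to_numpy()
            if means == "a":
                mean_a = mean_a / untr
            else:
                mean_b = mean_b / untr
    p = _vectorized_t(a, b)
    out = pd.DataFrame(
        {
            "gene": gm.genes,
            "time_min": timepoint,
            "pair": pair,
            "relative_level": mean_a / mean_b,
            "p_value": p,
            "significant": p < alpha,
            "star": [star_label(v) for v in p],
        }
    ).reset_index(drop=True)
    return out


def select_mk_dependent(
    genes: Iterable[str],
    comparisons: Mapping[str, pd.DataFrame],
    alpha: float = 0.05,
) -> set[str]:
    """Keep genes whose minimum p-value over the three pairwise genotype
    comparisons is below alpha ("at least for one condition significantly
    changed")."""
    genes = set(genes)
    pmin = None
    for pair in PAIRS:
        s = comparisons[pair].set_index("gene")["p_value"]
        pmin = s if pmin is None else np.minimum(pmin, s)
    dependent = set(pmin.index[pmin < alpha])
    return genes & dependent


def relation(mean_a: float, mean_b: float, threshold: float = 0.2) -> str:
    """GT / LT / EQ relation of two positive means at a strict relative
    threshold: GT if (a-b)/b > threshold, LT if < -threshold, else EQ."""
    if mean_a <= 0 or mean_b <= 0:
        raise ValueError("means must be positive")
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    d = (mean_a - mean_b) / mean_b
    if d > threshold:
        return "GT"
    if d < -threshold:
        return "LT"
    return "EQ"


def assign_group(triple: tuple[str, str, str]) -> str:
    """Map a relation triple (R_wm, R_dm, R_dw) to a regulatory group.

    Total and deterministic: each of the 27 triples maps to exactly one of
    I-VI or 'unclassified'.
    """
    r_wm, r_dm, r_dw = triple
    for r in triple:
        if r not in ("GT", "LT", "EQ"):
            raise ValueError(f"invalid relation {r!r}")
    if r_wm == "GT":
        return "III" if r_dm == "GT" else "I"
    if r_wm == "LT":
        return "II" if r_dw == "GT" else "IV"
    if r_dw == "LT":
        return "V"
    if r_dw == "GT":
        return "VI"
    return "unclassified"


def _genotype_means(gm: GeneMatrix, timepoint: int, level: str) -> dict[str, pd.Series]:
    means = {}
    for genotype in ("wt", "MK2KO", "MK23KO"):
        cols = select_samples(gm.samples, genotype, "LPS", timepoint)
        m = gm.values[cols].mean(axis=1)
        if level == "induction":
            m = m / gm.values[select_samples(gm.samples, genotype, "untreated")].mean(axis=1)
        means[genotype] = m
    return means


def relation_triples(
    gm: GeneMatrix,
    timepoint: int,
    threshold: float = 0.2,
    level: str = "treated",
    genes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Relation triples and group allocation for the given genes (default:
    all genes in the matrix), from the LPS-treated genotype means at one
    timepoint.  This is the allocation core; :func:`classify_all` applies
    it to the MK-dependent gene set."""
    means = _genotype_means(gm, timepoint, level)
    gene_list = sorted(genes) if genes is not None else list(gm.genes)
    rows = []
    for gene in gene_list:
        triple = (
            relation(means["wt"][gene], means["MK2KO"][gene], threshold),
            relation(means["MK23KO"][gene], means["MK2KO"][gene], threshold),
            relation(means["MK23KO"][gene], means["wt"][gene], threshold),
        )
        group = assign_group(triple)
        rows.append(
            {
                "gene": gene,
                "time_min": timepoint,
                "R_wm": triple[0],
                "R_dm": triple[1],
                "R_dw": triple[2],
                "group": group,
                "exemplar": GROUP_EXEMPLAR.get(group, ""),
            }
        )
    return pd.DataFrame(rows, columns=["gene", "time_min", "R_wm", "R_dm", "R_dw", "group", "exemplar"])


def classify_all(
    gm: GeneMatrix,
    timepoint: int,
    alpha: float = 0.05,
    threshold: float = 0.2,
    min_fold: float = 4.0,
    level: str = "treated",
) -> tuple[pd.DataFrame, dict]:
    """Run the full dependence-classification chain for one timepoint.

    Returns the per-gene assignment table (relative levels, p-values and
    stars for the three comparisons, the relation triple and the group)
    and a summary dict with group proportions among the assigned genes
    (unclassified reported separately).
    """
    wt_up = wt_upregulated_min4(gm, timepoint, alpha=alpha, min_fold=min_fold)
    comparisons = {pair: compare_genotypes(gm, timepoint, pair, alpha=alpha, level=level)
                   for pair in PAIRS}
    dependent = select_mk_dependent(wt_up, comparisons, alpha=alpha)
    log.info(
        "t=%d: %d wt-upregulated >=%g-fold, %d MK-dependent",
        timepoint, len(wt_up), min_fold, len(dependent),
    )
    if not dependent:
        log.warning("no MK-dependent genes at t=%d; empty classification", timepoint)

    assignments = relation_triples(gm, timepoint, threshold=threshold, level=level, genes=dependent)
    for pair in PAIRS:
        c = comparisons[pair].set_index("gene")
        assignments[f"level_{pair}"] = c["relative_level"].reindex(assignments["gene"]).to_numpy()
        assignments[f"p_{pair}"] = c["p_value"].reindex(assignments["gene"]).to_numpy()
        assignments[f"star_{pair}"] = c["star"].reindex(assignments["gene"]).to_numpy()

    if len(assignments):
        grouped = assignments[assignments["group"] != "unclassified"]
        n_assigned = len(grouped)
        proportions = {
            g: round(100.0 * int((grouped["group"] == g).sum()) / n_assigned) if n_assigned else 0
            for g in ("I", "II", "III", "IV", "V", "VI")
        }
        summary = {
            "time_min": timepoint,
            "n_wt_upregulated": len(wt_up),
            "n_dependent": len(dependent),
            "n_assigned": n_assigned,
            "n_unclassified": int((assignments["group"] == "unclassified").sum()),
            "group_percent": proportions,
        }
    else:
        summary = {
            "time_min": timepoint,
            "n_wt_upregulated": len(wt_up),
            "n_dependent": 0,
            "n_assigned": 0,
            "n_unclassified": 0,
            "group_percent": {g: 0 for g in ("I", "II", "III", "IV", "V", "VI")},
        }
    return assignments, summary
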