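"""Differential-result processing: significance, set classes, concordance.

Works on per-gene differential tables (``gene_id``, ``lfc``, ``p_adj``) as
produced upstream by count-based differential testing, one table per
assay (RNA or ATAC) x population x contrast.  Contrasts follow the
two-population, two-generation design: the direct treatment response
(``G3_treat``), the ancestral/transgenerational response (``G6_ancestral``)
and the control-vs-control drift contrast (``CtrlDrift``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

CONCORDANCE_CLASSES = ["up_up", "dn_dn", "up_dn", "dn_up"]


@dataclass
class RegressionSummary:
    """OLS fit summary: coefficients plus per-term partial F tests."""

    coefficients: dict[str, float]
    f_stats: dict[str, tuple[float, int, float]]  # term -> (F, df, p)
    n_obs: int
    r_squared: float = float("nan")


def flag_significant(records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Set ``significant`` to ``p_adj <= alpha`` (missing p => not significant).

    The threshold is inclusive; upstream-filtered genes carry missing p_adj
    and are never significant.
    """
    p = records["p_adj"]
    bad = p[(p < 0) | (p > 1)]
    if len(bad):
        raise ValueError(f"p_adj outside [0, 1] for {len(bad)} record(s)")
    out = records.copy()
    out["significant"] = (p <= alpha).fillna(False).astype(bool)
    return out


def classify_shared_unique(
    flags_pop1: pd.DataFrame,
    flags_pop2: pd.DataFrame,
    pop1: str = "pop1",
    pop2: str = "pop2",
) -> pd.DataFrame:
    """Partition genes into shared / unique-to-one-population / not-significant.

    Genes absent from one population's table (independent upstream filtering)
    count as not significant there rather than being dropped.
    """
    merged = pd.merge(
        flags_pop1[["gene_id", "significant"]],
        flags_pop2[["gene_id", "significant"]],
        on="gene_id", how="outer", suffixes=("_1", "_2"),
    )
    s1 = merged["significant_1"].where(merged["significant_1"].notna(), False).astype(bool)
    s2 = merged["significant_2"].where(merged["significant_2"].notna(), False).astype(bool)
    declass = np.select(
        [s1 & s2, s1 & ~s2, ~s1 & s2],
        ["shared", f"unique_{pop1}", f"unique_{pop2}"],
        default="not_sig",
    )
    return pd.DataFrame({"gene_id": merged["gene_id"], "declass": declass})


def intersect_de_da(
    deg_assignments: pd.DataFrame,
    dar_assignments: pd.DataFrame,
    pop1: str = "pop1",
    pop2: str = "pop2",
) -> dict[str, set]:
    """Genes both differentially expressed and differentially accessible.

    Per population, a gene qualifies when significant in both assays within
    that population (shared or unique-to-it in each assay's class table).
    Returns per-population DE/DA sets plus their intersection (``shared``)
    and set differences (``unique_<pop>``).
    """
    def sig_in(assign: pd.DataFrame, pop: str) -> set:
        mask = assign["declass"].isin(["shared", f"unique_{pop}"])
        return set(assign.loc[mask, "gene_id"])

    deda = {pop: sig_in(deg_assignments, pop) & sig_in(dar_assignments, pop)
            for pop in (pop1, pop2)}
    return {
        pop1: deda[pop1],
        pop2: deda[pop2],
        "shared": deda[pop1] & deda[pop2],
        f"unique_{pop1}": deda[pop1] - deda[pop2],
        f"unique_{pop2}": deda[pop2] - deda[pop1],
    }


def concordance_classify(rna_lfc: float, atac_lfc: float) -> str:
    """Concordance class from the signs of the RNA and ATAC log2 fold-changes.

    Exact zeros or missing values have no sign and yield ``undefined``.
    """
    if rna_lfc is None or atac_lfc is None:
        return "undefined"
    if np.isnan(rna_lfc) or np.isnan(atac_lfc) or rna_lfc == 0 or atac_lfc == 0:
        return "undefined"
    up_r, up_a = rna_lfc > 0, atac_lfc > 0
    return {
        (True, True): "up_up",
        (False, False): "dn_dn",
        (True, False): "up_dn",
        (False, True): "dn_up",
    }[(up_r, up_a)]


def concordance_classes(rna_lfc: pd.Series, atac_lfc: pd.Series) -> pd.Series:
    """Vectorized :func:`concordance_classify` over aligned LFC series."""
    r = pd.to_numeric(rna_lfc, errors="coerce")
    a = pd.to_numeric(atac_lfc, errors="coerce")
    out = np.select(
        [
            (r > 0) & (a > 0),
            (r < 0) & (a < 0),
            (r > 0) & (a < 0),
            (r < 0) & (a > 0),
        ],
        CONCORDANCE_CLASSES,
        default="undefined",
    )
    return pd.Series(out, index=rna_lfc.index)


def proportion_summary(class_counts: Mapping[str, int]) -> pd.DataFrame:
    """Percent of genes per class with the binomial standard error.

    pct = 100 k/n and se = 100 sqrt(p(1-p)/n) with p = k/n, the plain
    binomial proportion SE.  Full precision is returned; presentation
    rounds to 2 decimals.
    """
    n = sum(class_counts.values())
    if n <= 0:
        raise ValueError("proportion_summary needs at least one counted gene")
    if any(v < 0 for v in class_counts.values()):
        raise ValueError("negative class count")
    rows = []
    for klass, k in class_counts.items():
        p = k / n
        rows.append({
            "klass": klass,
            "k": int(k),
            "n": int(n),
            "pct": 100.0 * p,
            "se_pct": 100.0 * np.sqrt(p * (1.0 - p) / n),
        })
    return pd.DataFrame(rows, columns=["klass", "k", "n", "pct", "se_pct"])


def lfc_interaction_regression(
    table: pd.DataFrame, anova_type: int = 2
) -> RegressionSummary:
    """RNA LFC as a function of ATAC LFC, DE class, and their interaction.

    Fits ``rna_lfc ~ atac_lfc * C(declass)`` by OLS and reports partial F
    tests per term (Type II sums of squares by default, switchable to Type
    III).  With a single DE class present the model collapses to the simple
    regression ``rna_lfc ~ atac_lfc``.
    """
    df = table[["rna_lfc", "atac_lfc", "declass"]].dropna()
    levels = df["declass"].unique()
    if len(levels) >= 2 and (df.groupby("declass").size() < 3).any():
        raise ValueError("each DE class needs at least 3 observations")
    formula = (
        "rna_lfc ~ atac_lfc * C(declass)" if len(levels) >= 2 else "rna_lfc ~ atac_lfc"
    )
    model = smf.ols(formula, data=df)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise np.linalg.LinAlgError("singular design matrix in LFC regression")
    fit = model.fit()
    f_stats: dict[str, tuple[float, int, float]] = {}
    if len(levels) >= 2:
        anova = sm.stats.anova_lm(fit, typ=anova_type)
        for term, row in anova.iterrows():
            if term in ("Residual", "Intercept"):
                continue
            f_stats[term] = (float(row["F"]), int(row["df"]), float(row["PR(>F)"]))
    else:
        f_stats["atac_lfc"] = (
            float(fit.fvalue), int(fit.df_model), float(fit.f_pvalue)
        )
    return RegressionSummary(
        coefficients={k: float(v) for k, v in fit.params.items()},
        f_stats=f_stats,
        n_obs=int(fit.nobs),
        r_squared=float(fit.rsquared),
    )


def aggregate_promoter_accessibility(
    peak_results: pd.DataFrame,
    genes: pd.DataFrame,
    promoter_window: int = 1000,
) -> pd.DataFrame:
    """Collapse peak-level accessibility results to per-gene promoter values.

    The promoter is the strand-aware window running ``promoter_window`` bp
    from the 5' gene end away from the gene body.  Each gene receives the
    overlap-length-weighted mean LFC of the peaks overlapping its promoter;
    p_adj is carried over from the peak with the largest overlap.  Genes with
    no overlapping peak are omitted.
    """
    tree: dict[str, IntervalTree] = {}
    for idx, pk in peak_results.iterrows():
        tree.setdefault(pk["chrom"], IntervalTree())[pk["start"]:pk["end"]] = idx
    rows = []
    for g in genes.itertuples():
        if str(g.strand) == "-":
            p_start, p_end = g.end, g.end + promoter_window
        else:
            p_start, p_end = g.start - promoter_window, g.start
        t = tree.get(g.chrom)
        if t is None:
            continue
        hits = sorted(t[p_start:p_end], key=lambda h: h.data)
        if not hits:
            continue
        weights, lfcs, padjs, starts = [], [], [], []
        for h in hits:
            pk = peak_results.loc[h.data]
            ov = min(p_end, pk["end"]) - max(p_start, pk["start"])
            weights.append(max(ov, 0))
            lfcs.append(pk["lfc"])
            padjs.append(pk["p_adj"])
            starts.append(pk["start"])
        w = np.asarray(weights, dtype=float)
        if w.sum() <= 0:
            logger.warning("gene %s: zero overlap weights, equal weighting", g.gene_id)
            w = np.ones_like(w)
        lfc = float(np.average(lfcs, weights=w))
        # deterministic tie-break on equal weights: leftmost peak
        order = np.lexsort((starts, -w))
        rows.append({"gene_id": g.gene_id, "lfc": lfc, "p_adj": padjs[order[0]]})
    return pd.DataFrame(rows, columns=["gene_id", "lfc", "p_adj"])
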