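"""Transgenerational expression inheritance classification.

A gene is a transgenerational-inheritance (TEI) candidate when it responds
in the directly treated generation (G3), still responds in the untreated
descendant generation (G6), and is not explained by drift between the
control lineages (the control-vs-control contrast).  Direction consistency
between the generations' log2 fold-changes and the G6-on-G3 LFC regression
quantify how faithfully the response is transmitted.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .regulation import RegressionSummary

logger = logging.getLogger(__name__)


def exclude_control_drift(g6_degs: set, drift_degs: set,
                          drift_lfcs: Mapping[str, float] | None = None) -> set:
    """Drop G6 differential genes that already differ between control lineages."""
    excluded = set(g6_degs) & set(drift_degs)
    for g in sorted(excluded):
        lfc = drift_lfcs.get(g) if drift_lfcs is not None else None
        logger.info("control-drift exclusion: %s (drift LFC %s)", g, lfc)
    return set(g6_degs) - set(drift_degs)


def tei_overlap(g3_degs: set, g6_degs_filtered: set) -> tuple[set, dict[str, int]]:
    """Intersect G3 and drift-filtered G6 differential genes.

    Also returns the four-way partition counts for Venn-style reporting.
    """
    g3, g6 = set(g3_degs), set(g6_degs_filtered)
    both = g3 & g6
    counts = {
        "g3_only": len(g3 - g6),
        "g6_only": len(g6 - g3),
        "both": len(both),
        "union": len(g3 | g6),
    }
    return both, counts


def direction_consistency(
    records: pd.DataFrame, subset: Iterable[str] | None = None
) -> tuple[pd.DataFrame, float]:
    """Per-gene sign agreement of G3 and G6 LFCs and the percent consistent.

    ``records`` needs gene_id, g3_lfc, g6_lfc.  Genes with an exact-zero LFC
    have undefined direction and leave the denominator (logged).  The
    percent is rounded to the nearest integer, matching how such figures
    are reported; the flags retain full information.
    """
    df = records if subset is None else records[records["gene_id"].isin(set(subset))]
    df = df.copy()
    defined = (df["g3_lfc"] != 0) & (df["g6_lfc"] != 0) \
        & df["g3_lfc"].notna() & df["g6_lfc"].notna()
    n_undef = int((~defined).sum())
    if n_undef:
        logger.info("direction consistency: %d gene(s) with zero/missing LFC excluded", n_undef)
    consistent = np.sign(df["g3_lfc"]) == np.sign(df["g6_lfc"])
    df["direction_consistent"] = consistent.where(defined, other=pd.NA)
    denom = int(defined.sum())
    pct = float(round(100.0 * (consistent & defined).sum() / denom)) if denom else float("nan")
    return df, pct


def crossgen_regression(
    records: pd.DataFrame, subset: Iterable[str] | None = None
) -> RegressionSummary:
    """OLS of G6 LFC on G3 LFC over a gene subset: slope, F, df, p."""
    df = records if subset is None else records[records["gene_id"].isin(set(subset))]
    df = df[["g3_lfc", "g6_lfc"]].dropna()
    if len(df) < 3:
        raise ValueError("crossgen regression needs at least 3 genes")
    if np.allclose(df["g3_lfc"].var(ddof=0), 0.0):
        raise np.linalg.LinAlgError("zero variance in G3 LFC: singular design")
    fit = smf.ols("g6_lfc ~ g3_lfc", data=df).fit()
    return RegressionSummary(
        coefficients={k: float(v) for k, v in fit.params.items()},
        f_stats={"g3_lfc": (float(fit.fvalue), int(fit.df_model), float(fit.f_pvalue))},
        n_obs=int(fit.nobs),
        r_squared=float(fit.rsquared),
    )


def keyword_flag(
    descriptions: pd.DataFrame,
    keyword_groups: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Flag genes whose free-text description matches any group substring.

    Matching is case-insensitive substring search (so "epigen" hits
    "epigenetic"); a gene may match several groups.  ``descriptions`` needs
    gene_id and description columns.
    """
    desc = descriptions["description"].fillna("").astype(str).str.casefold()
    out = pd.DataFrame({"gene_id": descriptions["gene_id"]})
    for group, words in keyword_groups.items():
        mask = pd.Series(False, index=desc.index)
        for w in words:
            mask |= desc.str.contains(str(w).casefold(), regex=False)
        out[group] = mask.values
    return out


def geneset_membership_report(
    deg_records: pd.DataFrame,
    curated_sets: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Intersect a differential gene table with curated gene sets.

    ``deg_records`` needs gene_id and may carry g3_lfc/g6_lfc and
    direction_consistent columns, which are passed through for members.
    One row per (set, member gene); sets with no members yield a single
    empty-membership row so every queried set appears in the report.
    """
    carry = [c for c in ("g3_lfc", "g6_lfc", "direction_consistent")
             if c in deg_records.columns]
    rows = []
    for name in sorted(curated_sets):
        members = deg_records[deg_records["gene_id"].isin(set(curated_sets[name]))]
        if len(members) == 0:
            rows.append({"set_name": name, "gene_id": "", "n_members_found": 0,
                         **{c: np.nan for c in carry}})
            continue
        for rec in members.sort_values("gene_id").itertuples(index=False):
            rows.append({
                "set_name": name,
                "gene_id": rec.gene_id,
                "n_members_found": len(members),
                **{c: getattr(rec, c) for c in carry},
            })
    return pd.DataFrame(rows, columns=["set_name", "gene_id", "n_members_found", *carry])
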