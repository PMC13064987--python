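"""Chi-squared association of per-gene TE class with regulation classes.

Genes carry a three-level TE factor (no TE, reference TE, non-reference TE;
genes linked to several insertions collapse by the precedence
non-reference > reference, non-reference insertions being the ones most
likely to be recent and polymorphic).  Five characteristics are tested per
population: differential-expression class, differential-accessibility
class, direction of significant expression change, direction of
significant accessibility change, and joint expression/accessibility
direction over all genes.  Significant omnibus tests are followed by
cell-wise standardized-residual post-hoc tests with Bonferroni adjustment
across the cells of that table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .regulation import concordance_classes

logger = logging.getLogger(__name__)

TE_CLASS_LEVELS = ["none", "reference", "non_reference"]


@dataclass
class ContingencyResult:
    """Omnibus chi-squared result with optional post-hoc cell statistics."""

    observed: pd.DataFrame
    expected: pd.DataFrame
    chi2: float
    df: int
    p: float
    cell_residuals: pd.DataFrame | None = None
    cell_p_adj: pd.DataFrame | None = None
    characteristic: str = ""
    population: str = ""


def build_te_class_labels(
    links: pd.DataFrame, tes: pd.DataFrame, genes: pd.DataFrame
) -> pd.DataFrame:
    """One TE-class label per gene, non_reference taking precedence.

    A gene linked to at least one non-reference insertion is
    ``non_reference``; otherwise ``reference`` if linked to any reference
    insertion; otherwise ``none``.
    """
    te_type = tes.set_index("te_id")["te_type"]
    label = pd.Series("none", index=pd.Index(genes["gene_id"], name="gene_id"))
    if len(links):
        unknown = set(links["te_id"]) - set(te_type.index)
        if unknown:
            raise ValueError(f"links reference unknown TEs: {sorted(unknown)[:5]}")
        linked = links.assign(te_type=links["te_id"].map(te_type))
        has_nr = linked.loc[linked["te_type"] == "non_reference", "gene_id"].unique()
        has_r = linked.loc[linked["te_type"] == "reference", "gene_id"].unique()
        label.loc[label.index.intersection(has_r)] = "reference"
        label.loc[label.index.intersection(has_nr)] = "non_reference"
    return label.rename("te_class").reset_index()


def pearson_chi2(observed: pd.DataFrame | np.ndarray) -> ContingencyResult:
    """Pearson chi-squared test of independence, no continuity correction.

    Rows/columns with zero margins are dropped (with a warning) before
    testing; expected counts are the outer product of margins over the
    total.
    """
    obs = pd.DataFrame(observed).astype(float)
    if (obs.values < 0).any():
        raise ValueError("negative counts in contingency table")
    row_ok = obs.sum(axis=1) > 0
    col_ok = obs.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        logger.warning("dropping zero-margin rows/columns before chi-squared test")
        obs = obs.loc[row_ok, col_ok]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table needs >=2 rows and >=2 columns with positive margins")
    chi2, p, df, expected = stats.chi2_contingency(obs.values, correction=False)
    return ContingencyResult(
        observed=obs,
        expected=pd.DataFrame(expected, index=obs.index, columns=obs.columns),
        chi2=float(chi2),
        df=int(df),
        p=float(p),
    )


def posthoc_cell_tests(result: ContingencyResult) -> ContingencyResult:
    """Standardized-residual test for every cell, Bonferroni over the table.

    The residual for cell (i, j) is (O - E) / sqrt(E (1 - r_i/N)(1 - c_j/N));
    each gets a two-sided normal p-value multiplied by the number of cells
    (capped at 1).
    """
    obs = result.observed.values
    exp = result.expected.values
    n = obs.sum()
    r = obs.sum(axis=1, keepdims=True) / n
    c = obs.sum(axis=0, keepdims=True) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - exp) / np.sqrt(exp * (1.0 - r) * (1.0 - c))
    z = np.where(np.isfinite(z), z, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p_adj = np.minimum(p * obs.size, 1.0)
    result.cell_residuals = pd.DataFrame(
        z, index=result.observed.index, columns=result.observed.columns
    )
    result.cell_p_adj = pd.DataFrame(
        p_adj, index=result.observed.index, columns=result.observed.columns
    )
    return result


def _characteristics(gene_table: pd.DataFrame) -> dict[str, pd.Series]:
    """The five tested gene characteristics, derived from a merged gene table.

    ``gene_table`` needs columns rna_declass, atac_declass, rna_lfc,
    atac_lfc, rna_sig, atac_sig for one population's focal contrast.
    """
    rna_dir = pd.Series(
        np.where(gene_table["rna_lfc"] > 0, "up", "down"), index=gene_table.index
    ).where(gene_table["rna_sig"].astype(bool) & (gene_table["rna_lfc"] != 0))
    atac_dir = pd.Series(
        np.where(gene_table["atac_lfc"] > 0, "up", "down"), index=gene_table.index
    ).where(gene_table["atac_sig"].astype(bool) & (gene_table["atac_lfc"] != 0))
    joint = concordance_classes(gene_table["rna_lfc"], gene_table["atac_lfc"])
    return {
        "de_class": gene_table["rna_declass"],
        "da_class": gene_table["atac_declass"],
        "expression_direction": rna_dir,
        "accessibility_direction": atac_dir,
        "joint_direction": joint.where(joint != "undefined"),
    }


def run_te_association_suite(
    gene_table: pd.DataFrame,
    te_labels: pd.DataFrame,
    population: str = "pop",
    alpha: float = 0.05,
) -> list[ContingencyResult]:
    """Run the five TE-class association tests for one population.

    Each characteristic is cross-tabulated against the TE class; tests with
    fewer than two observed levels on either axis are skipped with a
    warning, and post-hoc cell tests run only when the omnibus p <= alpha.
    """
    merged = gene_table.merge(te_labels, on="gene_id", how="left")
    merged["te_class"] = merged["te_class"].fillna("none")
    results: list[ContingencyResult] = []
    for name, series in _characteristics(merged).items():
        tab = pd.crosstab(merged["te_class"], series.dropna().reindex(merged.index))
        tab = tab.reindex(
            [lv for lv in TE_CLASS_LEVELS if lv in tab.index]
        )
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            logger.warning(
                "%s/%s: fewer than 2 observed levels, test skipped", population, name
            )
            continue
        res = pearson_chi2(tab)
        res.characteristic = name
        res.population = population
        if res.p <= alpha:
            posthoc_cell_tests(res)
        results.append(res)
    return results


def association_report(results: list[ContingencyResult]) -> pd.DataFrame:
    """Flatten suite results: one omnibus row per test plus cell rows."""
    rows = []
    for res in results:
        rows.append({
            "population": res.population, "characteristic": res.characteristic,
            "row": "", "col": "", "chi2": res.chi2, "df": res.df, "p": res.p,
            "residual": np.nan, "cell_p_adj": np.nan,
        })
        if res.cell_residuals is not None:
            for i in res.cell_residuals.index:
                for j in res.cell_residuals.columns:
                    rows.append({
                        "population": res.population,
                        "characteristic": res.characteristic,
                        "row": str(i), "col": str(j),
                        "chi2": np.nan, "df": np.nan, "p": np.nan,
                        "residual": res.cell_residuals.loc[i, j],
                        "cell_p_adj": res.cell_p_adj.loc[i, j],
                    })
    return pd.DataFrame(rows, columns=[
        "population", "characteristic", "row", "col",
        "chi2", "df", "p", "residual", "cell_p_adj",
    ])
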