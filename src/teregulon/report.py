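"""Combined per-gene master table and candidate-gene reports.

The master table joins every differential result (both assays, both
populations, all contrasts), the cross-population DE/DA class per assay,
and the TE annotations into one row per gene.  Candidate tables pair
population-unique TE insertions with population-unique regulatory
responses: for each focal population and contrast, genes linked (within
the annotation window) to an insertion found only in that population and
whose focal response (expression, accessibility, or descendant-generation
expression) is unique to it, ranked by descending absolute focal LFC with
genes sharing one insertion grouped under that insertion.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio

RESPONSE_EXPRESSION = "Exp"
RESPONSE_ACCESSIBILITY = "Acc"


def build_master_table(
    diff: dict[tuple[str, str, str], pd.DataFrame],
    declass: dict[tuple[str, str], pd.DataFrame],
    links: dict[str, pd.DataFrame],
    tes: dict[str, pd.DataFrame],
    populations: tuple[str, str],
) -> pd.DataFrame:
    """Full outer join of all per-gene results; one row per gene.

    ``diff`` is keyed (assay, population, contrast) with significance
    flags already set; ``declass`` is keyed (assay, contrast); ``links``
    and ``tes`` are per-population TE-gene links and consensus sets.
    Missing cells stay NaN/absent.
    """
    pieces = []
    for (assay, pop, contrast), df in sorted(diff.items()):
        if df["gene_id"].duplicated().any():
            raise ValueError(f"duplicate gene ids in {assay}/{pop}/{contrast} table")
        a = assay.lower()
        piece = df.set_index("gene_id")[["lfc", "significant"]].rename(columns={
            "lfc": f"{a}_lfc_{pop}_{contrast}",
            "significant": f"{a}_sig_{pop}_{contrast}",
        })
        pieces.append(piece)
    for (assay, contrast), df in sorted(declass.items()):
        a = assay.lower()
        pieces.append(df.set_index("gene_id")[["declass"]].rename(
            columns={"declass": f"{a}_declass_{contrast}"}
        ))
    master = pd.concat(pieces, axis=1, join="outer")

    for pop in populations:
        link = links.get(pop, pd.DataFrame(columns=["te_id", "gene_id",
                                                    "relative_position", "distance"]))
        te = tes.get(pop, pd.DataFrame())
        if len(link) and len(te):
            te_info = te.set_index("te_id")
            if "population_unique" in te_info.columns:
                uniq = link["te_id"].map(te_info["population_unique"]).astype(bool)
            else:
                uniq = pd.Series(False, index=link.index)
            annotated = link.assign(
                family=link["te_id"].map(te_info["family"]),
                te_type=link["te_id"].map(te_info["te_type"]),
                unique=uniq,
            ).sort_values(["gene_id", "te_id"])
            agg = annotated.groupby("gene_id").agg(
                te_ids=("te_id", ";".join),
                te_families=("family", ";".join),
                te_types=("te_type", ";".join),
                te_positions=("relative_position", ";".join),
                te_unique=("unique", "any"),
            )
        else:
            agg = pd.DataFrame(columns=["te_ids", "te_families", "te_types",
                                        "te_positions", "te_unique"])
        agg = agg.rename(columns={c: f"{c}_{pop}" for c in agg.columns})
        master = master.join(agg, how="left")
        col = master[f"te_unique_{pop}"]
        master[f"te_unique_{pop}"] = col.where(col.notna(), False).astype(bool)
        for c in (f"te_ids_{pop}", f"te_families_{pop}", f"te_types_{pop}",
                  f"te_positions_{pop}"):
            master[c] = master[c].fillna("")

    master = master.sort_index().reset_index().rename(columns={"index": "gene_id"})
    return master


def build_candidate_table(
    master: pd.DataFrame,
    tes: pd.DataFrame,
    links: pd.DataFrame,
    population: str,
    other_population: str,
    contrast: str = "G3_treat",
    response_kind: str = RESPONSE_EXPRESSION,
) -> pd.DataFrame:
    """Population-unique TEs linked to population-unique responses, ranked.

    ``response_kind`` selects the focal assay: ``Exp`` ranks by RNA LFC of
    the focal contrast, ``Acc`` by ATAC LFC.  The response column reports
    ``Both`` when the gene's other-assay class is also unique to the focal
    population.  Rows are grouped by insertion, insertions ordered by their
    best absolute focal LFC (ties broken by gene id, then te id), and
    coordinates printed 1-based inclusive.
    """
    focal_assay = "rna" if response_kind == RESPONSE_EXPRESSION else "atac"
    other_assay = "atac" if focal_assay == "rna" else "rna"
    declass_col = f"{focal_assay}_declass_{contrast}"
    other_declass_col = f"{other_assay}_declass_{contrast}"
    target = f"unique_{population}"

    uniq_tes = tes[tes.get("population_unique", pd.Series(dtype=bool)) == True]  # noqa: E712
    if len(uniq_tes) == 0 or len(links) == 0:
        return _empty_candidates(population, other_population)
    info = master.set_index("gene_id")
    cand = links[links["te_id"].isin(set(uniq_tes["te_id"]))]
    cand = cand[cand["gene_id"].isin(info.index)]
    cand = cand[info.loc[cand["gene_id"], declass_col].values == target]
    if len(cand) == 0:
        return _empty_candidates(population, other_population)

    te_info = uniq_tes.set_index("te_id")
    rows = []
    for r in cand.itertuples():
        g = info.loc[r.gene_id]
        te = te_info.loc[r.te_id]
        other_unique = g.get(other_declass_col) == target
        focal_lfc = g[f"{focal_assay}_lfc_{population}_{contrast}"]
        rows.append({
            "te_id": r.te_id,
            "te_family": te["family"],
            "chrom": te["chrom"],
            "insertion_range": f"{int(te['start']) + 1}-{int(te['end'])}",
            "te_type": "R" if te["te_type"] == "reference" else "NR",
            "gene_id": r.gene_id,
            "te_position": r.relative_position,
            "response": "Both" if other_unique else response_kind,
            "focal_lfc": focal_lfc,
            f"rna_lfc_{population}": g.get(f"rna_lfc_{population}_{contrast}", np.nan),
            f"atac_lfc_{population}": g.get(f"atac_lfc_{population}_{contrast}", np.nan),
            f"rna_lfc_{other_population}": g.get(f"rna_lfc_{other_population}_{contrast}", np.nan),
            f"atac_lfc_{other_population}": g.get(f"atac_lfc_{other_population}_{contrast}", np.nan),
            f"rna_sig_{population}": bool(g.get(f"rna_sig_{population}_{contrast}", False)),
            f"atac_sig_{population}": bool(g.get(f"atac_sig_{population}_{contrast}", False)),
        })
    out = pd.DataFrame(rows)
    out["_abs"] = out["focal_lfc"].abs()
    # insertion groups ranked by their best gene; genes within a group by |LFC|
    grp_best = out.groupby("te_id")["_abs"].transform("max")
    grp_gene = out.loc[out.groupby("te_id")["_abs"].transform(
        lambda s: s == s.max()), :].groupby("te_id")["gene_id"].min()
    out["_grp_best"] = grp_best
    out["_grp_gene"] = out["te_id"].map(grp_gene)
    out = out.sort_values(
        ["_grp_best", "_grp_gene", "te_id", "_abs", "gene_id"],
        ascending=[False, True, True, False, True], kind="mergesort",
    ).drop(columns=["_abs", "_grp_best", "_grp_gene", "focal_lfc"])
    return out.reset_index(drop=True)


def _empty_candidates(population: str, other_population: str) -> pd.DataFrame:
    return pd.DataFrame(columns=[
        "te_id", "te_family", "chrom", "insertion_range", "te_type",
        "gene_id", "te_position", "response",
        f"rna_lfc_{population}", f"atac_lfc_{population}",
        f"rna_lfc_{other_population}", f"atac_lfc_{other_population}",
        f"rna_sig_{population}", f"atac_sig_{population}",
    ])


def write_reports(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    config: object | None = None,
    seed: int | None = None,
) -> dict:
    """Write every report TSV plus a JSON run manifest; deterministic.

    The manifest records a config digest, the seed, and per-file sha256 and
    row counts, so identical inputs and configuration produce
    byte-identical output trees.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = {}
    for name in sorted(tables):
        path = out_dir / f"{name}.tsv"
        tio.write_table(tables[name], path)
        entries[name] = {
            "sha256": tio.sha256_of(path),
            "n_rows": int(len(tables[name])),
        }
    if config is None:
        digest = ""
    else:
        cfg = dataclasses.asdict(config) if dataclasses.is_dataclass(config) else config
        digest = hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest()
    tio.write_manifest(out_dir / "manifest.json", entries, digest, seed)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    return manifest
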