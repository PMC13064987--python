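"""End-to-end orchestration: config validation, staging, and the run itself.

Stages run in a fixed order — TE consensus, regulation, association,
transgenerational classification, reporting — with structured log lines
(stage name, wall time, row counts) and all intermediate products written
to the output directory as plain TSV so partial runs stay inspectable.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, io as tio, regulation, report, synthetic, te_consensus, transgen

logger = logging.getLogger(__name__)

DEFAULT_KEYWORD_GROUPS = {
    "stress": ["stress"],
    "epigenome": ["epigen", "chromatin", "histone", "methyl"],
}
CONTRASTS = ("G3_treat", "G6_ancestral", "CtrlDrift")


@dataclass
class RunConfig:
    """Validated run configuration (paths + thresholds)."""

    populations: tuple[str, str]
    genes: Path
    reference_status: dict[str, Path]
    nonref_calls: dict[str, dict[str, Path]]
    diff_tables: dict[str, dict[str, dict[str, Path]]]
    out_dir: Path
    atac_peaks: dict[str, dict[str, Path]] = field(default_factory=dict)
    descriptions: Path | None = None
    gene_sets: dict[str, Path] = field(default_factory=dict)
    keyword_groups: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_KEYWORD_GROUPS.items()}
    )
    alpha: float = 0.05
    window: int = 1000
    merge_distance: int = 25
    min_samples: int = 2
    n_samples: int = 3
    match_distance: int = 25
    promoter_window: int = 1000
    seed: int | None = None


def validate_config(path: str | Path) -> RunConfig:
    """Parse and cross-check a YAML run config, reporting all problems at once."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    base = Path(path).parent
    errors: list[str] = []

    def resolve(p) -> Path:
        p = Path(p)
        return p if p.is_absolute() else base / p

    def need_file(key: str, p) -> Path:
        rp = resolve(p)
        if not rp.exists():
            errors.append(f"{key}: file not found: {rp}")
        return rp

    pops = raw.get("populations")
    if not (isinstance(pops, list) and len(pops) == 2):
        errors.append("populations: exactly two population names required")
        pops = ["pop1", "pop2"]

    genes = need_file("genes", raw["genes"]) if "genes" in raw else None
    if genes is None:
        errors.append("genes: missing required key")

    ref_status, calls, diff = {}, {}, {}
    for pop in pops:
        try:
            ref_status[pop] = need_file(f"reference_status.{pop}",
                                        raw["reference_status"][pop])
        except (KeyError, TypeError):
            errors.append(f"reference_status.{pop}: missing required key")
        try:
            calls[pop] = {
                caller: need_file(f"nonref_calls.{pop}.{caller}", p)
                for caller, p in raw["nonref_calls"][pop].items()
            }
            if len(calls[pop]) != 2:
                errors.append(f"nonref_calls.{pop}: exactly two callers required")
        except (KeyError, TypeError):
            errors.append(f"nonref_calls.{pop}: missing required key")
    peaks: dict[str, dict[str, Path]] = {}
    for pop, per_contrast in (raw.get("atac_peaks") or {}).items():
        peaks[pop] = {
            contrast: need_file(f"atac_peaks.{pop}.{contrast}", p)
            for contrast, p in (per_contrast or {}).items()
        }
    for assay in ("RNA", "ATAC"):
        diff[assay] = {}
        for pop in pops:
            diff[assay][pop] = {}
            for contrast in CONTRASTS:
                # a peak-level table can stand in for a gene-level ATAC table
                if assay == "ATAC" and contrast in peaks.get(pop, {}):
                    continue
                try:
                    diff[assay][pop][contrast] = need_file(
                        f"diff_tables.{assay}.{pop}.{contrast}",
                        raw["diff_tables"][assay][pop][contrast],
                    )
                except (KeyError, TypeError):
                    errors.append(
                        f"diff_tables.{assay}.{pop}.{contrast}: missing required key"
                    )

    thresholds = {}
    for key, default in (("alpha", 0.05), ("window", 1000), ("merge_distance", 25),
                         ("min_samples", 2), ("n_samples", 3), ("match_distance", 25),
                         ("promoter_window", 1000)):
        val = raw.get(key, default)
        if not isinstance(val, (int, float)) or val <= 0:
            errors.append(f"{key}: must be a positive number, got {val!r}")
        thresholds[key] = val

    descriptions = None
    if raw.get("descriptions"):
        descriptions = need_file("descriptions", raw["descriptions"])
    gene_sets = {
        name: need_file(f"gene_sets.{name}", p)
        for name, p in (raw.get("gene_sets") or {}).items()
    }
    if "out_dir" not in raw:
        errors.append("out_dir: missing required key")

    if errors:
        raise ValueError(
            f"invalid run config {path}:\n  " + "\n  ".join(errors)
        )
    return RunConfig(
        populations=tuple(pops),
        genes=genes,
        reference_status=ref_status,
        nonref_calls=calls,
        diff_tables=diff,
        out_dir=resolve(raw["out_dir"]),
        atac_peaks=peaks,
        descriptions=descriptions,
        gene_sets=gene_sets,
        keyword_groups=raw.get("keyword_groups", DEFAULT_KEYWORD_GROUPS),
        alpha=float(thresholds["alpha"]),
        window=int(thresholds["window"]),
        merge_distance=int(thresholds["merge_distance"]),
        min_samples=int(thresholds["min_samples"]),
        n_samples=int(thresholds["n_samples"]),
        match_distance=int(thresholds["match_distance"]),
        promoter_window=int(thresholds["promoter_window"]),
        seed=raw.get("seed"),
    )


def classify_all(
    diff: dict[tuple[str, str, str], pd.DataFrame],
    populations: tuple[str, str],
) -> dict[tuple[str, str], pd.DataFrame]:
    """Shared/unique class tables for every assay and contrast present."""
    pop1, pop2 = populations
    declass: dict[tuple[str, str], pd.DataFrame] = {}
    for assay, pop, contrast in diff:
        if pop != pop1 or (assay, contrast) in declass:
            continue
        declass[(assay, contrast)] = regulation.classify_shared_unique(
            diff[(assay, pop1, contrast)], diff[(assay, pop2, contrast)],
            pop1=pop1, pop2=pop2,
        )
    return declass


def build_population_gene_table(
    diff: dict[tuple[str, str, str], pd.DataFrame],
    declass: dict[tuple[str, str], pd.DataFrame],
    pop: str,
    contrast: str = "G3_treat",
) -> pd.DataFrame:
    """Per-gene association inputs for one population and contrast.

    Collapses the cross-population DE/DA classes to the population-local
    three-level factor (shared / unique-to-this-population / not
    significant) and joins both assays' LFCs and significance flags.
    """
    gt = pd.merge(
        diff[("RNA", pop, contrast)][["gene_id", "lfc", "significant"]].rename(
            columns={"lfc": "rna_lfc", "significant": "rna_sig"}),
        diff[("ATAC", pop, contrast)][["gene_id", "lfc", "significant"]].rename(
            columns={"lfc": "atac_lfc", "significant": "atac_sig"}),
        on="gene_id",
    )
    for assay, col in (("RNA", "rna_declass"), ("ATAC", "atac_declass")):
        cls = declass[(assay, contrast)].set_index("gene_id")["declass"]
        gt[col] = gt["gene_id"].map(cls).map(
            lambda c: "shared" if c == "shared"
            else ("unique" if c == f"unique_{pop}" else "not_sig")
        )
    return gt


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage=%s status=start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            status = "error" if exc_type else "done"
            logger.info("stage=%s status=%s wall_s=%.2f", name, status, dt)
            return False

    return _Timer()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages on the configured inputs; returns the run manifest."""
    pop1, pop2 = config.populations

    with _stage("te_consensus"):
        genes = tio.read_gene_annotation(config.genes)
        if len(genes) == 0:
            raise ValueError("empty gene annotation")
        known_chroms = set(genes["chrom"])
        tes: dict[str, pd.DataFrame] = {}
        for pop in config.populations:
            status = tio.read_reference_status(config.reference_status[pop])
            samples = sorted(status["sample_id"].unique())
            ref = te_consensus.consolidate_reference_tes(
                status, samples, population=pop, known_chroms=known_chroms
            )
            caller_tables = [
                tio.read_nonref_calls(p) for p in config.nonref_calls[pop].values()
            ]
            nonref = te_consensus.consolidate_nonreference_tes(
                caller_tables[0], caller_tables[1],
                merge_distance=config.merge_distance,
                min_samples=config.min_samples,
                n_samples=config.n_samples,
                population=pop, known_chroms=known_chroms,
            )
            tes[pop] = pd.concat([ref, nonref], ignore_index=True)
            logger.info("stage=te_consensus pop=%s n_reference=%d n_nonreference=%d",
                        pop, len(ref), len(nonref))
        tes[pop1], tes[pop2] = te_consensus.label_population_unique(
            tes[pop1], tes[pop2], match_distance=config.match_distance
        )
        links = {
            pop: te_consensus.annotate_te_gene_links(tes[pop], genes,
                                                     window=config.window)
            for pop in config.populations
        }

    with _stage("regulation"):
        diff: dict[tuple[str, str, str], pd.DataFrame] = {}
        for assay, per_pop in config.diff_tables.items():
            for pop, per_contrast in per_pop.items():
                for contrast, path in per_contrast.items():
                    records = tio.read_diff_table(path)
                    diff[(assay, pop, contrast)] = regulation.flag_significant(
                        records, alpha=config.alpha
                    )
        for pop, per_contrast in config.atac_peaks.items():
            for contrast, path in per_contrast.items():
                aggregated = regulation.aggregate_promoter_accessibility(
                    tio.read_peak_results(path), genes,
                    promoter_window=config.promoter_window,
                )
                diff[("ATAC", pop, contrast)] = regulation.flag_significant(
                    aggregated, alpha=config.alpha
                )
        declass = classify_all(diff, config.populations)
        deda = regulation.intersect_de_da(
            declass[("RNA", "G3_treat")], declass[("ATAC", "G3_treat")],
            pop1=pop1, pop2=pop2,
        )

        # Table-1-style concordance summaries over DE/DA gene sets
        summary_rows = []
        lfc = {
            pop: pd.merge(
                diff[("RNA", pop, "G3_treat")][["gene_id", "lfc"]].rename(columns={"lfc": "rna_lfc"}),
                diff[("ATAC", pop, "G3_treat")][["gene_id", "lfc"]].rename(columns={"lfc": "atac_lfc"}),
                on="gene_id",
            )
            for pop in config.populations
        }
        for set_name, pop in (("shared", pop1), ("shared", pop2),
                              (f"unique_{pop1}", pop1), (f"unique_{pop2}", pop2)):
            gene_set = deda[set_name]
            sub = lfc[pop][lfc[pop]["gene_id"].isin(gene_set)]
            classes = regulation.concordance_classes(sub["rna_lfc"], sub["atac_lfc"])
            counts = {k: int((classes == k).sum())
                      for k in regulation.CONCORDANCE_CLASSES}
            if sum(counts.values()) == 0:
                continue
            summ = regulation.proportion_summary(counts)
            summ.insert(0, "population", pop)
            summ.insert(0, "gene_set", set_name)
            summary_rows.append(summ)
        concordance_summary = (
            pd.concat(summary_rows, ignore_index=True) if summary_rows
            else pd.DataFrame(columns=["gene_set", "population", "klass",
                                       "k", "n", "pct", "se_pct"])
        )

        stats_rows = []
        for pop in config.populations:
            cls = declass[("RNA", "G3_treat")].set_index("gene_id")["declass"]
            tbl = lfc[pop].assign(
                declass=lfc[pop]["gene_id"].map(cls).map(
                    lambda c, _p=pop: "shared" if c == "shared"
                    else ("unique" if c == f"unique_{_p}" else "not_deg")
                )
            )
            try:
                reg = regulation.lfc_interaction_regression(tbl)
                for term, (fval, dfree, p) in reg.f_stats.items():
                    stats_rows.append({
                        "metric": f"lfc_interaction_{term}", "population": pop,
                        "value": fval, "df": dfree, "p": p,
                    })
            except (ValueError, np.linalg.LinAlgError) as exc:
                logger.warning("interaction regression skipped for %s: %s", pop, exc)

    with _stage("association"):
        assoc_results = []
        for pop in config.populations:
            label_df = association.build_te_class_labels(links[pop], tes[pop], genes)
            gt = build_population_gene_table(diff, declass, pop)
            assoc_results.extend(
                association.run_te_association_suite(
                    gt, label_df, population=pop, alpha=config.alpha
                )
            )
        assoc_report = association.association_report(assoc_results)

    with _stage("transgen"):
        transgen_tables = {}
        for pop in config.populations:
            def sig_set(assay, contrast, _p=pop):
                d = diff[(assay, _p, contrast)]
                return set(d.loc[d["significant"], "gene_id"])

            g3 = sig_set("RNA", "G3_treat")
            drift = sig_set("RNA", "CtrlDrift")
            g6 = sig_set("RNA", "G6_ancestral")
            drift_lfcs = diff[("RNA", pop, "CtrlDrift")].set_index("gene_id")["lfc"]
            g6_filtered = transgen.exclude_control_drift(g6, drift, drift_lfcs)
            candidates, overlap_counts = transgen.tei_overlap(g3, g6_filtered)
            records = pd.merge(
                diff[("RNA", pop, "G3_treat")][["gene_id", "lfc"]].rename(columns={"lfc": "g3_lfc"}),
                diff[("RNA", pop, "G6_ancestral")][["gene_id", "lfc"]].rename(columns={"lfc": "g6_lfc"}),
                on="gene_id",
            )
            records["g3_sig"] = records["gene_id"].isin(g3)
            records["g6_sig"] = records["gene_id"].isin(g6)
            records["control_drift"] = records["gene_id"].isin(drift)
            records["tei_candidate"] = records["gene_id"].isin(candidates)
            flagged, pct = transgen.direction_consistency(records, candidates)
            stats_rows.append({"metric": "tei_candidates", "population": pop,
                               "value": len(candidates), "df": np.nan, "p": np.nan})
            stats_rows.append({"metric": "percent_direction_consistent",
                               "population": pop, "value": pct,
                               "df": np.nan, "p": np.nan})
            if len(candidates) >= 3:
                reg = transgen.crossgen_regression(records, candidates)
                fval, dfree, p = reg.f_stats["g3_lfc"]
                stats_rows.append({
                    "metric": "crossgen_slope", "population": pop,
                    "value": reg.coefficients["g3_lfc"], "df": dfree, "p": p,
                })
            else:
                logger.warning("crossgen regression skipped for %s: "
                               "fewer than 3 overlap genes", pop)
            out = records.merge(
                flagged[["gene_id", "direction_consistent"]], on="gene_id", how="left"
            )
            if config.descriptions is not None:
                kw = transgen.keyword_flag(
                    tio.read_descriptions(config.descriptions), config.keyword_groups
                )
                out = out.merge(kw, on="gene_id", how="left")
            transgen_tables[f"transgen_{pop}"] = out
            if config.gene_sets:
                curated = {name: tio.read_gene_set(p)
                           for name, p in config.gene_sets.items()}
                sub = out[out["gene_id"].isin(g6_filtered)]
                transgen_tables[f"genesets_{pop}"] = (
                    transgen.geneset_membership_report(sub, curated)
                )

    with _stage("report"):
        master = report.build_master_table(
            diff, declass, links, tes, config.populations
        )
        tables = {
            "master": master,
            "concordance_summary": concordance_summary,
            "association": assoc_report,
            "summary_stats": pd.DataFrame(
                stats_rows, columns=["metric", "population", "value", "df", "p"]
            ),
            **transgen_tables,
        }
        for assay_kind, contrast in (("Exp", "G3_treat"), ("Acc", "G3_treat"),
                                     ("Exp", "G6_ancestral")):
            for pop, other in ((pop1, pop2), (pop2, pop1)):
                name = f"candidates_{assay_kind.lower()}_{contrast}_{pop}"
                tables[name] = report.build_candidate_table(
                    master, tes[pop], links[pop], pop, other,
                    contrast=contrast, response_kind=assay_kind,
                )
        for assay in ("RNA", "ATAC"):
            for contrast in CONTRASTS:
                tables[f"declass_{assay.lower()}_{contrast}"] = declass[(assay, contrast)]
        for pop in config.populations:
            tables[f"consensus_tes_{pop}"] = tes[pop]
            tables[f"te_gene_links_{pop}"] = links[pop]
        deda_rows = [{"set": k, "n_genes": len(v),
                      "genes": ";".join(sorted(v))} for k, v in sorted(deda.items())]
        tables["deda_sets"] = pd.DataFrame(deda_rows, columns=["set", "n_genes", "genes"])
        manifest = report.write_reports(
            tables, config.out_dir, config=config, seed=config.seed
        )
    return manifest


def simulate_cohort(cfg: synthetic.SyntheticConfig, out_dir: str | Path) -> Path:
    """Generate a cohort, write every pipeline input file plus a run config.

    Returns the path of the written ``run_config.yaml``, ready for
    :func:`run_pipeline` via :func:`validate_config`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = synthetic.generate_truth(cfg)
    status, calls = synthetic.emit_caller_outputs(truth)
    diff = synthetic.emit_diff_tables(truth)

    tio.write_gene_annotation_gff3(truth.genes, out_dir / "genes.gff3")
    truth.to_json(out_dir / "truth.json")
    tio.write_table(synthetic.emit_descriptions(truth), out_dir / "descriptions.tsv")

    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 71]))
    sets_dir = out_dir / "gene_sets"
    sets_dir.mkdir(exist_ok=True)
    gene_ids = truth.genes["gene_id"].to_numpy()
    for name, size in (("trxg_like", 44), ("pcg_like", 19)):
        members = sorted(rng.choice(gene_ids, size=size, replace=False))
        (sets_dir / f"{name}.txt").write_text("\n".join(members) + "\n")

    raw = {
        "populations": list(cfg.populations),
        "genes": "genes.gff3",
        "descriptions": "descriptions.tsv",
        "gene_sets": {name: f"gene_sets/{name}.txt"
                      for name in ("trxg_like", "pcg_like")},
        "reference_status": {}, "nonref_calls": {},
        "diff_tables": {"RNA": {}, "ATAC": {}},
        "out_dir": "results",
        "seed": int(cfg.seed),
    }
    for pop in cfg.populations:
        fname = f"ref_status_{pop}.tsv"
        tio.write_table(status[pop], out_dir / fname)
        raw["reference_status"][pop] = fname
        raw["nonref_calls"][pop] = {}
        for caller, table in calls[pop].items():
            cname = f"calls_{pop}_{caller}.tsv"
            tio.write_table(table, out_dir / cname)
            raw["nonref_calls"][pop][caller] = cname
    for (assay, pop, contrast), table in diff.items():
        dname = f"diff_{assay.lower()}_{pop}_{contrast}.tsv"
        tio.write_table(table, out_dir / dname)
        raw["diff_tables"][assay].setdefault(pop, {})[contrast] = dname

    config_path = out_dir / "run_config.yaml"
    config_path.write_text(yaml.safe_dump(raw, sort_keys=True))
    return config_path
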