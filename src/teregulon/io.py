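"""Readers and writers for the pipeline's on-disk formats.

Internal coordinates are 0-based half-open (BED convention); GFF3 input is
converted on read, and the "insertion range" columns of report tables are
printed 1-based inclusive.  All tables are plain TSV.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

FLOAT_FORMAT = "%.6g"

REQUIRED_CALL_COLUMNS = ["chrom", "start", "end", "family", "sample_id", "caller"]
REQUIRED_STATUS_COLUMNS = ["te_id", "sample_id", "chrom", "start", "end", "family", "status"]


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Gene models from GFF3 (type=gene) or BED6.

    Returns gene_id, chrom, start, end, strand with 0-based half-open
    coordinates; gene ids must be unique.
    """
    path = Path(path)
    if path.suffix.lower() in (".bed", ".bed6"):
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "gene_id", "score", "strand"],
            dtype={"chrom": str},
        )
        genes = df[["gene_id", "chrom", "start", "end", "strand"]].copy()
    else:
        import gffutils

        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="error",
        )
        rows = []
        for feat in db.features_of_type("gene", order_by=("seqid", "start")):
            rows.append({
                "gene_id": feat.id, "chrom": feat.seqid,
                "start": feat.start - 1, "end": feat.end,
                "strand": feat.strand,
            })
        genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    if genes["gene_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate gene ids")
    if len(genes) and not (genes["start"] < genes["end"]).all():
        raise ValueError(f"{path}: gene with start >= end")
    return genes


def write_gene_annotation_gff3(genes: pd.DataFrame, path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for g in genes.itertuples():
        lines.append(
            f"{g.chrom}\tteregulon\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_nonref_calls(path: str | Path) -> pd.DataFrame:
    """BED3+ non-reference caller calls: chrom, start, end, family, sample, caller."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(REQUIRED_CALL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = df[df["end"] - df["start"] < 1]
    if len(bad):
        raise ValueError(f"{path}: line with non-positive interval at index {bad.index[0]}")
    return df


def read_reference_status(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(REQUIRED_STATUS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = ~df["status"].isin(["present", "polymorphic", "absent"])
    if bad.any():
        raise ValueError(f"{path}: invalid status value {df.loc[bad, 'status'].iloc[0]!r}")
    return df


def read_diff_table(path: str | Path) -> pd.DataFrame:
    """Differential-result TSV with header gene_id, lfc, p_adj."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "lfc", "p_adj"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate gene ids")
    return df


def read_descriptions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "description"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_gene_set(path: str | Path) -> list[str]:
    """Curated gene set: one gene id per line; the file stem names the set."""
    return [
        ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()
    ]


def read_peak_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"chrom", "start", "end", "lfc", "p_adj"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic TSV writer (fixed float formatting, no index)."""
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path: str | Path, entries: dict, config_digest: str,
                   seed: int | None) -> None:
    manifest = {
        "config_sha256": config_digest,
        "seed": seed,
        "files": entries,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
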