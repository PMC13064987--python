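"""Population-level consensus calling of transposable-element (TE) insertions.

Two kinds of insertion are handled:

* **Reference TEs** — insertions annotated in the reference assembly, genotyped
  per DNA sample by a reference-genotyping caller as ``present``,
  ``polymorphic`` or ``absent``.  A reference TE enters a population's
  consensus set only when every replicate sample supports it (present or
  polymorphic).

* **Non-reference TEs** — insertions absent from the reference assembly,
  detected independently by two insertion callers.  Within each caller,
  same-family calls within a merge distance are merged across samples; a
  consensus insertion requires the two callers' merged calls to intersect
  (same chromosome and family, gap at most the merge distance) with each
  caller supporting it in a minimum number of replicate samples.

All coordinates are 0-based half-open internally.  Table schemas:

``reference status`` — te_id, sample_id, chrom, start, end, family, status
``non-reference calls`` — caller, sample_id, chrom, start, end, family
``genes`` — gene_id, chrom, start, end, strand
``consensus`` — te_id, population, te_type, chrom, start, end, family,
    support (text, ``caller=count`` pairs joined by ``,``), off_annotation
``links`` — te_id, gene_id, relative_position, distance
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

REFERENCE = "reference"
NON_REFERENCE = "non_reference"

CONSENSUS_COLUMNS = [
    "te_id", "population", "te_type", "chrom", "start", "end",
    "family", "support", "off_annotation",
]
LINK_COLUMNS = ["te_id", "gene_id", "relative_position", "distance"]


def normalize_family(family: str) -> str:
    """Case-fold and strip a TE family label for comparison."""
    return str(family).strip().casefold()


def _format_support(counts: Mapping[str, int]) -> str:
    return ",".join(f"{c}={counts[c]}" for c in sorted(counts))


def parse_support(text: str) -> dict[str, int]:
    """Invert the ``caller=count`` serialization used in consensus tables."""
    if not text:
        return {}
    return {k: int(v) for k, v in (item.split("=") for item in text.split(","))}


def _validate_intervals(df: pd.DataFrame, what: str) -> None:
    bad = df[df["end"] - df["start"] < 1]
    if len(bad):
        raise ValueError(
            f"{what}: {len(bad)} interval(s) with non-positive length, "
            f"first at {bad.iloc[0]['chrom']}:{bad.iloc[0]['start']}-{bad.iloc[0]['end']}"
        )


def consolidate_reference_tes(
    status: pd.DataFrame,
    samples: Sequence[str],
    population: str = "pop",
    known_chroms: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Retain reference TEs genotyped present/polymorphic in *every* sample.

    ``status`` carries one row per (te_id, sample_id) with the annotation
    coordinates repeated on each row; a TE with a missing or conflicting
    status for any listed sample is excluded with a warning rather than an
    exception.
    """
    samples = list(samples)
    unknown = set(status["sample_id"]) - set(samples)
    if unknown:
        raise ValueError(f"status rows reference unknown samples: {sorted(unknown)}")
    _validate_intervals(status, "reference status")

    rows = []
    for te_id, grp in status.groupby("te_id", sort=True):
        per_sample = grp.drop_duplicates(["sample_id"]).set_index("sample_id")["status"]
        if len(grp) != len(per_sample):
            logger.warning("reference TE %s: duplicated (te_id, sample) rows; excluded", te_id)
            continue
        missing = [s for s in samples if s not in per_sample.index]
        if missing:
            logger.warning("reference TE %s: no status for sample(s) %s; excluded", te_id, missing)
            continue
        if not per_sample.loc[samples].isin(["present", "polymorphic"]).all():
            continue
        first = grp.iloc[0]
        rows.append({
            "te_id": te_id,
            "population": population,
            "te_type": REFERENCE,
            "chrom": first["chrom"],
            "start": int(first["start"]),
            "end": int(first["end"]),
            "family": str(first["family"]).strip(),
            "support": _format_support({"reference": len(samples)}),
            "off_annotation": (
                known_chroms is not None and first["chrom"] not in set(known_chroms)
            ),
        })
    return pd.DataFrame(rows, columns=CONSENSUS_COLUMNS)


def _merge_caller_calls(calls: pd.DataFrame, merge_distance: int) -> pd.DataFrame:
    """Merge one caller's per-sample calls within ``merge_distance``.

    Same (chrom, family) calls whose intervals overlap or lie within the
    merge distance collapse to their union interval; supporting samples are
    pooled.  Single-linkage over position order, which is exhaustive because
    merging only ever extends the right edge.
    """
    out = []
    key = calls.assign(_fam=calls["family"].map(normalize_family))
    for (chrom, fam), grp in key.groupby(["chrom", "_fam"], sort=True):
        grp = grp.sort_values(["start", "end"], kind="mergesort")
        cur_start = cur_end = None
        cur_samples: set = set()
        cur_family = None
        for row in grp.itertuples():
            if cur_start is None or row.start - cur_end > merge_distance:
                if cur_start is not None:
                    out.append((chrom, cur_start, cur_end, cur_family, frozenset(cur_samples)))
                cur_start, cur_end = row.start, row.end
                cur_samples = {row.sample_id}
                cur_family = str(row.family).strip()
            else:
                cur_end = max(cur_end, row.end)
                cur_samples.add(row.sample_id)
        if cur_start is not None:
            out.append((chrom, cur_start, cur_end, cur_family, frozenset(cur_samples)))
    return pd.DataFrame(out, columns=["chrom", "start", "end", "family", "samples"])


def consolidate_nonreference_tes(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    merge_distance: int = 25,
    min_samples: int = 2,
    n_samples: int = 3,
    population: str = "pop",
    known_chroms: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Intersect two callers' merged insertion calls into a consensus set.

    A consensus insertion is emitted where a merged call from caller A lies
    within ``merge_distance`` of a same-family merged call from caller B and
    each caller saw it in at least ``min_samples`` of ``n_samples`` replicate
    samples.  The emitted interval is the union of the paired merged
    intervals; overlapping consensus intervals of one family are re-merged so
    the final set is exhaustive.
    """
    for df, name in ((calls_a, "caller A"), (calls_b, "caller B")):
        _validate_intervals(df, name)
    callers = []
    for df in (calls_a, calls_b):
        named = df["caller"].unique()
        if len(named) != 1:
            raise ValueError("each input table must come from exactly one caller")
        callers.append(str(named[0]))
    if callers[0] == callers[1]:
        raise ValueError("the two call tables must come from distinct callers")

    merged_a = _merge_caller_calls(calls_a, merge_distance)
    merged_b = _merge_caller_calls(calls_b, merge_distance)

    # index caller B merged calls for proximity lookup
    trees: dict[tuple, IntervalTree] = {}
    for idx, row in merged_b.iterrows():
        k = (row["chrom"], normalize_family(row["family"]))
        # expand by distance+1: half-open tree overlap is strict, gap == distance must hit
        trees.setdefault(k, IntervalTree())[row["start"] - merge_distance - 1:row["end"] + merge_distance + 1] = idx

    pairs = []
    for row in merged_a.itertuples():
        tree = trees.get((row.chrom, normalize_family(row.family)))
        if tree is None:
            continue
        if len(row.samples) < min_samples:
            continue
        for hit in tree[row.start:row.end]:
            b = merged_b.loc[hit.data]
            if len(b["samples"]) < min_samples:
                continue
            pairs.append((
                row.chrom,
                min(row.start, b["start"]),
                max(row.end, b["end"]),
                row.family,
                row.samples,
                b["samples"],
            ))
    pair_df = pd.DataFrame(
        pairs, columns=["chrom", "start", "end", "family", "samples_a", "samples_b"]
    )

    # exhaustive final merge of qualifying consensus intervals
    rows = []
    if len(pair_df):
        pair_df = pair_df.assign(_fam=pair_df["family"].map(normalize_family))
        for (chrom, fam), grp in pair_df.groupby(["chrom", "_fam"], sort=True):
            grp = grp.sort_values(["start", "end"], kind="mergesort")
            cur = None
            for r in grp.itertuples():
                if cur is None or r.start - cur[1] > merge_distance:
                    if cur is not None:
                        rows.append(cur)
                    cur = [r.start, r.end, r.family, set(r.samples_a), set(r.samples_b), chrom]
                else:
                    cur[1] = max(cur[1], r.end)
                    cur[3] |= set(r.samples_a)
                    cur[4] |= set(r.samples_b)
            if cur is not None:
                rows.append(cur)

    known = set(known_chroms) if known_chroms is not None else None
    out = []
    for i, (start, end, family, sa, sb, chrom) in enumerate(
        sorted(rows, key=lambda r: (r[5], r[0], r[1], r[2]))
    ):
        off = known is not None and chrom not in known
        if off:
            logger.warning("consensus TE on chromosome %s absent from annotation", chrom)
        out.append({
            "te_id": f"{population}_nr_{i:05d}",
            "population": population,
            "te_type": NON_REFERENCE,
            "chrom": chrom,
            "start": int(start),
            "end": int(end),
            "family": str(family).strip(),
            "support": _format_support({callers[0]: len(sa), callers[1]: len(sb)}),
            "off_annotation": off,
        })
    return pd.DataFrame(out, columns=CONSENSUS_COLUMNS)


def _relative_position(
    te_start: int, te_end: int, g_start: int, g_end: int, strand: str
) -> tuple[str, int]:
    """Strand-aware placement of a TE interval relative to one gene."""
    overlaps = te_start < g_end and te_end > g_start
    if overlaps:
        inside = te_start >= g_start and te_end <= g_end
        crosses_left = te_start < g_start
        crosses_right = te_end > g_end
        if inside or (crosses_left and crosses_right):
            return "genic", 0
        # exactly one boundary crossed
        five_prime_left = strand != "-"
        if crosses_left:
            return ("us_ovlp" if five_prime_left else "ds_ovlp"), 0
        return ("ds_ovlp" if five_prime_left else "us_ovlp"), 0
    if te_end <= g_start:  # TE on the left
        gap = g_start - te_end
        side_is_five_prime = strand != "-"
    else:
        gap = te_start - g_end
        side_is_five_prime = strand == "-"
    return ("upstream" if side_is_five_prime else "downstream"), int(gap)


def annotate_te_gene_links(
    tes: pd.DataFrame, genes: pd.DataFrame, window: int = 1000
) -> pd.DataFrame:
    """Link each consensus TE to every gene within ``window`` bp.

    Overlap counts as distance 0.  A TE contained in (or spanning) a gene is
    ``genic``; one crossing a single gene boundary is ``us_ovlp``/``ds_ovlp``
    by the strand-aware 5'/3' side; otherwise ``upstream``/``downstream``
    with the gap as distance.  Windowing, not nearest-gene assignment: a TE
    may link several genes and vice versa.
    """
    if len(tes) == 0 or len(genes) == 0:
        return pd.DataFrame(columns=LINK_COLUMNS)
    trees: dict[str, IntervalTree] = {}
    for idx, g in genes.iterrows():
        trees.setdefault(g["chrom"], IntervalTree())[
            g["start"] - window - 1:g["end"] + window + 1
        ] = idx
    links = []
    for te in tes.itertuples():
        tree = trees.get(te.chrom)
        if tree is None:
            continue
        for hit in sorted(tree[te.start:te.end], key=lambda h: h.data):
            g = genes.loc[hit.data]
            pos, dist = _relative_position(
                te.start, te.end, int(g["start"]), int(g["end"]), str(g["strand"])
            )
            if dist <= window:
                links.append({
                    "te_id": te.te_id,
                    "gene_id": g["gene_id"],
                    "relative_position": pos,
                    "distance": dist,
                })
    return pd.DataFrame(links, columns=LINK_COLUMNS)


def label_population_unique(
    tes_pop1: pd.DataFrame, tes_pop2: pd.DataFrame, match_distance: int = 25
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mark insertions with no same-family counterpart in the other population.

    An insertion is ``population_unique`` when no insertion of the same
    family in the other population's consensus set lies within
    ``match_distance`` bp on the same chromosome; the match is symmetric.
    """
    def build(tes: pd.DataFrame) -> dict[tuple, IntervalTree]:
        trees: dict[tuple, IntervalTree] = {}
        for row in tes.itertuples():
            k = (row.chrom, normalize_family(row.family))
            trees.setdefault(k, IntervalTree())[
                row.start - match_distance - 1:row.end + match_distance + 1
            ] = True
        return trees

    def flag(tes: pd.DataFrame, other: dict[tuple, IntervalTree]) -> pd.DataFrame:
        unique = []
        for row in tes.itertuples():
            tree = other.get((row.chrom, normalize_family(row.family)))
            unique.append(tree is None or not tree.overlaps(row.start, row.end))
        out = tes.copy()
        out["population_unique"] = unique
        return out

    return flag(tes_pop1, build(tes_pop2)), flag(tes_pop2, build(tes_pop1))
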