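import numpy as np
import pandas as pd
import pytest

from teregulon import pipeline, regulation, synthetic


@pytest.fixture(scope="session")
def easy_truth():
    """High-signal cohort used by several recovery tests."""
    return synthetic.generate_truth(synthetic.easy_config(seed=11))


@pytest.fixture(scope="session")
def easy_diff(easy_truth):
    return {
        k: regulation.flag_significant(v)
        for k, v in synthetic.emit_diff_tables(easy_truth).items()
    }


@pytest.fixture(scope="session")
def easy_declass(easy_diff, easy_truth):
    return pipeline.classify_all(easy_diff, easy_truth.config.populations)


@pytest.fixture()
def genes_df():
    """A handful of stranded genes on one chromosome."""
    return pd.DataFrame({
        "gene_id": ["gA", "gB", "gC"],
        "chrom": ["chr1", "chr1", "chr2"],
        "start": [10_000, 30_000, 5_000],
        "end": [12_000, 33_000, 8_000],
        "strand": ["+", "-", "+"],
    })


def make_calls(caller, rows):
    """rows: (sample_id, chrom, start, end, family)"""
    return pd.DataFrame(
        [
            {"caller": caller, "sample_id": s, "population": "pop",
             "chrom": c, "start": a, "end": b, "family": f}
            for s, c, a, b, f in rows
        ]
    )


def truth_class_series(truth):
    """Expected cross-population DE class per gene from a truth manifest."""
    tr = truth.gene_truth
    pop1, pop2 = truth.config.populations
    return pd.Series(
        np.select(
            [tr["class_pop1"] == "shared",
             tr["class_pop1"] == "unique",
             tr["class_pop2"] == "unique"],
            ["shared", f"unique_{pop1}", f"unique_{pop2}"],
            default="not_sig",
        ),
        index=pd.Index(tr["gene_id"], name="gene_id"),
    )
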