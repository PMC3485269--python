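import numpy as np
import pandas as pd
import pytest

from srnaherit import clustering, simulate


@pytest.fixture(scope="session")
def worked_example():
    return simulate.worked_example()


@pytest.fixture(scope="session")
def worked_pipeline(worked_example):
    """Worked example taken through clustering and quantification."""
    exp = worked_example
    reads = exp.reads[~exp.reads["seq_id"].isin(exp.blocklist)]
    clusters = clustering.build_clusters(reads)
    averaged, filtered = clustering.quantify(clusters, reads, exp.design)
    return {
        "exp": exp,
        "reads": reads,
        "clusters": clusters,
        "averaged": averaged,
        "filtered": filtered,
    }


def make_reads(rows, library_id="lib1"):
    """Small helper to build a read table from (seq_id, chrom, start, length,
    strand, abundance, n_loci) tuples."""
    df = pd.DataFrame(
        rows, columns=["seq_id", "chrom", "start", "length", "strand", "abundance", "n_loci"]
    )
    df["end"] = df["start"] + df["length"]
    df["library_id"] = library_id
    return df[
        ["seq_id", "chrom", "start", "end", "strand", "length", "abundance", "n_loci", "library_id"]
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(42)
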