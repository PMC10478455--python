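import numpy as np
import pandas as pd
import pytest

from snowassembly.community_data import CommunityMatrix


@pytest.fixture
def small_counts() -> CommunityMatrix:
    """Five taxa x four samples, hand-picked to exercise the filter rules."""
    df = pd.DataFrame(
        {
            "s1": [5, 1, 5, 1, 3],
            "s2": [3, 0, 0, 1, 2],
            "s3": [2, 0, 0, 0, 4],
            "s4": [0, 0, 0, 0, 1],
        },
        index=["taxA", "taxB", "taxC", "taxD", "taxE"],
    )
    return CommunityMatrix(df)


@pytest.fixture
def three_tip_newick(tmp_path):
    p = tmp_path / "tree.nwk"
    p.write_text("((A:0.1,B:0.1):0.2,C:0.3);\n")
    return p


def write_counts_tsv(tmp_path, df, name="counts.tsv"):
    p = tmp_path / name
    out = df.copy()
    out.index.name = "taxon_id"
    out.to_csv(p, sep="\t")
    return p


@pytest.fixture
def rng():
    return np.random.default_rng(20230905)
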