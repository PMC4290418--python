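from __future__ import annotations

import pytest

from adepd.risk import builtin_transform
from adepd.simulate import worked_fixture


@pytest.fixture(scope="session")
def iucn50():
    return builtin_transform("IUCN50")


@pytest.fixture()
def fixture_bundle():
    """(treeset, statuses, cohort, expected) of the hand-verified 6-tip study."""
    return worked_fixture()


@pytest.fixture()
def fixture_files(tmp_path, fixture_bundle):
    """The worked fixture written out as the CLI's on-disk input formats."""
    import pandas as pd

    from adepd.tree import write_newick

    ts, statuses, cohort, expected = fixture_bundle
    trees = tmp_path / "trees.nwk"
    write_newick(ts, trees)
    stat = tmp_path / "statuses.csv"
    pd.DataFrame(
        {"species": list(statuses), "iucn_category": list(statuses.values())}
    ).to_csv(stat, index=False)
    coh = tmp_path / "cohort.csv"
    cohort.to_csv(coh)
    return {"trees": trees, "statuses": stat, "cohort": coh, "expected": expected,
            "tmp_path": tmp_path}
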