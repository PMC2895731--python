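from pathlib import Path

import pytest

from anatfunc.fixtures import make_worked_example_fixture

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def worked_triple():
    return make_worked_example_fixture()


@pytest.fixture(scope="session")
def plural_pairs():
    pairs = []
    for line in (DATA_DIR / "plural_pairs.tsv").read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        plural, singular = line.split("\t")
        pairs.append((plural, singular))
    assert len(pairs) >= 200
    return pairs
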