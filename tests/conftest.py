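import numpy as np
import pytest

from hlabayes.alphabet import encode
from hlabayes.model import FreqPrior, Hyperparams, ReferencePanel
from hlabayes.scoring import PlacedRead
from hlabayes.simulate import SimConfig, generate_mock_db


def make_placed(read_id: str, cols, chars: str, quals=None) -> PlacedRead:
    cols = np.asarray(cols, dtype=np.int64)
    if quals is None:
        quals = [30] * len(chars)
    return PlacedRead(read_id, cols, encode(chars), np.asarray(quals, dtype=np.int16))


def make_panel(gene: str, alleles: dict[str, str], imputed: dict[str, list[int]] | None = None) -> ReferencePanel:
    names = sorted(alleles)
    ref = np.stack([encode(alleles[n]) for n in names])
    mask = np.zeros_like(ref, dtype=bool)
    if imputed:
        for n, cols in imputed.items():
            mask[names.index(n), cols] = True
    return ReferencePanel(gene, names, ref, mask)


@pytest.fixture
def hp() -> Hyperparams:
    return Hyperparams()

@pytest.fixture
def fp() -> FreqPrior:
    return FreqPrior()


@pytest.fixture(scope="session")
def small_db():
    """8-allele mock bundle with a 5%-diverged homolog gene (session cache)."""
    return generate_mock_db(SimConfig(seed=11, n_alleles=8))


@pytest.fixture(scope="session")
def medium_db():
    """20-allele mock bundle used by recovery tests (session cache)."""
    return generate_mock_db(SimConfig(seed=5, n_alleles=20))


@pytest.fixture
def tiny_panel() -> ReferencePanel:
    """Three 4-column alleles of one gene, one with an imputed column."""
    return make_panel(
        "A",
        {"A*01:01": "ACGT", "A*02:01": "ACTT", "A*03:01": "GCGT"},
        imputed={"A*03:01": [0]},
    )
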