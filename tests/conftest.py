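import numpy as np
import pandas as pd
import pytest

from popconserve import GenotypeMatrix


def make_gm(dosage, chroms=None, positions=None, sexes=None, ids=None,
            ref="A", alt="G"):
    """Build a GenotypeMatrix from a dosage array with minimal metadata."""
    dosage = np.asarray(dosage, dtype=np.int8)
    ns, nv = dosage.shape
    if chroms is None:
        chroms = ["1"] * nv
    if positions is None:
        positions = []
        counters = {}
        for c in chroms:
            counters[c] = counters.get(c, 0) + 100
            positions.append(counters[c])
    if ids is None:
        ids = [f"S{i + 1}" for i in range(ns)]
    if sexes is None:
        sexes = ["unknown"] * ns
    samples = pd.DataFrame({"id": ids, "sex": sexes}, dtype=object)
    variants = pd.DataFrame(
        {
            "chrom": [str(c) for c in chroms],
            "pos": positions,
            "id": [f"snp{j}" for j in range(nv)],
            "ref": [ref] * nv,
            "alt": [alt] * nv,
        }
    )
    return GenotypeMatrix(samples, variants, dosage)


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)


@pytest.fixture
def tiny_gm():
    """3 samples x 4 variants, one missing call, one X-linked variant."""
    return make_gm(
        [[0, 1, 2, -1], [1, 1, 0, 2], [2, 0, 1, 1]],
        chroms=["1", "1", "2", "X"],
        positions=[100, 200, 100, 500],
        sexes=["male", "female", "female"],
    )
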