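import numpy as np
import pytest

from abkfs.data_model import SampleMeta
from abkfs.discretise import DiscretisedMatrix
from abkfs.synthetic import GeneratorConfig, generate


@pytest.fixture
def worked_instance():
    """The 4-sample / 3-feature instance with alpha*=2, beta*=2, min k=2.

    Rows are features, columns samples s1..s4 with classes (0,0,1,1):
    s1:(0,0,1) s2:(0,1,1) s3:(1,1,0) s4:(1,0,0).
    """
    codes = np.array(
        [
            [0, 0, 1, 1],  # f1
            [0, 1, 1, 0],  # f2
            [1, 1, 0, 0],  # f3
        ]
    )
    meta = [
        SampleMeta("s1", "A", 0),
        SampleMeta("s2", "A", 0),
        SampleMeta("s3", "A", 1),
        SampleMeta("s4", "A", 1),
    ]
    dm = DiscretisedMatrix(
        codes=codes,
        feature_ids=["f1", "f2", "f3"],
        sample_ids=[s.sample_id for s in meta],
        cuts={},
    )
    return dm, meta


@pytest.fixture
def worked_instance_two_colours(worked_instance):
    """The same instance with a second colour: s5:(1,0,0) class 0, s6:(1,0,1) class 1.

    The pair (s5, s6) differs on f3 only, so alpha* drops to 1.
    """
    dm, meta = worked_instance
    codes = np.column_stack([dm.codes, [1, 0, 0], [1, 0, 1]])
    meta = meta + [SampleMeta("s5", "B", 0), SampleMeta("s6", "B", 1)]
    dm2 = DiscretisedMatrix(
        codes=codes,
        feature_ids=dm.feature_ids,
        sample_ids=[s.sample_id for s in meta],
        cuts={},
    )
    return dm2, meta


def random_instance(rng, n_features=None, n_samples=None, n_regions=1,
                    n_bins=2, with_individuals=False):
    """A random discretised instance guaranteed to have an inter-class pair
    in every region (both classes present per region)."""
    n = n_features if n_features is not None else int(rng.integers(3, 13))
    m = n_samples if n_samples is not None else int(rng.integers(4, 11))
    m = max(m, 2 * n_regions)
    codes = rng.integers(0, n_bins, size=(n, m)).astype(np.int16)
    regions = [f"R{i % n_regions}" for i in range(m)]
    klass = np.zeros(m, dtype=int)
    # force both classes in every region, randomise the rest
    for r in range(n_regions):
        idx = [i for i in range(m) if i % n_regions == r]
        klass[idx[0]] = 0
        klass[idx[1]] = 1
        for i in idx[2:]:
            klass[i] = int(rng.integers(0, 2))
    meta = []
    for i in range(m):
        indiv = f"ind{i}" if with_individuals else None
        meta.append(SampleMeta(f"s{i}", regions[i], int(klass[i]), indiv))
    dm = DiscretisedMatrix(
        codes=codes,
        feature_ids=[f"f{j}" for j in range(n)],
        sample_ids=[s.sample_id for s in meta],
        cuts={},
    )
    return dm, meta


@pytest.fixture(scope="session")
def planted_dataset():
    """One draw of the reference 5-region synthetic study (seed 0)."""
    return generate(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def small_planted_dataset():
    """A faster 2-region study with strongly planted shared features."""
    cfg = GeneratorConfig(
        n_features=60,
        n_shared_de=8,
        n_specific_de=3,
        regions={"R1": (8, 8), "R2": (8, 8)},
        effect_size=4.0,
        seed=11,
    )
    return generate(cfg)
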