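import numpy as np
import pytest

from mrsense import SummaryDataset, VariantAssociation


def build_dataset(bx, by, sx=None, sy=None, ids=None, covariates=None,
                  oriented=True, **meta):
    """Construct a SummaryDataset from plain sequences.

    Defaults: unit outcome SEs and small exposure SEs, so ratio estimates
    and weights can be read off directly from (bx, by, sy).
    """
    bx = list(map(float, bx))
    by = list(map(float, by))
    sx = [0.01] * len(bx) if sx is None else list(map(float, sx))
    sy = [1.0] * len(bx) if sy is None else list(map(float, sy))
    ids = ids or [f"rs{i + 1}" for i in range(len(bx))]
    variants = tuple(
        VariantAssociation(
            variant_id=ids[i], beta_exposure=bx[i], se_exposure=sx[i],
            beta_outcome=by[i], se_outcome=sy[i],
            covariate_betas=tuple(covariates[i]) if covariates is not None else None,
        )
        for i in range(len(bx))
    )
    return SummaryDataset(variants=variants, oriented=oriented, **meta)


def random_dataset(rng, j=10, theta=0.3, heterogeneity=0.0):
    """Random oriented dataset: exposure associations U(0.1, 0.5), outcome
    associations theta * bx plus noise, varied outcome SEs."""
    bx = rng.uniform(0.1, 0.5, size=j)
    sy = rng.uniform(0.02, 0.2, size=j)
    by = theta * bx + rng.normal(0.0, sy) + rng.normal(0.0, heterogeneity, size=j)
    return build_dataset(bx, by, sx=rng.uniform(0.005, 0.02, size=j), sy=sy)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_variant():
    # ratio estimates (1, 2) with unit SEs
    return build_dataset(bx=[1, 1], by=[1, 2], sy=[1, 1])


@pytest.fixture
def homogeneous():
    # every variant's ratio estimate is exactly 0.5
    bx = [0.1, 0.2, 0.3, 0.4]
    return build_dataset(bx=bx, by=[0.5 * b for b in bx], sy=[0.05] * 4)
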