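import numpy as np
import pandas as pd
import pytest

from scnkit import CohortSpec, RegionAtlas, ThicknessDataset, generate_cohort


@pytest.fixture(scope="session")
def atlas20() -> RegionAtlas:
    ids = tuple(f"synth_region_{i:03d}" for i in range(20))
    hemis = tuple("left" if i % 2 == 0 else "right" for i in range(20))
    return RegionAtlas(ids, hemis)


@pytest.fixture(scope="session")
def small_cohort() -> ThicknessDataset:
    """20 regions, 4 modules, clear group difference; fast fixture."""
    return generate_cohort(
        CohortSpec(
            n_patients=20, n_controls=22, n_regions=20, n_modules=4,
            loading_patient=0.4, loading_control=0.8, seed=11,
        )
    )


@pytest.fixture(scope="session")
def default_cohort() -> ThicknessDataset:
    """Full-size default cohort (56 + 59 subjects, 148 regions)."""
    return generate_cohort(CohortSpec(seed=7))


def random_graph(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    """Symmetric boolean adjacency, no self-loops."""
    upper = np.triu(rng.random((n, n)) < p, k=1)
    return upper | upper.T


def make_dataset(
    thickness: np.ndarray,
    atlas: RegionAtlas,
    group: list[str],
    rng: np.random.Generator,
    covariates: pd.DataFrame | None = None,
) -> ThicknessDataset:
    """Wrap a raw thickness matrix into a validated dataset."""
    n = thickness.shape[0]
    idx = pd.Index([f"s{i:03d}" for i in range(n)], name="subject_id")
    if covariates is None:
        covariates = pd.DataFrame(
            {
                "age": rng.uniform(45, 70, n),
                "sex": rng.integers(0, 2, n),
                "tiv": rng.normal(1.45e6, 1.3e5, n),
            },
            index=idx,
        )
    else:
        covariates = covariates.set_axis(idx)
    thick = pd.DataFrame(thickness, index=idx, columns=list(atlas.region_id))
    return ThicknessDataset(thick, covariates, pd.Series(group, index=idx), atlas)
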