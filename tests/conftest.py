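import numpy as np
import pytest

from bearvoc.datatypes import (
    BodySite,
    CompoundID,
    Dataset,
    PeakTable,
    SampleMetadata,
    Sex,
    Stage,
)
from bearvoc.synthetic import SimulationConfig, simulate_dataset


def make_table(values, stage=Stage.RAW, sample_ids=None, labels=None) -> PeakTable:
    """Small peak table from a nested list (compounds x samples)."""
    values = np.asarray(values, dtype=float)
    n_c, n_s = values.shape
    labels = labels or [f"{50 + i}.0@{i + 1}.50" for i in range(n_c)]
    sample_ids = sample_ids or [f"s{j + 1}" for j in range(n_s)]
    return PeakTable([CompoundID(lab) for lab in labels], sample_ids, values,
                     Stage(stage))


def make_metadata(n, sexes=None, ages=None, sites=None, individuals=None,
                  replicates=None) -> list[SampleMetadata]:
    """Quick metadata for n samples s1..sn with overridable columns."""
    sexes = sexes or ["F"] * n
    ages = ages or [4] * n
    sites = sites or [list(BodySite)[i % 4].value for i in range(n)]
    individuals = individuals or [f"ind{i + 1}" for i in range(n)]
    replicates = replicates or [1] * n
    return [
        SampleMetadata(
            sample_id=f"s{i + 1}",
            individual_id=individuals[i],
            sex=Sex(sexes[i]),
            age_years=ages[i],
            body_site=BodySite(sites[i]),
            replicate=replicates[i],
        )
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def study_dataset() -> Dataset:
    """Default 12-bear design minus the failed pede sample (77 samples)."""
    dataset, _ = simulate_dataset(SimulationConfig(seed=1))
    return dataset.drop_samples(["Y862_pedes_2"], "failed file conversion")


@pytest.fixture(scope="session")
def study_dataset_full() -> Dataset:
    """Default 12-bear design with all 78 samples."""
    dataset, _ = simulate_dataset(SimulationConfig(seed=1))
    return dataset
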