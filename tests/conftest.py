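import numpy as np
import pandas as pd
import pytest

from rrfi.model import build_design_system, model_from_code
from rrfi.pedigree import validate_and_sort_pedigree
from rrfi.synth import FixtureConfig, generate_weekly_dataset


def random_pedigree(n_founders, n_offspring, seed):
    """Random multi-generation pedigree (with some inbreeding) for property
    tests; returns the sorted PedigreeTable."""
    rng = np.random.default_rng(seed)
    rows = [(i + 1, 0, 0) for i in range(n_founders)]
    ids = list(range(1, n_founders + 1))
    for j in range(n_offspring):
        s, d = rng.choice(ids, size=2, replace=False)
        rows.append((n_founders + j + 1, int(s), int(d)))
        ids.append(n_founders + j + 1)
    return validate_and_sort_pedigree(rows)


@pytest.fixture(scope="session")
def weekly_ds():
    """Small synthetic weekly dataset (2 batches x 80 animals) with truth."""
    return generate_weekly_dataset(
        FixtureConfig(n_batches=2, animals_per_batch=80, seed=42)
    )


@pytest.fixture(scope="session")
def design8(weekly_ds):
    return build_design_system(
        weekly_ds.records, weekly_ds.pedigree, model_from_code(8)
    )


@pytest.fixture(scope="session")
def design1(weekly_ds):
    return build_design_system(
        weekly_ds.records, weekly_ds.pedigree, model_from_code(1)
    )


def unrelated_records(n_animals, n_rec, mu, var_a, var_e, seed,
                      var_p=0.0, pen_groups=1):
    """Records for unrelated animals under an intercept-only model; returns
    (records frame, pedigree, true animal effects)."""
    rng = np.random.default_rng(seed)
    ped = validate_and_sort_pedigree([(i + 1, 0, 0) for i in range(n_animals)])
    a = rng.normal(0, np.sqrt(var_a), n_animals)
    p = rng.normal(0, np.sqrt(var_p), n_animals) if var_p > 0 else np.zeros(n_animals)
    rows = []
    for i in range(n_animals):
        for _ in range(n_rec):
            rows.append({
                "animal_id": i + 1, "batch": 0, "week": 0,
                "pen": i % pen_groups,
                "fi": mu + a[i] + p[i] + rng.normal(0, np.sqrt(var_e)),
                "mw": 0.0, "wg": 0.0, "fg": 0.0,
            })
    return pd.DataFrame(rows), ped, a
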