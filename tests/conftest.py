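import itertools

import numpy as np
import pandas as pd
import pytest

from annak.dissim import DissimMatrix
from annak.dyads import build_dyad_table


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_dissim_from_values(values, ids, name="idx"):
    """Square matrix from condensed upper-triangle values (test helper)."""
    n = len(ids)
    d = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    d[iu] = values
    return DissimMatrix(name, ids, d + d.T - np.diag(np.diag(d)))


def make_subject_table(traits, ids=None, **covariates):
    ids = ids or [f"S{k:03d}" for k in range(1, len(traits) + 1)]
    df = pd.DataFrame({"pt": traits}, index=ids)
    for name, vals in covariates.items():
        df[name] = vals
    return df


def make_member_effect_table(n_subjects, rng, *, member_sd=1.0, noise_sd=1.0,
                             group_shift=0.0, dv_name="dv"):
    """Dyad table whose dv is additive member effects + dyad noise, with an
    optional HH-vs-LL mean shift. Used as a controlled model-fitting input."""
    ids = [f"S{k:03d}" for k in range(1, n_subjects + 1)]
    traits = rng.integers(10, 29, size=n_subjects)
    effects = rng.normal(0.0, member_sd, size=n_subjects)
    subjects = make_subject_table(traits, ids)
    values = []
    med = np.median(traits)
    hi = traits > med
    for i, j in itertools.combinations(range(n_subjects), 2):
        shift = group_shift * (int(hi[i]) + int(hi[j])) / 2.0
        values.append(effects[i] + effects[j] + shift + rng.normal(0.0, noise_sd))
    dm = make_dissim_from_values(np.abs(values) + 1e-9, ids, dv_name)
    table = build_dyad_table(subjects, "pt", {dv_name: dm})
    # overwrite with signed values (dissim matrices are non-negative, but the
    # models accept any real-valued dv column)
    table.data[dv_name] = values
    return table
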