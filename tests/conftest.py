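import numpy as np
import pandas as pd
import pytest

from germscreen.core_io import MetabolomeMatrix
from germscreen.synthetic import SyntheticConfig, generate


def build_matrix(
    values,
    varieties=("fast", "slow"),
    timepoints=(0, 3, 6, 9, 12, 24, 36, 48),
    n_replicates=3,
    met_ids=None,
    classes=None,
    names=None,
):
    """Assemble a MetabolomeMatrix from an (n_samples × n_metabolites) array.

    Samples are ordered variety-major, then time point, then replicate —
    the same order the synthetic generator uses.
    """
    values = np.asarray(values, dtype=float)
    rows = []
    for v in varieties:
        for t in timepoints:
            for r in range(1, n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{v}-{t}h-{r}",
                        "variety": v,
                        "timepoint_hai": int(t),
                        "replicate": r,
                    }
                )
    samples = pd.DataFrame(rows).set_index("sample_id")
    assert len(samples) == values.shape[0]
    n_met = values.shape[1]
    if met_ids is None:
        met_ids = [f"met{i:04d}" for i in range(n_met)]
    metabolites = pd.DataFrame(
        {
            "name": names if names is not None else met_ids,
            "compound_class": classes if classes is not None else "others",
            "module_tag": "none",
        },
        index=pd.Index(met_ids, name="metabolite_id"),
    )
    vals = pd.DataFrame(values, index=samples.index, columns=metabolites.index)
    return MetabolomeMatrix(samples=samples, metabolites=metabolites, values=vals)


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset shared by read-only tests."""
    return generate(SyntheticConfig(rng_seed=1))


@pytest.fixture(scope="session")
def noiseless_dataset():
    return generate(SyntheticConfig(rng_seed=2, noise_cv=0.0))
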