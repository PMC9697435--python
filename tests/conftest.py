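import numpy as np
import pandas as pd
import pytest

from onset_omics.io import OmicsMatrix, SampleSheet
from onset_omics.simulate import SimulationConfig


def make_sheet(n_eocrc=3, n_locrc=3, drop=()):
    """Paired sample sheet with n persons per onset group."""
    rows = []
    for group, prefix, n in (("EOCRC", "E", n_eocrc), ("LOCRC", "L", n_locrc)):
        for i in range(n):
            pid = f"{prefix}{i + 1:03d}"
            for tissue, tag in (("tumor", "T"), ("normal", "N")):
                sid = f"{pid}-{tag}"
                if sid in drop:
                    continue
                rows.append({"sample_id": sid, "person_id": pid,
                             "tissue": tissue, "onset_group": group})
    return SampleSheet(pd.DataFrame(rows))


def noise_free_matrix(sheet, effects_eocrc, effects_locrc, mu=8.0,
                      person_offsets=None):
    """Deterministic expression matrix: mu + person offset + tissue effect.

    ``effects_*`` map feature_id -> tumor-minus-normal effect applied to the
    named onset group.
    """
    features = list(effects_eocrc)
    values = {}
    for _, row in sheet.data.iterrows():
        offset = (person_offsets or {}).get(row["person_id"], 0.0)
        col = []
        for f in features:
            eff = (effects_locrc if row["onset_group"] == "LOCRC"
                   else effects_eocrc)[f]
            col.append(mu + offset + (eff if row["tissue"] == "tumor" else 0.0))
        values[row["sample_id"]] = col
    return OmicsMatrix(pd.DataFrame(values, index=features), "expression_log2")


@pytest.fixture
def sheet6():
    return make_sheet(3, 3)


@pytest.fixture
def small_config():
    return SimulationConfig(
        n_persons_per_group={"EOCRC": 12, "LOCRC": 15},
        n_features=80,
        n_gene_sets=2,
        set_size=5,
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
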