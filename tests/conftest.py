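import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import crossmeth as cm

settings.register_profile("suite", derandomize=True, deadline=None,
                          max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def tiny_design():
    """One rat-like cohort, 4 control vs 4 stress."""
    return cm.DatasetDesign(dataset_id="rat_pfc", species="rat",
                            tissue="prefrontal_cortex", role="core",
                            n_control=4, n_stress=4)


@pytest.fixture
def tiny_config(tiny_design):
    return cm.StudyConfig(
        datasets=[tiny_design],
        n_genes=6,
        planted_genes=[
            cm.PlantedGene(gene_label="HYP", state_by_dataset={"rat_pfc": "hyper"}),
            cm.PlantedGene(gene_label="LOW", state_by_dataset={"rat_pfc": "hypo"}),
            cm.PlantedGene(gene_label="MIX", state_by_dataset={"rat_pfc": "mixed"}),
        ],
        seed=7,
    )


@pytest.fixture(scope="session")
def demo_study():
    """The bundled funnel demo study, simulated once for the session."""
    cfg = cm.funnel_demo_config(seed=3)
    return cm.generate_study(cfg)


def gene_calls_for(study, ds_id, fdr=0.2):
    """Probe-call -> gene-call chain for one simulated dataset."""
    data = study.datasets[ds_id]
    probe_calls = cm.call_dataset(data.bound, data.input, data.groups,
                                  annotation=study.annotation[ds_id].probes,
                                  fdr_threshold=fdr)
    assigned, _ = cm.map_probes_to_genes(probe_calls,
                                         study.annotation[ds_id].genes)
    return cm.classify_genes(assigned, dataset_id=ds_id), probe_calls


@pytest.fixture
def logratio_matrix():
    """Deterministic 6-probe, 4v4 log-ratio matrix."""
    rng = np.random.default_rng(11)
    samples = [f"c{i}" for i in range(4)] + [f"s{i}" for i in range(4)]
    values = pd.DataFrame(rng.normal(0, 0.5, (6, 8)),
                          index=[f"p{i}" for i in range(6)], columns=samples)
    groups = pd.Series(["control"] * 4 + ["stress"] * 4, index=samples)
    return cm.LogRatioMatrix(values, groups)
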