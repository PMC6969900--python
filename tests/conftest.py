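import numpy as np
import pandas as pd
import pytest

from mlsom import JointMatrix, PipelineConfig, train_som


def make_joint(values: np.ndarray, layer_of=None, group_of=None,
               genes=None, samples=None) -> JointMatrix:
    """Wrap a raw genes x samples array (centered on the fly) as a
    JointMatrix with minimal metadata."""
    n, s = values.shape
    genes = genes or [f"g{i:03d}" for i in range(n)]
    samples = samples or [f"s{j:03d}" for j in range(s)]
    layer_of = layer_of or {smp: "L" for smp in samples}
    group_of = group_of or {smp: ("target" if j < s // 2 else "reference")
                            for j, smp in enumerate(samples)}
    meta = pd.DataFrame(
        {"layer": [layer_of[smp] for smp in samples],
         "role": ["target_disease"] * s,
         "group": [group_of[smp] for smp in samples],
         "subgroup": [""] * s},
        index=pd.Index(samples, name="sample"))
    centered = values - values.mean(axis=1, keepdims=True)
    return JointMatrix(values=pd.DataFrame(centered, index=genes,
                                           columns=samples), samples=meta)


@pytest.fixture(scope="session")
def two_cluster_joint():
    """60 genes in two well-separated profile clusters (+1/-1 vs -1/+1,
    noise SD 0.1) across 6 samples."""
    rng = np.random.default_rng(0)
    n, s = 60, 6
    half = np.tile([1.0, -1.0], s // 2)
    X = np.r_[half[None, :] + rng.normal(0, 0.1, (n // 2, s)),
              -half[None, :] + rng.normal(0, 0.1, (n // 2, s))]
    return make_joint(X)


@pytest.fixture(scope="session")
def small_trained():
    """A small trained map on planted-module data, shared across tests."""
    from mlsom import build_joint_matrix, repositioning_scenario

    dataset, truth = repositioning_scenario(seed=11, n_genes=600,
                                            module_size=60, n_per_group=6)
    joint = build_joint_matrix(dataset)
    config = PipelineConfig(grid_size=10, random_seed=11)
    model = train_som(joint, config)
    return dataset, truth, joint, config, model
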