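import numpy as np
import pytest

import structpose as sp


@pytest.fixture(scope="session")
def worm_schema():
    return sp.builtin_schema("celegans")


@pytest.fixture(scope="session")
def fish_schema():
    return sp.builtin_schema("zebrafish")


@pytest.fixture(scope="session")
def fly_schema():
    return sp.builtin_schema("drosophila")


@pytest.fixture(scope="session")
def worm_scene():
    """A deterministic 3-worm scene shared across tests."""
    return sp.generate_scene(
        sp.SceneConfig(species="celegans", image_size=(128, 128),
                       n_instances=(3, 3), occlusion_prob=0.3, seed=7)
    )


@pytest.fixture(scope="session")
def tiny_model():
    """A small fixed-seed network for structural tests (worm schema)."""
    cfg = sp.ModelConfig(schema="celegans", channels=16, head_channels=8,
                         sgl_ffn_dim=32, backbone_widths=(8, 12, 16, 16), seed=3)
    return sp.build_model(cfg)


def random_pose(rng, schema, center=(64, 64), spread=30.0, image_size=(128, 128)):
    """A random labeled pose for evaluation tests."""
    k = schema.n_keypoints
    xy = np.asarray(center) + rng.uniform(-spread, spread, size=(k, 2))
    xy[:, 0] = np.clip(xy[:, 0], 1, image_size[1] - 2)
    xy[:, 1] = np.clip(xy[:, 1], 1, image_size[0] - 2)
    v = np.full(k, 2.0)
    inst = sp.PoseInstance(keypoints=np.column_stack([xy, v]))
    inst.center = sp.instance_center(inst, schema)
    inst.scale_s = inst.compute_scale()
    return inst
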