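import numpy as np
import pytest

from patchvote.backbone import BackboneConfig, build_backbone


def numerical_gradient(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of scalar f() with respect to array x."""
    grad = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        grad[i] = (fp - fm) / (2 * eps)
    return grad


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture(scope="session")
def small_backbone_cfg():
    """Width-scaled canonical-layout restricted backbone (rf 39, stride 16)."""
    return BackboneConfig(width_scale=0.25, cardinality=8)


@pytest.fixture(scope="session")
def small_extractor(small_backbone_cfg):
    return build_backbone(small_backbone_cfg, np.random.default_rng(7))


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """48-scene phantom dataset shared across training tests."""
    from patchvote.synthetic import SceneSpec, generate_dataset
    base = tmp_path_factory.mktemp("phantoms")
    generate_dataset(SceneSpec(n=48, seed=5), base / "d", overwrite=True)
    return base / "d"
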