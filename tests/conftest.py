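import numpy as np
import pytest

from histopatch.io_dataset import CLASSES
from histopatch.patching import PatchRecord
from histopatch.pipeline import PipelineConfig, run_pipeline
from histopatch.synthetic import FixtureSpec, make_dataset


def make_patch(pixels: np.ndarray, parent_id: str = "img", row: int = 0, col: int = 0, label: str = "normal") -> PatchRecord:
    return PatchRecord(parent_id=parent_id, row=row, col=col, y=row * 256, x=col * 256, pixels=pixels, label=label)


@pytest.fixture(scope="session")
def easy_spec() -> FixtureSpec:
    """Small, noiseless, well-separated fixture profile."""
    return FixtureSpec.easy(n_per_class=4, height=512, width=1024, seed=5)


@pytest.fixture(scope="session")
def fixture_patches(easy_spec):
    """All patches of a small rendered fixture set (48 patches, 12 per class)."""
    from histopatch.patching import extract_patches

    patches = []
    for record in make_dataset(easy_spec):
        patches.extend(extract_patches(record))
    return patches


@pytest.fixture(scope="session")
def toy_clusters():
    """Four well-separated 2-D Gaussian clusters, one per tissue class."""
    rng = np.random.default_rng(42)
    centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0], [10.0, 10.0]])
    x, y = [], []
    for ci, label in enumerate(CLASSES):
        x.append(centers[ci] + 0.5 * rng.standard_normal((15, 2)))
        y.extend([label] * 15)
    return np.vstack(x), y, centers


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory):
    """One full end-to-end run on the easy fixture benchmark."""
    out = tmp_path_factory.mktemp("run")
    config = PipelineConfig(out_dir=str(out), seed=1)
    return run_pipeline(config)
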