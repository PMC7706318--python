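import numpy as np
import pytest

from paddycount.codec import (
    DensityConfig,
    QuantizerSpec,
    class_map_from_count_map,
    count_map_from_density,
    density_from_dots,
    rasterize_dots,
)
from paddycount.network import PATCH_SIZE, BackboneSpec, CountingNetwork
from paddycount import nnkit as nn
from paddycount.synth import SceneSpec, render_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    return render_scene(SceneSpec(size=(256, 256), n_plants=40, seed=7))


class RiggedModel(CountingNetwork):
    """Counter whose head is rigged to emit a chosen class map.

    With ``fill_class`` set, every patch gets that class; otherwise the
    ground-truth class map of ``self.annotation`` (rasterized on the padded
    input extent) is emitted as one-hot logits. Exercises the full decode
    path of ``predict`` without a trained backbone.
    """

    def __init__(self, quantizer: QuantizerSpec, fill_class: int | None = None, sigma: float = 4.0):
        super().__init__(
            backbone_spec=BackboneSpec("tiny", stage_channels=(8, 12, 16)),
            quantizer=quantizer,
            sigma=sigma,
            downsample_ratio=1.0,
        )
        self.fill_class = fill_class
        self.annotation = None

    def forward(self, x):
        if not isinstance(x, nn.Tensor):
            x = nn.Tensor(x)
        shape = (x.data.shape[2], x.data.shape[3])
        nr = (shape[0] - PATCH_SIZE) // self.patch_stride + 1
        nc = (shape[1] - PATCH_SIZE) // self.patch_stride + 1
        if self.fill_class is not None:
            classes = np.full((nr, nc), self.fill_class, dtype=np.int64)
        else:
            dots = rasterize_dots(self.annotation, shape)
            density = density_from_dots(dots, DensityConfig(sigma=self.sigma))
            counts = count_map_from_density(density, PATCH_SIZE, self.patch_stride)
            classes = class_map_from_count_map(counts, self.quantizer).values
        logits = np.zeros((1, self.quantizer.n_classes, nr, nc), dtype=np.float32)
        for c in range(self.quantizer.n_classes):
            logits[0, c][classes == c] = 10.0
        return nn.Tensor(logits)


@pytest.fixture
def rigged_model_factory():
    return RiggedModel
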