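import numpy as np
import pytest
from hypothesis import settings

from cotresnet import (
    PhantomParams,
    TrainConfig,
    build_slice_dataset,
    generate_cohort,
    split_dataset,
)
from cotresnet.nn import BatchNorm2d, Conv2d, Linear, Module, global_avg_pool

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

#: learning rate for desk-scale runs (width-1/8 nets on ~10^2 slices); the
#: reference schedule's 3e-5 is sized for full-scale training.
DESK_LR = 3e-4


class TinyNet(Module):
    """Minimal conv classifier for fast training-loop tests."""

    def __init__(self, n_classes=2, seed=0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.conv = Conv2d(1, 4, 3, stride=2, padding=1, rng=rng)
        self.bn = BatchNorm2d(4)
        self.fc = Linear(4, n_classes, rng=rng)

    def forward(self, x):
        y = self.bn(self.conv(x)).relu()
        return self.fc(global_avg_pool(y))


@pytest.fixture()
def tiny_net():
    return TinyNet(seed=0)


@pytest.fixture(scope="session")
def small_params():
    return PhantomParams(grid=32)


@pytest.fixture(scope="session")
def small_cohort(small_params):
    """4 AD + 3 MCI + 2 HC phantoms at grid 32."""
    return generate_cohort((4, 3, 2), small_params, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    ds = build_slice_dataset(small_cohort, n_slices=10, resize_target=None)
    return split_dataset(ds, seed=11)


@pytest.fixture(scope="session")
def separable_dataset():
    """Strongly separable AD-vs-HC phantom slices at grid 64 (the sanity task)."""
    vols = generate_cohort((8, 0, 8), PhantomParams(grid=64), seed=7)
    ds = build_slice_dataset(vols, n_slices=10, resize_target=None)
    return split_dataset(ds, seed=7)


@pytest.fixture(scope="session")
def sanity_train_result(separable_dataset):
    """Width-1/8 CoT-ResNet-18 trained 20 epochs on the separable task."""
    from cotresnet import ArchSpec, build_model, train

    model = build_model(
        ArchSpec("cot_resnet18", n_classes=2, width_multiplier=0.125), seed=0
    )
    cfg = TrainConfig(lr0=DESK_LR, max_epochs=20, seed=0)
    return train(model, separable_dataset, cfg, task="AD:HC")
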