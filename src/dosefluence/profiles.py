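"""Scale presets bundling phantom, model and training configuration.

``paper`` mirrors the clinical-scale protocol (224 x 224 transverse grid,
160 x 160 fluence planes, base width 32, 150 epochs x 400 iterations);
``default`` keeps that geometry with a shorter schedule; ``tiny`` and
``micro`` are reduced grids for desk-scale runs and tests.  All profiles
share the 2.5 mm resolution, the nine 40-degree-spaced beams, and the
normalization/augmentation protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import ModelConfig
from .phantom import PhantomConfig
from .training import TrainConfig

__all__ = ["Profile", "get_profile", "PROFILE_NAMES"]


@dataclass(frozen=True)
class Profile:
    name: str
    phantom: PhantomConfig
    model: ModelConfig
    train: TrainConfig
    window_stride: int
    n_train: int
    n_val: int
    n_test: int


def _micro() -> Profile:
    phantom = PhantomConfig(
        grid_shape=(16, 48, 48),
        fluence_shape=(32, 32),
        opt_iterations=50,
    )
    model = ModelConfig(base_channels=8)
    train = TrainConfig(
        patch_slices=16, batch_size=2, epochs=4, iterations_per_epoch=25,
        model=model,
    )
    return Profile("micro", phantom, model, train, window_stride=12,
                   n_train=2, n_val=1, n_test=1)


def _tiny() -> Profile:
    phantom = PhantomConfig(
        grid_shape=(32, 96, 96),
        fluence_shape=(64, 64),
        opt_iterations=60,
    )
    model = ModelConfig(base_channels=8)
    train = TrainConfig(
        patch_slices=32, batch_size=2, epochs=10, iterations_per_epoch=50,
        model=model,
    )
    return Profile("tiny", phantom, model, train, window_stride=24,
                   n_train=20, n_val=4, n_test=4)


def _default() -> Profile:
    phantom = PhantomConfig()  # 64 x 224 x 224, 160 x 160 fluence
    model = ModelConfig()  # base 32
    train = TrainConfig(epochs=20, iterations_per_epoch=100, model=model)
    return Profile("default", phantom, model, train, window_stride=24,
                   n_train=20, n_val=4, n_test=4)


def _paper() -> Profile:
    phantom = PhantomConfig()
    model = ModelConfig()
    train = TrainConfig(epochs=150, iterations_per_epoch=400, model=model)
    return Profile("paper", phantom, model, train, window_stride=24,
                   n_train=260, n_val=40, n_test=40)


_FACTORIES = {"micro": _micro, "tiny": _tiny, "default": _default, "paper": _paper}
PROFILE_NAMES = tuple(_FACTORIES)


def get_profile(name: str) -> Profile:
    try:
        return _FACTORIES[name]()
    except KeyError:
        raise ValueError(f"unknown profile {name!r}; choose from {PROFILE_NAMES}") from None
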