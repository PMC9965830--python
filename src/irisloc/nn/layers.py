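"""Layer objects: parameter containers with a forward ``__call__``."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, batch_norm, conv2d, relu

__all__ = ["Layer", "Conv2d", "BatchNorm2d", "ConvBlock", "Sequential"]


class Layer:
    """Base class: tracks parameters and a shared train/eval mode flag."""

    def __init__(self) -> None:
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Layer):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Layer):
                        params.extend(item.parameters())
        return params

    def train(self, mode: bool = True) -> "Layer":
        self.training = mode
        for value in self.__dict__.values():
            if isinstance(value, Layer):
                value.train(mode)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Layer):
                        item.train(mode)
        return self

    def eval(self) -> "Layer":
        return self.train(False)

    # checkpointing ------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of parameters and buffers."""
        state: dict[str, np.ndarray] = {}

        def collect(obj: "Layer", prefix: str) -> None:
            for name, value in obj.__dict__.items():
                key = f"{prefix}{name}"
                if isinstance(value, Tensor) and value.requires_grad:
                    state[key] = value.data
                elif isinstance(value, np.ndarray):
                    state[key] = value
                elif isinstance(value, Layer):
                    collect(value, key + ".")
                elif isinstance(value, (list, tuple)):
                    for i, item in enumerate(value):
                        if isinstance(item, Layer):
                            collect(item, f"{key}.{i}.")

        collect(self, "")
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_arrays()
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"checkpoint missing arrays: {sorted(missing)}")
        for key, arr in own.items():
            np.copyto(arr, state[key])


class Conv2d(Layer):
    """3x3 (or kxk) convolution with He-normal initialization."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 1,
                 padding: int | None = None, rng: np.random.Generator | None = None,
                 bias_init: float = 0.0) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, scale, (out_ch, in_ch, kernel, kernel)).astype(np.float32),
            requires_grad=True,
        )
        self.bias = Tensor(np.full(out_ch, bias_init, dtype=np.float32),
                           requires_grad=True)
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Layer):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        out, m, v = batch_norm(x, self.gamma, self.beta, self.running_mean,
                               self.running_var, self.eps,
                               use_batch_stats=self.training)
        if self.training:
            self.running_mean += self.momentum * (m.astype(np.float32) - self.running_mean)
            self.running_var += self.momentum * (v.astype(np.float32) - self.running_var)
        return out


class ConvBlock(Layer):
    """conv -> batch norm -> relu."""

    def __init__(self, in_ch: int, out_ch: int, stride: int = 1,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, stride=stride, rng=rng)
        self.bn = BatchNorm2d(out_ch)

    def __call__(self, x: Tensor) -> Tensor:
        return relu(self.bn(self.conv(x)))


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        super().__init__()
        self.layers = list(layers)

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
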