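"""Layer/module abstractions over the autodiff ops."""

from __future__ import annotations

from typing import Dict, List

import numpy as np

from .autograd import Tensor, conv3d, instance_norm, leaky_relu

__all__ = ["Module", "Conv3d", "InstanceNorm3d", "ConvBlock"]


class Module:
    """Base class: tracks parameters of itself and registered submodules."""

    def __init__(self):
        self._params: Dict[str, Tensor] = {}
        self._modules: Dict[str, "Module"] = {}

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
            isinstance(v, Module) for v in value
        ):
            for i, v in enumerate(value):
                self.__dict__.setdefault("_modules", {})[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def parameters(self) -> List[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> Dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, m in self._modules.items():
            out.update(m.named_parameters(prefix + name + "."))
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: Dict[str, np.ndarray]):
        params = self.named_parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = arr.copy()


class Conv3d(Module):
    """3D convolution, stride 1, same zero-padding, He-initialized."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        super().__init__()
        fan_in = c_in * k**3
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, std, size=(c_out, c_in, k, k, k)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias)


class InstanceNorm3d(Module):
    def __init__(self, c: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return instance_norm(x, self.gamma, self.beta, self.eps)


class ConvBlock(Module):
    """Two (conv 3x3x3 -> instance norm -> leaky ReLU) stages."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        rng: np.random.Generator,
        leaky_slope: float = 0.01,
        norm_eps: float = 1e-5,
    ):
        super().__init__()
        self.conv1 = Conv3d(c_in, c_out, 3, rng)
        self.norm1 = InstanceNorm3d(c_out, norm_eps)
        self.conv2 = Conv3d(c_out, c_out, 3, rng)
        self.norm2 = InstanceNorm3d(c_out, norm_eps)
        self.slope = leaky_slope

    def __call__(self, x: Tensor) -> Tensor:
        x = leaky_relu(self.norm1(self.conv1(x)), self.slope)
        x = leaky_relu(self.norm2(self.conv2(x)), self.slope)
        return x
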