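"""Packing/unpacking of model parameters onto an unconstrained vector.

The sampler works on a single flat vector of transformed coordinates: log for
positive parameters, scaled logit for interval-bounded ones. Each block keeps
its natural-scale shape, its transform, and its slice into the packed vector.
Jacobian terms of the transforms are accumulated so densities specified on
the natural scale stay correct on the sampling scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit


class LogTransform:
    """x -> exp(x), mapping R to (0, inf)."""

    def forward(self, x):  # transformed -> natural
        return np.exp(x)

    def backward(self, value):
        value = np.asarray(value, dtype=float)
        if (value <= 0).any():
            raise ValueError("log transform needs positive values")
        return np.log(value)

    def log_jacobian(self, x):
        return float(np.sum(x))


class LogitTransform:
    """x -> lo + (hi - lo) * sigmoid(x), mapping R to (lo, hi)."""

    def __init__(self, lo: float, hi: float):
        if not hi > lo:
            raise ValueError("need hi > lo")
        self.lo, self.hi = float(lo), float(hi)

    def forward(self, x):
        return self.lo + (self.hi - self.lo) * expit(x)

    def backward(self, value):
        value = np.asarray(value, dtype=float)
        if (value <= self.lo).any() or (value >= self.hi).any():
            raise ValueError(f"values must lie strictly in ({self.lo}, {self.hi})")
        p = (value - self.lo) / (self.hi - self.lo)
        return np.log(p) - np.log1p(-p)

    def log_jacobian(self, x):
        x = np.asarray(x, dtype=float)
        # d natural / dx = (hi - lo) * sigmoid(x) * (1 - sigmoid(x))
        return float(
            np.sum(np.log(self.hi - self.lo) - np.logaddexp(0.0, -x)
                   - np.logaddexp(0.0, x))
        )


@dataclass(frozen=True)
class Block:
    """One named parameter block in the packed vector."""

    name: str
    shape: tuple[int, ...]
    transform: object

    @property
    def size(self) -> int:
        return int(np.prod(self.shape)) if self.shape else 1


class ParameterSpace:
    """Ordered collection of blocks with pack/unpack on the flat vector."""

    def __init__(self, blocks: list[Block]):
        self.blocks = blocks
        self.slices: dict[str, slice] = {}
        offset = 0
        for b in blocks:
            self.slices[b.name] = slice(offset, offset + b.size)
            offset += b.size
        self.size = offset
        # vectorised transform tables for the hot path
        self._is_log = np.zeros(self.size, dtype=bool)
        self._lo = np.zeros(self.size)
        self._span = np.ones(self.size)
        for b in blocks:
            sl = self.slices[b.name]
            if isinstance(b.transform, LogTransform):
                self._is_log[sl] = True
            else:
                self._lo[sl] = b.transform.lo
                self._span[sl] = b.transform.hi - b.transform.lo
        self._log_span_total = float(np.log(self._span[~self._is_log]).sum())

    def pack(self, natural: dict[str, np.ndarray]) -> np.ndarray:
        x = np.empty(self.size)
        for b in self.blocks:
            x[self.slices[b.name]] = np.ravel(
                b.transform.backward(natural[b.name])
            )
        return x

    def unpack(self, x: np.ndarray) -> dict[str, np.ndarray]:
        natural = np.empty(self.size)
        m = self._is_log
        natural[m] = np.exp(np.minimum(x[m], 700.0))  # avoid inf under optimizer probes
        natural[~m] = self._lo[~m] + self._span[~m] * expit(x[~m])
        out = {}
        for b in self.blocks:
            seg = natural[self.slices[b.name]]
            out[b.name] = seg.reshape(b.shape) if b.shape else float(seg[0])
        return out

    def log_jacobian(self, x: np.ndarray) -> float:
        # log|d natural/dx|: x for log coords; log span + log sig + log(1-sig)
        # for logit coords (softplus form)
        logit_x = x[~self._is_log]
        softplus = np.logaddexp(0.0, logit_x) + np.logaddexp(0.0, -logit_x)
        return float(x[self._is_log].sum() + self._log_span_total
                     - softplus.sum())

    def flat_names(self) -> list[str]:
        names = []
        for b in self.blocks:
            if not b.shape:
                names.append(b.name)
            else:
                for idx in np.ndindex(*b.shape):
                    names.append(f"{b.name}[" + ",".join(map(str, idx)) + "]")
        return names
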