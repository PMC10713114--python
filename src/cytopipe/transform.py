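"""Per-channel display transformations: logicle, biexponential, arcsinh.

Cytometry fluorescence/metal intensities span several decades and carry
meaningful near-zero and negative values (spreading error, compensation
residuals).  A pure log scale destroys the negatives; these transforms
are linear near zero and logarithmic at high signal.

arcsinh
    ``y = asinh(a + b * x) + c``.

biexponential
    ``y`` solves ``B(y) = a*exp(b*(y - w)) - c*exp(-d*(y - w)) + f = x``,
    found by bracketed root-finding.  With a = c = 0.5, b = d = 1,
    f = w = 0 this reduces exactly to ``asinh``.

logicle
    The Parks-Roederer-Moore biexponential family parameterized by
    (t, w, m, a): t is the top of scale, m the total display decades,
    w the linearization width in decades, a the additional negative
    decades.  The closed form is the *inverse* (scale -> data); the
    forward transform solves it numerically.  Output is in decades, so
    the top of scale t maps to m + a and transformed values are directly
    comparable across channels before rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

from .errors import EstimationError, ParameterError
from .model import Dataset, Sample

__all__ = [
    "TransformSpec",
    "apply_transform",
    "inverse_transform",
    "estimate_logicle",
    "transform_values",
]

_KINDS = ("logicle", "biexponential", "arcsinh")


@dataclass(frozen=True)
class TransformSpec:
    """One channel's transformation kind and named parameters."""

    kind: str
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ParameterError(f"unknown transform kind {self.kind!r}")
        p = dict(self.params)
        object.__setattr__(self, "params", p)
        if self.kind == "logicle":
            t, w, m, a = (p.get(k) for k in ("t", "w", "m", "a"))
            if t is None or w is None or m is None:
                raise ParameterError("logicle requires parameters t, w, m (a optional)")
            p.setdefault("a", 0.0)
            if t <= 0:
                raise ParameterError(f"logicle: t must be > 0, got {t}")
            if m <= 0:
                raise ParameterError(f"logicle: m must be > 0, got {m}")
            if not (0 <= w <= m / 2):
                raise ParameterError(f"logicle: need 0 <= w <= m/2, got w={w}, m={m}")
            if p["a"] < 0:
                raise ParameterError(f"logicle: a must be >= 0, got {p['a']}")
        elif self.kind == "biexponential":
            for k in ("a", "b", "c", "d", "f", "w"):
                p.setdefault(k, {"a": 0.5, "b": 1.0, "c": 0.5, "d": 1.0}.get(k, 0.0))
            if p["b"] <= 0 or p["d"] <= 0:
                raise ParameterError("biexponential: b and d must be > 0")
            if p["a"] < 0 or p["c"] < 0 or p["a"] + p["c"] <= 0:
                raise ParameterError("biexponential: need a, c >= 0 and a + c > 0")
        elif self.kind == "arcsinh":
            for k, v in (("a", 0.0), ("b", 1.0), ("c", 0.0)):
                p.setdefault(k, v)
            if p["b"] == 0:
                raise ParameterError("arcsinh: b must be nonzero")

    def to_dict(self) -> dict:
        return {"kind": self.kind, "params": dict(self.params)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "TransformSpec":
        return cls(kind=d["kind"], params=dict(d["params"]))


# ---------------------------------------------------------------------------
# logicle internals


class _Logicle:
    """Coefficients of the logicle scale function.

    The scale position u in [0, 1] covers m + a decades.  The inverse
    (scale -> data) is ``S(u) = ca*exp(b*u) - cc*exp(-d*u) + cf`` with
    coefficients chosen so that S(1) = t, S(x1) = 0 at the center of the
    linear region, and the quasi-linear region spans 2*w_n on the u axis.
    """

    def __init__(self, t: float, w: float, m: float, a: float = 0.0):
        self.t, self.w, self.m, self.a = t, w, m, a
        decades = m + a
        self.decades = decades
        b = decades * np.log(10.0)
        w_n = w / decades
        x2 = a / decades
        x1 = x2 + w_n
        x0 = x2 + 2.0 * w_n
        if w_n > 0:
            # d solves 2 (ln d - ln b) + w_n (b + d) = 0 on (0, b)
            g = lambda d: 2.0 * (np.log(d) - np.log(b)) + w_n * (b + d)
            d = brentq(g, 1e-12, b, xtol=1e-14, rtol=1e-15)
        else:
            d = b
        c_a = np.exp(x0 * (b + d))
        mf_a = np.exp(b * x1) - c_a / np.exp(d * x1)
        scale = t / ((np.exp(b) - mf_a) - c_a / np.exp(d))
        self.b, self.d = b, d
        self.ca = scale
        self.cc = c_a * scale
        self.cf = -mf_a * scale

    def scale_to_data(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=np.float64)
        return self.ca * np.exp(self.b * u) - self.cc * np.exp(-self.d * u) + self.cf

    def _slope(self, u: np.ndarray) -> np.ndarray:
        return self.b * self.ca * np.exp(self.b * u) + self.d * self.cc * np.exp(-self.d * u)

    def data_to_scale(self, x: np.ndarray) -> tuple[np.ndarray, int]:
        """Invert S by bisection-guarded Newton; returns (u, n_clamped).

        Values below S(0), the most negative representable signal, are
        clamped to u = 0 and counted.
        """
        x = np.asarray(x, dtype=np.float64)
        floor = self.scale_to_data(0.0)
        clamped = x < floor
        n_clamped = int(np.count_nonzero(clamped))
        xc = np.where(clamped, floor, x)
        # S is convex-ish and strictly increasing on [0, ~1.5]; bracket
        # generously above 1 so values slightly over t still invert.
        lo = np.zeros_like(xc)
        hi = np.full_like(xc, 1.5)
        while np.any(self.scale_to_data(hi) < xc):
            hi = np.where(self.scale_to_data(hi) < xc, hi + 0.5, hi)
        u = 0.5 * (lo + hi)
        for _ in range(100):
            f = self.scale_to_data(u) - xc
            lo = np.where(f < 0, u, lo)
            hi = np.where(f > 0, u, hi)
            step = f / self._slope(u)
            u_new = u - step
            outside = (u_new <= lo) | (u_new >= hi)
            u_new = np.where(outside, 0.5 * (lo + hi), u_new)
            if np.all(np.abs(u_new - u) < 1e-14):
                u = u_new
                break
            u = u_new
        return u, n_clamped


def _biexp_value(y, p):
    yw = y - p["w"]
    return p["a"] * np.exp(p["b"] * yw) - p["c"] * np.exp(-p["d"] * yw) + p["f"]


def _biexp_solve(x: np.ndarray, p: Mapping[str, float]) -> np.ndarray:
    """Solve B(y) = x elementwise by bisection-guarded Newton (1e-8 abs)."""
    x = np.asarray(x, dtype=np.float64)
    lo = np.full_like(x, -1.0)
    hi = np.full_like(x, 1.0)
    for _ in range(200):
        need_lo = _biexp_value(lo, p) > x
        need_hi = _biexp_value(hi, p) < x
        if not (np.any(need_lo) or np.any(need_hi)):
            break
        lo = np.where(need_lo, 2 * lo - 1, lo)
        hi = np.where(need_hi, 2 * hi + 1, hi)
    y = 0.5 * (lo + hi)
    for _ in range(200):
        f = _biexp_value(y, p) - x
        lo = np.where(f < 0, y, lo)
        hi = np.where(f > 0, y, hi)
        yw = y - p["w"]
        slope = p["a"] * p["b"] * np.exp(p["b"] * yw) + p["c"] * p["d"] * np.exp(-p["d"] * yw)
        y_new = y - f / slope
        outside = (y_new <= lo) | (y_new >= hi)
        y_new = np.where(outside, 0.5 * (lo + hi), y_new)
        if np.all(np.abs(y_new - y) < 1e-10):
            y = y_new
            break
        y = y_new
    return y


# ---------------------------------------------------------------------------
# public API


def transform_values(values: np.ndarray, spec: TransformSpec) -> np.ndarray:
    """Apply a transform to a plain vector (no Sample bookkeeping)."""
    x = np.asarray(values, dtype=np.float64)
    p = spec.params
    if spec.kind == "arcsinh":
        return np.arcsinh(p["a"] + p["b"] * x) + p["c"]
    if spec.kind == "biexponential":
        return _biexp_solve(x, p)
    lg = _Logicle(p["t"], p["w"], p["m"], p["a"])
    u, _ = lg.data_to_scale(x)
    return u * lg.decades


def inverse_transform(values: np.ndarray, spec: TransformSpec) -> np.ndarray:
    """Map transformed values back to the original (linear) scale."""
    y = np.asarray(values, dtype=np.float64)
    p = spec.params
    if spec.kind == "arcsinh":
        return (np.sinh(y - p["c"]) - p["a"]) / p["b"]
    if spec.kind == "biexponential":
        return _biexp_value(y, p)
    lg = _Logicle(p["t"], p["w"], p["m"], p["a"])
    return lg.scale_to_data(y / lg.decades)


def apply_transform(
    dataset: Dataset, specs: Mapping[str, TransformSpec], inverse: bool = False
) -> Dataset:
    """Transform the named channels of every sample in place (on a copy).

    Channels absent from ``specs`` are untouched.  The full parameter
    record is appended to each sample's provenance so the exact transform
    is recoverable later.
    """
    for label in specs:
        if label not in dataset.channel_labels:
            raise ParameterError(
                f"transform spec names unknown channel {label!r}; "
                f"panel: {dataset.channel_labels}"
            )
    out = dataset.copy()
    fn = inverse_transform if inverse else transform_values
    for s in out.samples:
        for label, spec in specs.items():
            j = s.channel_index(label)
            s.events[:, j] = fn(s.events[:, j], spec)
        s.log(
            "inverse_transform" if inverse else "apply_transform",
            specs={label: spec.to_dict() for label, spec in specs.items()},
        )
    return out


def estimate_logicle(sample: Sample, channel: str, m: float = 4.5) -> TransformSpec:
    """Data-driven logicle parameters for one channel.

    Follows the de-facto standard estimator: t is the declared channel
    range ($PnR) or the observed maximum; w is half the decades between
    the top of scale and the 5th percentile of the negative events,
    floored at 0.1.  Channels with no negative events get w = 1.0.
    """
    if sample.n_events < 100:
        raise EstimationError(
            f"need >= 100 events to estimate logicle, got {sample.n_events}"
        )
    j = sample.channel_index(channel)
    x = sample.events[:, j]
    pnr = sample.keywords.get(f"$P{j + 1}R")
    t = float(pnr) if pnr else float(np.max(x))
    if t <= 0:
        t = float(np.max(x)) if np.max(x) > 0 else 1.0
    neg = x[x < 0]
    if neg.size == 0:
        w = 1.0
    else:
        r = float(np.percentile(neg, 5))
        w = max(0.1, (m - np.log10(t / abs(r))) / 2.0)
    w = min(w, m / 2.0)
    return TransformSpec("logicle", {"t": t, "w": w, "m": m, "a": 0.0})
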