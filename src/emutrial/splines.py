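"""Restricted cubic spline basis for follow-up time.

The discrete-time hazard models represent time since baseline with a
restricted cubic spline — piecewise cubic, constrained to be linear
beyond the boundary knots — with default knots at 6, 12, 24 and 36
months. The truncated-power parameterization is used: for knots
t_1 < ... < t_K the basis has K-1 columns, the first being x itself and,
for j = 1..K-2,

    s_j(x) = [ (x-t_j)_+^3
               - (x-t_{K-1})_+^3 (t_K-t_j)/(t_K-t_{K-1})
               + (x-t_K)_+^3   (t_{K-1}-t_j)/(t_K-t_{K-1}) ] / (t_K-t_1)^2

The division by (t_K - t_1)^2 keeps the nonlinear columns on roughly the
same scale as the linear one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = ["SplineSpec", "rcs_basis"]

DEFAULT_KNOTS = (6.0, 12.0, 24.0, 36.0)


@dataclass(frozen=True)
class SplineSpec:
    """Knot layout for the restricted cubic time spline (months)."""

    knots: tuple[float, ...] = DEFAULT_KNOTS

    def __post_init__(self):
        ks = tuple(float(k) for k in self.knots)
        if len(ks) < 3:
            raise ConfigurationError("a restricted cubic spline needs >= 3 knots")
        if any(b <= a for a, b in zip(ks, ks[1:])):
            raise ConfigurationError("spline knots must be strictly increasing")
        object.__setattr__(self, "knots", ks)

    @property
    def n_columns(self) -> int:
        return len(self.knots) - 1

    def column_names(self, prefix: str = "t") -> list[str]:
        return [prefix] + [f"{prefix}_rcs{j}" for j in range(1, len(self.knots) - 1)]


def rcs_basis(x, spec: SplineSpec | None = None) -> np.ndarray:
    """Evaluate the restricted cubic spline basis at `x`.

    Returns an array of shape (len(x), K-1); column 0 is the identity.
    """
    if spec is None:
        spec = SplineSpec()
    x = np.atleast_1d(np.asarray(x, dtype=float))
    t = np.asarray(spec.knots)
    K = t.size
    out = np.empty((x.size, K - 1))
    out[:, 0] = x
    denom = (t[-1] - t[0]) ** 2
    ratio_hi = t[-1] - t[-2]

    def tp3(v):  # truncated cube
        return np.clip(v, 0.0, None) ** 3

    for j in range(K - 2):
        term = (
            tp3(x - t[j])
            - tp3(x - t[-2]) * (t[-1] - t[j]) / ratio_hi
            + tp3(x - t[-1]) * (t[-2] - t[j]) / ratio_hi
        )
        out[:, j + 1] = term / denom
    return out
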