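"""Low-rank penalized spline bases for the additive count model.

Each covariate smooth uses a rank-k basis with a quadratic roughness
penalty:

* ``tps`` — the 1-D thin-plate smoother (equivalently, cubic smoothing
  spline) reproducing-kernel basis with knots at covariate quantiles.  The
  penalty is the kernel Gram matrix: positive semi-definite with a null
  space spanned by the linear trend, so an infinitely penalized smooth
  collapses to a straight line.  No knot-placement tuning is required
  beyond k.
* ``cyclic`` — a harmonic (sine/cosine) basis for the epi-week seasonal
  term, period 52 weeks, with the j^4 penalty implied by the integrated
  squared second derivative.  Periodicity in value and every derivative at
  the week-1/week-53 boundary is exact by construction.
* ``linear`` — a single unpenalized centered column (used for forcing a
  parametric limit or as a degenerate smooth).

All bases absorb the sum-to-zero identifiability constraint by centering
their columns over the training rows, so any fitted smooth averages to
zero over the training data and the model intercept is the log baseline
rate.  Evaluation outside the training range extends the smooth linearly
(continuous value and first derivative at the boundary).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SmoothSpec", "SmoothBasis"]


@dataclass
class SmoothSpec:
    """Specification of one smooth term.

    Parameters
    ----------
    column : name of the covariate in the design frame.
    k : basis dimension (>= 3 for tps; >= 4 for cyclic; ignored for linear).
        One degree of freedom is absorbed by the sum-to-zero constraint, so
        the fitted block has k - 1 coefficients.
    basis : {"tps", "cyclic", "linear"}.
    period : cycle length for the cyclic basis (weeks).
    lam : optional fixed smoothing parameter; when None (default) the
        smoothing parameter is estimated by REML.
    """

    column: str
    k: int = 8
    basis: str = "tps"
    period: float = 52.0
    lam: float | None = None


def _tps_kernel(s, t):
    """Reproducing kernel of the 1-D thin-plate / cubic-spline smoother on [0,1]."""
    s = np.asarray(s, dtype=float)
    t = np.asarray(t, dtype=float)
    hs = (s - 0.5) ** 2 - 1.0 / 12.0
    ht = (t - 0.5) ** 2 - 1.0 / 12.0
    a = np.abs(s - t) - 0.5
    return hs * ht / 4.0 - (a**4 - 0.5 * a**2 + 7.0 / 240.0) / 24.0


def _tps_kernel_dt(s, t):
    """d/dt of the kernel (for linear extension beyond the data range)."""
    s = np.asarray(s, dtype=float)
    t = np.asarray(t, dtype=float)
    hs = (s - 0.5) ** 2 - 1.0 / 12.0
    a = np.abs(s - t) - 0.5
    sign = np.sign(t - s)
    return hs * (t - 0.5) / 2.0 - sign * (4.0 * a**3 - a) / 24.0


@dataclass
class SmoothBasis:
    """Fitted basis for one smooth: transform + penalty + constraint."""

    spec: SmoothSpec
    lo_: float = 0.0
    hi_: float = 1.0
    knots_: np.ndarray = field(default_factory=lambda: np.zeros(0))
    col_means_: np.ndarray = field(default_factory=lambda: np.zeros(0))
    penalty_: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    k_used_: int = 0

    # ---------------------------------------------------------------- fit
    def fit(self, values) -> "SmoothBasis":
        x = np.asarray(values, dtype=float)
        if np.ptp(x) == 0:
            raise ValueError(f"constant covariate {self.spec.column!r}: no smooth can be built")
        kind = self.spec.basis
        if kind == "linear":
            self.col_means_ = np.array([x.mean()])
            self.penalty_ = np.zeros((1, 1))
            self.k_used_ = 2
            self.lo_, self.hi_ = float(x.min()), float(x.max())
            return self
        if kind == "tps":
            k = self.spec.k
            if k < 3:
                raise ValueError("tps basis needs k >= 3")
            n_distinct = len(np.unique(x))
            if n_distinct < k:
                warnings.warn(
                    f"covariate {self.spec.column!r} has {n_distinct} distinct values; "
                    f"reducing basis dimension from {k} to {n_distinct}"
                )
                k = n_distinct
                if k < 3:
                    raise ValueError(f"covariate {self.spec.column!r} too coarse for a smooth")
            self.lo_, self.hi_ = float(x.min()), float(x.max())
            t = self._rescale(x)
            q = k - 2
            probs = (np.arange(q) + 1.0) / (q + 1.0)
            knots = np.quantile(np.unique(t), probs)
            # nudge coincident knots apart (heavily tied covariates)
            for i in range(1, q):
                if knots[i] <= knots[i - 1]:
                    knots[i] = knots[i - 1] + 1e-8
            self.knots_ = knots
            raw = self._raw_columns(t)
            self.col_means_ = raw.mean(axis=0)
            S = np.zeros((q + 1, q + 1))
            gram = _tps_kernel(knots[:, None], knots[None, :])
            gram = (gram + gram.T) / 2.0
            # clip tiny negative eigenvalues from rounding; penalty must be psd
            w, V = np.linalg.eigh(gram)
            gram = (V * np.clip(w, 0.0, None)) @ V.T
            S[1:, 1:] = gram
            self.penalty_ = S
            self.k_used_ = k
            return self
        if kind == "cyclic":
            k = self.spec.k
            if k < 4:
                raise ValueError("cyclic basis needs k >= 4")
            m = (k - 2) // 2
            self.k_used_ = 2 * m + 2
            self.lo_, self.hi_ = float(x.min()), float(x.max())
            raw = self._raw_columns(x)
            self.col_means_ = raw.mean(axis=0)
            j = np.repeat(np.arange(1, m + 1), 2).astype(float)
            self.penalty_ = np.diag(j**4)
            return self
        raise ValueError(f"unknown basis type {kind!r}")

    # ---------------------------------------------------------- internals
    def _rescale(self, x):
        return (np.asarray(x, dtype=float) - self.lo_) / (self.hi_ - self.lo_)

    def _raw_columns(self, t):
        """Un-centered basis columns at already-rescaled values (tps) or raw (cyclic)."""
        kind = self.spec.basis
        if kind == "linear":
            return np.asarray(t, dtype=float)[:, None]
        if kind == "tps":
            t = np.asarray(t, dtype=float)
            cols = [t] + [_tps_kernel(kj, t) for kj in self.knots_]
            return np.column_stack(cols)
        # cyclic: phase in [0, 2*pi) with week w -> (w - 1) / period
        w = np.asarray(t, dtype=float)
        theta = 2.0 * np.pi * (w - 1.0) / self.spec.period
        m = (self.k_used_ - 2) // 2
        cols = []
        for j in range(1, m + 1):
            cols += [np.sin(j * theta), np.cos(j * theta)]
        return np.column_stack(cols)

    def _raw_derivative(self, t):
        """d(raw columns)/dt at rescaled values (tps only)."""
        t = np.asarray(t, dtype=float)
        cols = [np.ones_like(t)] + [_tps_kernel_dt(kj, t) for kj in self.knots_]
        return np.column_stack(cols)

    # ----------------------------------------------------------- transform
    def transform(self, values) -> np.ndarray:
        """Evaluate the constrained basis at new covariate values.

        Values beyond the training range are handled by linear extension of
        each basis function from the nearest boundary; a warning is issued
        because extrapolated smooths are only first-order trustworthy.
        """
        x = np.asarray(values, dtype=float)
        kind = self.spec.basis
        if kind == "linear":
            return x[:, None] - self.col_means_
        if kind == "cyclic":
            return self._raw_columns(x) - self.col_means_
        t = self._rescale(x)
        inside = (t >= 0.0) & (t <= 1.0)
        tc = np.clip(t, 0.0, 1.0)
        raw = self._raw_columns(tc)
        if not inside.all():
            warnings.warn(
                f"{(~inside).sum()} value(s) of {self.spec.column!r} outside the "
                "training range; smooth extended linearly"
            )
            out = ~inside
            raw[out] += (t[out] - tc[out])[:, None] * self._raw_derivative(tc[out])
        return raw - self.col_means_

    @property
    def n_cols(self) -> int:
        return len(self.col_means_)

    @property
    def penalty_rank(self) -> int:
        return int(np.linalg.matrix_rank(self.penalty_)) if self.penalty_.size else 0

    # -------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        return {
            "spec": {
                "column": self.spec.column,
                "k": self.spec.k,
                "basis": self.spec.basis,
                "period": self.spec.period,
                "lam": self.spec.lam,
            },
            "lo": self.lo_,
            "hi": self.hi_,
            "knots": self.knots_.tolist(),
            "col_means": self.col_means_.tolist(),
            "penalty": self.penalty_.tolist(),
            "k_used": self.k_used_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SmoothBasis":
        spec = SmoothSpec(**d["spec"])
        b = cls(spec=spec)
        b.lo_ = d["lo"]
        b.hi_ = d["hi"]
        b.knots_ = np.asarray(d["knots"], dtype=float)
        b.col_means_ = np.asarray(d["col_means"], dtype=float)
        b.penalty_ = np.asarray(d["penalty"], dtype=float)
        b.k_used_ = d["k_used"]
        return b
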