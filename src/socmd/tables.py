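"""Piecewise-polynomial function tables (ROM-table function evaluation).

The pipeline hardware evaluates its fixed function forms (the Ewald
real-space cut-off factor, inverse powers for the dispersion terms) from
a read-only table of per-segment polynomial coefficients rather than
from a general-purpose FPU.  This module models that scheme: a function
is sampled on uniform segments of its domain, each segment carries a
least-squares polynomial fit, and evaluation selects the segment and
evaluates the polynomial by Horner's rule.

Accuracy target: single-precision-grade relative error (about 1.2e-7)
across the tabulated domain.  Functions with a large dynamic range reach
that target by fitting ``log f`` (``log_value=True``), optionally against
``log t`` (``log_arg=True``), which makes the relative error uniform; a
pure power law tabulated log-log is exact to fit noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "FunctionTable",
    "build_function_table",
    "eval_table",
    "erfc_table",
    "inverse_power_table",
    "SINGLE_PRECISION_RTOL",
]

SINGLE_PRECISION_RTOL = 1.2e-7


@dataclass(frozen=True)
class FunctionTable:
    """Segmented polynomial approximation of a scalar function."""

    lo: float
    hi: float
    coeffs: np.ndarray      # (segments, degree+1), highest power first
    log_arg: bool = False   # segments uniform in log(t)
    log_value: bool = False  # polynomial approximates log(f)

    @property
    def segments(self) -> int:
        return self.coeffs.shape[0]


def build_function_table(func, domain, segments: int = 256, degree: int = 2,
                         log_arg: bool = False, log_value: bool = False,
                         samples_per_segment: int = 16) -> FunctionTable:
    """Fit ``func`` with per-segment least-squares polynomials.

    Parameters
    ----------
    func:
        Callable accepting a NumPy array.  With ``log_value=True`` it
        must be strictly positive on the domain.
    domain:
        ``(lo, hi)`` interval of the argument.
    segments:
        Number of uniform segments (in ``t``, or ``log t`` if
        ``log_arg``).
    degree:
        Polynomial degree per segment (2 = quadratic, the default).
    """
    lo, hi = float(domain[0]), float(domain[1])
    if not hi > lo:
        raise ValueError("empty table domain")
    if segments < 1:
        raise ValueError("need at least one segment")
    if log_arg and lo <= 0:
        raise ValueError("log-spaced table needs a positive domain")

    edges = (np.geomspace(lo, hi, segments + 1) if log_arg
             else np.linspace(lo, hi, segments + 1))
    coeffs = np.empty((segments, degree + 1))
    for s in range(segments):
        t = np.linspace(edges[s], edges[s + 1], samples_per_segment)
        y = np.asarray(func(t), dtype=np.float64)
        u = np.log(t) if log_arg else t
        v = np.log(y) if log_value else y
        coeffs[s] = np.polyfit(u, v, degree)
    return FunctionTable(lo=lo, hi=hi, coeffs=coeffs,
                         log_arg=log_arg, log_value=log_value)


def eval_table(table: FunctionTable, t):
    """Evaluate a table at scalar or array argument ``t`` (domain-checked)."""
    t_arr = np.asarray(t, dtype=np.float64)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    if np.any(t_arr < table.lo) or np.any(t_arr > table.hi):
        raise ValueError("argument outside table domain")

    if table.log_arg:
        u = np.log(t_arr)
        lo, hi = np.log(table.lo), np.log(table.hi)
    else:
        u = t_arr
        lo, hi = table.lo, table.hi
    idx = np.clip(((u - lo) / (hi - lo) * table.segments).astype(np.int64),
                  0, table.segments - 1)

    c = table.coeffs[idx]            # (n, degree+1)
    y = c[:, 0].copy()
    for k in range(1, c.shape[1]):   # Horner
        y = y * u + c[:, k]
    if table.log_value:
        y = np.exp(y)
    return float(y[0]) if scalar else y


def erfc_table(t_max: float = 6.0, segments: int = 512) -> FunctionTable:
    """Default table for ``erfc`` on ``[0, t_max]``.

    ``log erfc`` is close to ``-t**2`` and very smooth, so a quadratic
    log-value fit holds single-precision relative accuracy over the full
    dynamic range of the function (down to ~1e-17 at t=6).
    """
    return build_function_table(special.erfc, (0.0, t_max),
                                segments=segments, log_value=True)


def inverse_power_table(power: int, domain, segments: int = 256) -> FunctionTable:
    """Table for ``t**-power``; log-log quadratic fit of a power law is
    linear and therefore exact to fit noise."""
    return build_function_table(lambda t: t ** (-float(power)), domain,
                                segments=segments, log_arg=True, log_value=True)
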