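"""Reporting arithmetic for accuracy comparisons.

Three small utilities used when summarizing classifier metrics across
patch-size experiments: the sample standard deviation (n-1 denominator),
the symmetric percentage difference (|a-b| over the mean of a and b), and
the standard Z-score of a value against a reference series.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["sample_sd", "pct_diff", "z_score", "InsufficientDataError"]


class InsufficientDataError(ValueError):
    pass


def sample_sd(xs: Sequence[float]) -> float:
    """Sample standard deviation, sqrt(sum((x - mean)^2) / (n - 1))."""
    xs = np.asarray(xs, dtype=np.float64)
    if xs.size < 2:
        raise InsufficientDataError(f"need at least 2 values, got {xs.size}")
    if not np.all(np.isfinite(xs)):
        raise ValueError("non-finite value in series")
    return float(np.std(xs, ddof=1))


def pct_diff(a: float, b: float) -> float:
    """Symmetric percentage difference: |a - b| / ((a + b) / 2) * 100.

    Unlike relative difference to a baseline, this is symmetric in its
    arguments and zero iff a == b.
    """
    if a + b == 0:
        raise ZeroDivisionError("percentage difference undefined when a + b = 0")
    return abs(a - b) / ((a + b) / 2.0) * 100.0


def z_score(x: float, ref: Sequence[float]) -> float:
    """(x - mean(ref)) / sample_sd(ref)."""
    sd = sample_sd(ref)
    if sd == 0:
        raise ZeroDivisionError("z-score undefined for zero-spread reference")
    return (float(x) - float(np.mean(ref))) / sd
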