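"""Piecewise-constant (step-function) arithmetic over genomic coordinates.

Coverage tracks, masks and base-composition indicators are all step
functions of the genomic coordinate.  Window statistics (coverage sums,
covered-base counts, unmasked lengths) are integrals of such functions over
half-open intervals, which we evaluate from a single cumulative array with
two binary searches per window instead of materialising per-base arrays.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "merge_intervals",
    "interval_total",
    "StepFunction",
    "coverage_step",
    "indicator_step",
]


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort and merge overlapping/adjacent half-open intervals."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            if e > out_e[-1]:
                out_e[-1] = e
        else:
            out_s.append(s)
            out_e.append(e)
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def interval_total(starts: np.ndarray, ends: np.ndarray) -> int:
    """Total length covered by merged intervals."""
    s, e = merge_intervals(starts, ends)
    return int(np.sum(e - s))


class StepFunction:
    """f(x) = values[i] on [breakpoints[i], breakpoints[i+1]).

    ``breakpoints`` has one more entry than ``values``; the first breakpoint
    is 0 and the last is the chromosome length.
    """

    def __init__(self, breakpoints: np.ndarray, values: np.ndarray):
        self.bp = np.asarray(breakpoints, dtype=np.int64)
        self.values = np.asarray(values, dtype=np.float64)
        if self.bp.size != self.values.size + 1:
            raise ValueError("breakpoints must have len(values)+1 entries")
        seg = np.diff(self.bp).astype(np.float64)
        self._cum = np.concatenate([[0.0], np.cumsum(self.values * seg)])

    @property
    def length(self) -> int:
        return int(self.bp[-1])

    def integral_to(self, x: np.ndarray) -> np.ndarray:
        """Vectorised cumulative integral from 0 to each x."""
        x = np.asarray(x, dtype=np.int64)
        j = np.searchsorted(self.bp, x, side="right") - 1
        j = np.clip(j, 0, self.values.size - 1)
        return self._cum[j] + self.values[j] * (x - self.bp[j])

    def window_sums(self, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Integral of f over each half-open [start, end)."""
        return self.integral_to(ends) - self.integral_to(starts)

    def multiply(self, other: "StepFunction") -> "StepFunction":
        """Pointwise product on the union of breakpoints."""
        if self.length != other.length:
            raise ValueError("step functions span different lengths")
        # constant factors need no breakpoint merge (e.g. an empty mask)
        if other.values.size and np.all(other.values == other.values[0]):
            return StepFunction(self.bp, self.values * other.values[0])
        if self.values.size and np.all(self.values == self.values[0]):
            return StepFunction(other.bp, other.values * self.values[0])
        bp = _sorted_union(self.bp, other.bp)
        left = bp[:-1]
        a = self.values[np.clip(np.searchsorted(self.bp, left, side="right") - 1, 0, self.values.size - 1)]
        b = other.values[np.clip(np.searchsorted(other.bp, left, side="right") - 1, 0, other.values.size - 1)]
        return StepFunction(bp, a * b)

    def threshold(self, minimum: float = 1.0) -> "StepFunction":
        """Indicator step function of f >= minimum."""
        return StepFunction(self.bp, (self.values >= minimum).astype(np.float64))


def _dedupe_sorted(a: np.ndarray) -> np.ndarray:
    if a.size <= 1:
        return a
    keep = np.empty(a.size, dtype=bool)
    keep[0] = True
    np.not_equal(a[1:], a[:-1], out=keep[1:])
    return a[keep]


def _sorted_union(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Union of two sorted arrays (cheaper than hash-based np.union1d)."""
    c = np.concatenate([a, b])
    c.sort(kind="stable")
    return _dedupe_sorted(c)


def coverage_step(length: int, starts: np.ndarray, ends: np.ndarray, values: np.ndarray) -> StepFunction:
    """Step function from sorted, non-overlapping value intervals; gaps are 0."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    values = np.asarray(values, dtype=np.float64)
    if starts.size == 0:
        return StepFunction(np.array([0, length]), np.array([0.0]))
    # sorted non-overlapping intervals interleave to an already-sorted array
    inter = np.empty(2 * starts.size, dtype=np.int64)
    inter[0::2] = starts
    inter[1::2] = ends
    bp = _dedupe_sorted(np.concatenate([[0], inter, [length]]))
    left = bp[:-1]
    idx = np.searchsorted(starts, left, side="right") - 1
    vals = np.zeros(left.size)
    inside = (idx >= 0) & (left < ends[np.clip(idx, 0, None)])
    vals[inside] = values[idx[inside]]
    return StepFunction(bp, vals)


def indicator_step(length: int, starts: np.ndarray, ends: np.ndarray, *, inside: float = 1.0, outside: float = 0.0) -> StepFunction:
    """Indicator of merged intervals (e.g. a mask, or its complement)."""
    s, e = merge_intervals(np.asarray(starts), np.asarray(ends))
    ones = np.full(s.size, 1.0)
    f = coverage_step(length, s, e, ones)
    return StepFunction(f.bp, np.where(f.values > 0, inside, outside))
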