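"""Set-bounded data containers: boxes, polyhedra, measurement and input sequences.

Measurements are intervals (or, generally, polyhedra) guaranteed to contain
the unknown true output at each measured time index; inputs are likewise
given per index as boxes (width zero when known exactly).  Parameter and
state prior knowledge enters as boxes over named variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .poly import Interval


class Box:
    """Axis-aligned box: per-variable interval bounds.

    Zero-width dimensions are allowed and represent exactly known values.
    """

    def __init__(self, bounds: Mapping[str, Interval | Tuple[float, float]]):
        self.bounds: Dict[str, Interval] = {}
        for name, iv in bounds.items():
            if not isinstance(iv, Interval):
                iv = Interval(float(iv[0]), float(iv[1]))
            self.bounds[name] = iv

    @property
    def variables(self) -> Tuple[str, ...]:
        return tuple(self.bounds)

    def __getitem__(self, name: str) -> Interval:
        return self.bounds[name]

    def __contains__(self, name: str) -> bool:
        return name in self.bounds

    def __iter__(self):
        return iter(self.bounds.items())

    def contains_point(self, point: Mapping[str, float],
                       tol: float = 0.0) -> bool:
        return all(iv.contains(point[v], tol) for v, iv in self.bounds.items())

    def midpoint(self) -> Dict[str, float]:
        return {v: iv.midpoint for v, iv in self.bounds.items()}

    def sample(self, rng: np.random.Generator, n: int = 1
               ) -> List[Dict[str, float]]:
        names = list(self.bounds)
        lo = np.array([self.bounds[v].lower for v in names])
        hi = np.array([self.bounds[v].upper for v in names])
        pts = rng.uniform(size=(n, len(names))) * (hi - lo) + lo
        return [dict(zip(names, row)) for row in pts]

    def intersect(self, other: "Box") -> "Box | None":
        if set(self.bounds) != set(other.bounds):
            raise ValueError("boxes over different variable sets")
        out = {}
        for v, iv in self.bounds.items():
            cap = iv.intersect(other.bounds[v])
            if cap is None:
                return None
            out[v] = cap
        return Box(out)

    def replace(self, name: str, iv: Interval) -> "Box":
        new = dict(self.bounds)
        new[name] = iv
        return Box(new)

    def subset_of(self, other: "Box", tol: float = 0.0) -> bool:
        return all(other.bounds[v].lower - tol <= iv.lower
                   and iv.upper <= other.bounds[v].upper + tol
                   for v, iv in self.bounds.items())

    def __repr__(self) -> str:
        inner = ", ".join(f"{v}:[{iv.lower:g},{iv.upper:g}]"
                          for v, iv in self.bounds.items())
        return f"Box({inner})"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Box):
            return NotImplemented
        return self.bounds == other.bounds


@dataclass
class PolyhedralSet:
    """Polyhedron {z : A z <= b} over named variables."""

    variables: Tuple[str, ...]
    A: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.b = np.asarray(self.b, dtype=float).ravel()
        if self.A.shape[0] != self.b.shape[0]:
            raise ValueError("A and b have inconsistent row counts")
        if self.A.shape[1] != len(self.variables):
            raise ValueError("A column count != number of variables")

    @classmethod
    def from_box(cls, box: Box) -> "PolyhedralSet":
        names = box.variables
        n = len(names)
        A = np.vstack([np.eye(n), -np.eye(n)])
        b = np.concatenate([[box[v].upper for v in names],
                            [-box[v].lower for v in names]])
        return cls(names, A, b)

    def contains_point(self, point: Mapping[str, float],
                       tol: float = 0.0) -> bool:
        z = np.array([point[v] for v in self.variables])
        return bool(np.all(self.A @ z <= self.b + tol))


@dataclass
class MeasurementSequence:
    """Set-bounded measurements 𝒴 at strictly increasing time indexes."""

    # index -> {observable -> Interval}  (interval measurements), or a
    # PolyhedralSet over the measured observables at that index.
    sets: Dict[int, "Dict[str, Interval] | PolyhedralSet"] = field(
        default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {int(k): v for k, v in sorted(self.sets.items())}

    @property
    def indexes(self) -> List[int]:
        return sorted(self.sets)

    @property
    def window(self) -> Tuple[int, int]:
        idx = self.indexes
        if not idx:
            raise ValueError("empty measurement sequence")
        return idx[0], idx[-1]

    def observables_at(self, k: int) -> Tuple[str, ...]:
        s = self.sets[k]
        if isinstance(s, PolyhedralSet):
            return s.variables
        return tuple(s)

    def restrict(self, indexes: Sequence[int]) -> "MeasurementSequence":
        return MeasurementSequence({k: self.sets[k] for k in indexes})

    def contains(self, k: int, values: Mapping[str, float],
                 tol: float = 0.0) -> bool:
        s = self.sets[k]
        if isinstance(s, PolyhedralSet):
            return s.contains_point(values, tol)
        return all(iv.contains(values[obs], tol) for obs, iv in s.items())

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class InputSequence:
    """Per-index input boxes 𝒰 (width 0 when the input is known exactly)."""

    sets: Dict[int, Dict[str, Interval]] = field(default_factory=dict)
    default: Dict[str, Interval] = field(default_factory=dict)

    @classmethod
    def constant(cls, values: Mapping[str, float]) -> "InputSequence":
        return cls(sets={}, default={u: Interval(float(v), float(v))
                                     for u, v in values.items()})

    def at(self, k: int) -> Dict[str, Interval]:
        return self.sets.get(k, self.default)

    def value_at(self, k: int) -> Dict[str, float]:
        """Midpoints (exact values for width-0 inputs), for simulation."""
        return {u: iv.midpoint for u, iv in self.at(k).items()}
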