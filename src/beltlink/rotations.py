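"""Deterministic quasi-uniform rotation sets for exhaustive SO(3) scanning.

The super-Fibonacci spiral places N unit quaternions quasi-uniformly on the
3-sphere by a closed-form irrational winding — no randomness, so a given set
size always yields the identical rotation set, which makes pose scans
bitwise reproducible.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["RotationSet", "super_fibonacci", "rotation_set"]

_PHI = math.sqrt(2.0)
_PSI = 1.533751168755204288118041  # positive root of x^4 = x + 4


def super_fibonacci(n: int) -> np.ndarray:
    """N quasi-uniform unit quaternions (scalar-last, shape (n, 4))."""
    if n < 1:
        raise ValueError("need at least one rotation")
    i = np.arange(n, dtype=float)
    s = i + 0.5
    t = s / n
    d = 2.0 * math.pi * s
    r = np.sqrt(t)
    big_r = np.sqrt(1.0 - t)
    alpha = d / _PHI
    beta = d / _PSI
    q = np.column_stack(
        [r * np.sin(alpha), r * np.cos(alpha), big_r * np.sin(beta), big_r * np.cos(beta)]
    )
    return q


def quaternion_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrices for quaternions (x, y, z, w), shape (..., 3, 3)."""
    q = np.asarray(q, dtype=float)
    x, y, z, w = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    m = np.empty(q.shape[:-1] + (3, 3))
    m[..., 0, 0] = 1 - 2 * (y * y + z * z)
    m[..., 0, 1] = 2 * (x * y - z * w)
    m[..., 0, 2] = 2 * (x * z + y * w)
    m[..., 1, 0] = 2 * (x * y + z * w)
    m[..., 1, 1] = 1 - 2 * (x * x + z * z)
    m[..., 1, 2] = 2 * (y * z - x * w)
    m[..., 2, 0] = 2 * (x * z - y * w)
    m[..., 2, 1] = 2 * (y * z + x * w)
    m[..., 2, 2] = 1 - 2 * (x * x + y * y)
    return m


def max_nearest_neighbor_angle(quats: np.ndarray) -> float:
    """Largest rotation angle (radians) from any set member to its nearest
    neighbour — a proxy for the angular gap of the covering."""
    dots = np.abs(quats @ quats.T)
    np.fill_diagonal(dots, -1.0)
    nearest = dots.max(axis=1).clip(-1.0, 1.0)
    # rotation angle between quaternions p, q is 2·arccos(|p·q|)
    return float((2.0 * np.arccos(nearest)).max())


@dataclass(frozen=True)
class RotationSet:
    """A fixed set of rotations with its reported angular gap."""

    quaternions: np.ndarray
    matrices: np.ndarray
    max_gap: float

    def __len__(self) -> int:
        return len(self.quaternions)


def rotation_set(n: int) -> RotationSet:
    q = super_fibonacci(n)
    return RotationSet(
        quaternions=q,
        matrices=quaternion_to_matrix(q),
        max_gap=max_nearest_neighbor_angle(q) if n > 1 else 2.0 * math.pi,
    )
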