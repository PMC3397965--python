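"""Small geometric primitives: rotations, dihedrals, optimal superposition."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation


@dataclass(frozen=True)
class RigidTransform:
    """y = R @ x + t, rotation applied about the origin."""

    rotation: np.ndarray  # (3,3)
    translation: np.ndarray  # (3,)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _cross3(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # np.cross has high call overhead for single 3-vectors
    return np.array([a[1] * b[2] - a[2] * b[1],
                     a[2] * b[0] - a[0] * b[2],
                     a[0] * b[1] - a[1] * b[0]])


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation of `angle` radians about `axis`."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("rotation axis must be nonzero")
    x, y, z = axis / n
    c, s = np.cos(angle), np.sin(angle)
    t = 1.0 - c
    return np.array([
        [t * x * x + c, t * x * y - s * z, t * x * z + s * y],
        [t * x * y + s * z, t * y * y + c, t * y * z - s * x],
        [t * x * z - s * y, t * y * z + s * x, t * z * z + c],
    ])


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in radians."""
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))


def dihedral_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Signed torsion a-b-c-d in radians, IUPAC convention, range (-pi, pi]."""
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = _cross3(b1, b2)
    n2 = _cross3(b2, b3)
    m1 = _cross3(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.arctan2(y, x))


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of `mobile` onto `reference`.

    Returns the transform and the residual RMSD. Proper rotations only.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("superposition requires matched (N, 3) coordinate arrays")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    rot, rssd = Rotation.align_vectors(reference - rc, mobile - mc)
    rmsd = rssd / np.sqrt(len(mobile))
    rmat = rot.as_matrix()
    return RigidTransform(rmat, rc - rmat @ mc), float(rmsd)


def rmsd_between(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD without fitting."""
    d = np.asarray(a, float) - np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def random_unit_quaternion(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)


def quaternion_to_matrix(q: np.ndarray) -> np.ndarray:
    # scipy uses (x, y, z, w) ordering; we store (w, x, y, z)
    w, x, y, z = q
    return Rotation.from_quat([x, y, z, w]).as_matrix()


def small_random_rotation(rng: np.random.Generator, max_angle: float) -> np.ndarray:
    """Uniform-axis rotation with angle drawn uniformly from [-max_angle, max_angle]."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    return rotation_about_axis(axis, rng.uniform(-max_angle, max_angle))


def compose_quaternion(q: np.ndarray, rmat: np.ndarray) -> np.ndarray:
    """Return quaternion of rmat @ R(q), normalized, (w, x, y, z) ordering."""
    w, x, y, z = q
    r = Rotation.from_matrix(rmat) * Rotation.from_quat([x, y, z, w])
    x, y, z, w = r.as_quat()
    out = np.array([w, x, y, z])
    return out / np.linalg.norm(out)
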