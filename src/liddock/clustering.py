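"""Conformational similarity metric and two-pass leader clustering.

Similarity between two conformations of the same molecule combines atom-type
compatibility (over hydrogen-bond classes donor / acceptor / both / nonpolar)
with Gaussian spatial proximity. For atom i of conformation A against all
atoms j of conformation B,

    D_i(A|B) = sum_j g(d_ij) * c(class_i, class_j),
    g(d) = exp(-d^2 / (2 sigma^2)) for d <= cutoff, 0 beyond,

with sigma fixed by g(cutoff) = proximity_threshold. The similarity is the
continuous Tanimoto coefficient between descriptor vectors; the default
operand pairing compares the self-descriptor D(A|A) against the cross
descriptor D(A|B), symmetrized by averaging the two directions (the
"cross" convention comparing D(A|B) against D(B|A) is selectable).
Conformations are grouped by a two-pass leader algorithm at threshold 0.85.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import ClassificationError, Structure

_CLASS_ORDER = ("donor", "acceptor", "both", "nonpolar")

#: Default atom-type compatibility. Same type = 1, donor vs acceptor = 0,
#: a dual (both) atom matches either polar role, nonpolar matches nothing polar.
DEFAULT_COMPATIBILITY = {
    ("donor", "donor"): 1.0, ("acceptor", "acceptor"): 1.0,
    ("both", "both"): 1.0, ("nonpolar", "nonpolar"): 1.0,
    ("donor", "acceptor"): 0.0, ("donor", "both"): 1.0,
    ("donor", "nonpolar"): 0.0, ("acceptor", "both"): 1.0,
    ("acceptor", "nonpolar"): 0.0, ("both", "nonpolar"): 0.0,
}


def compatibility_matrix(table: dict | None = None) -> np.ndarray:
    """4x4 symmetric compatibility matrix over the class order (d, a, b, n)."""
    table = table or DEFAULT_COMPATIBILITY
    m = np.empty((4, 4))
    for i, ci in enumerate(_CLASS_ORDER):
        for j, cj in enumerate(_CLASS_ORDER):
            v = table.get((ci, cj), table.get((cj, ci)))
            if v is None:
                raise ValueError(f"no compatibility entry for ({ci}, {cj})")
            m[i, j] = v
    if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 1.0):
        raise ValueError("compatibility matrix must be symmetric with unit diagonal")
    if m[0, 1] != 0.0:
        raise ValueError("donor-acceptor compatibility must be 0")
    return m


@dataclass(frozen=True)
class ProximityParams:
    """Gaussian proximity parameters (cutoff in A, threshold dimensionless)."""

    cutoff: float = 2.5
    proximity_threshold: float = 0.1

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if not 0 < self.proximity_threshold < 1:
            raise ValueError("proximity threshold must lie in (0, 1)")

    @property
    def sigma(self) -> float:
        return self.cutoff / np.sqrt(-2.0 * np.log(self.proximity_threshold))


def _class_indices(structure: Structure) -> np.ndarray:
    out = np.empty(structure.n_atoms, dtype=int)
    for i, atom in enumerate(structure.atoms):
        if atom.hbond_class is None:
            raise ClassificationError(
                f"atom {atom.name} unclassified; run assign_atom_classes first")
        out[i] = _CLASS_ORDER.index(atom.hbond_class)
    return out


def descriptor_vector(structure: Structure, coords_a: np.ndarray,
                      coords_b: np.ndarray,
                      params: ProximityParams | None = None,
                      compat: np.ndarray | None = None) -> np.ndarray:
    """Per-atom descriptors D_i(A|B) of conformation A against conformation B."""
    params = params or ProximityParams()
    compat = compatibility_matrix() if compat is None else compat
    cls = _class_indices(structure)
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    dist = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    g = np.exp(-dist ** 2 / (2.0 * params.sigma ** 2))
    g[dist > params.cutoff] = 0.0
    return (g * compat[cls][:, cls]).sum(axis=1)


def atom_descriptor(atom_index: int, structure: Structure,
                    coords_a: np.ndarray, coords_b: np.ndarray,
                    params: ProximityParams | None = None,
                    compat: np.ndarray | None = None) -> float:
    """Descriptor of one atom of A summed over all atoms of B (>= 0)."""
    return float(descriptor_vector(structure, coords_a, coords_b,
                                   params, compat)[atom_index])


def _tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    ab = float(np.dot(a, b))
    denom = float(np.dot(a, a) + np.dot(b, b)) - ab
    if denom == 0.0:
        return 1.0  # both descriptor vectors identically zero
    return ab / denom


def tanimoto_similarity(structure: Structure, coords_a: np.ndarray,
                        coords_b: np.ndarray,
                        params: ProximityParams | None = None,
                        compat: np.ndarray | None = None,
                        convention: str = "self-cross") -> float:
    """Continuous Tanimoto similarity of two conformations, in [0, 1].

    Symmetric; exactly 1 for identical conformations; 0 when the
    conformations share no atoms within the proximity cutoff.
    """
    if np.shape(coords_a) != np.shape(coords_b):
        raise ValueError("conformations must share one atom set (pairing error)")
    if convention == "self-cross":
        daa = descriptor_vector(structure, coords_a, coords_a, params, compat)
        dab = descriptor_vector(structure, coords_a, coords_b, params, compat)
        dbb = descriptor_vector(structure, coords_b, coords_b, params, compat)
        dba = descriptor_vector(structure, coords_b, coords_a, params, compat)
        return 0.5 * (_tanimoto(daa, dab) + _tanimoto(dbb, dba))
    if convention == "cross":
        dab = descriptor_vector(structure, coords_a, coords_b, params, compat)
        dba = descriptor_vector(structure, coords_b, coords_a, params, compat)
        return _tanimoto(dab, dba)
    raise ValueError(f"unknown Tanimoto convention {convention!r}")


@dataclass
class Cluster:
    center: int               # index of the founding member
    members: list[int] = field(default_factory=list)


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    threshold: float

    def labels(self, n: int) -> np.ndarray:
        lab = np.full(n, -1, dtype=int)
        for ci, cl in enumerate(self.clusters):
            for m in cl.members:
                lab[m] = ci
        return lab

    @property
    def sizes(self) -> list[int]:
        return [len(c.members) for c in self.clusters]


def _leader_pass(order: list[int], sim: np.ndarray, threshold: float) -> list[Cluster]:
    clusters: list[Cluster] = []
    for idx in order:
        best_cluster, best_sim = None, -1.0
        for cl in clusters:
            s = max(sim[idx, m] for m in cl.members)
            if s > best_sim + 1e-15:  # ties keep the earlier-founded cluster
                best_cluster, best_sim = cl, s
        if best_cluster is not None and best_sim > threshold:
            best_cluster.members.append(idx)
        else:
            clusters.append(Cluster(center=idx, members=[idx]))
    return clusters


def similarity_matrix(structure: Structure, conformations,
                      params: ProximityParams | None = None,
                      compat: np.ndarray | None = None,
                      convention: str = "self-cross") -> np.ndarray:
    n = len(conformations)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = tanimoto_similarity(
                structure, conformations[i], conformations[j],
                params, compat, convention)
    return sim


def cluster_conformations(structure: Structure, conformations,
                          threshold: float = 0.85,
                          params: ProximityParams | None = None,
                          compat: np.ndarray | None = None,
                          convention: str = "self-cross") -> ClusterSet:
    """Two-pass leader clustering of conformations at a similarity threshold.

    First pass assigns each conformation (in input order) to the cluster
    holding its most similar existing member when that similarity exceeds the
    threshold, founding a new cluster otherwise. Members are then reordered
    largest-cluster-first and the pass repeats once. Output clusters are
    sorted by size, largest first; each cluster's founding member is its
    center.
    """
    n = len(conformations)
    if n == 0:
        raise ValueError("clustering requires at least one conformation")
    sim = similarity_matrix(structure, conformations, params, compat, convention)
    first = _leader_pass(list(range(n)), sim, threshold)
    first.sort(key=lambda c: -len(c.members))
    reordered = [m for cl in first for m in cl.members]
    second = _leader_pass(reordered, sim, threshold)
    second.sort(key=lambda c: -len(c.members))
    return ClusterSet(second, threshold)
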