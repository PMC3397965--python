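"""Seeded generators of toy systems with known ground truth.

Every generator is a pure function of its spec (same seed, same output,
bit for bit) and plants a quantity the corresponding analysis operation
must recover exactly: a low-energy pose for the docking search, hydrogen-
bond occupancies and per-residue fluctuation amplitudes for the trajectory
analyses, cluster memberships for the similarity clustering, and closed-
form normal-mode frequencies for the entropy and minimization machinery.

Toy receptors are smooth attraction wells expressed through the package's
own nonbonded forms, not real amino-acid geometry: sufficient to exercise
sampling and scoring, and nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis import HBondCriteria, Trajectory
from .clustering import ProximityParams, similarity_matrix
from .energy import EnergyParams, total_docking_energy
from .geometry import rotation_about_axis
from .remc import PoseState, realize_pose
from .structure import (Atom, HarmonicBond, Residue, Structure, Torsion,
                        assign_atom_classes)


class GenerationError(ValueError):
    """Raised when a spec requests geometry that cannot be planted."""


# -- toy receptor-lid complex ----------------------------------------------

@dataclass(frozen=True)
class ToyComplexSpec:
    n_pockets: int = 3
    lid_length: int = 5          # residues (one CA pseudo-atom each)
    anchor_seq_id: int = 1
    rng_seed: int = 0
    pocket_depths: tuple[float, ...] = (-4.0, -4.0, -4.0)

    def __post_init__(self) -> None:
        if self.lid_length < 2:
            raise ValueError("lid needs at least 2 residues")
        if len(self.pocket_depths) != self.n_pockets:
            raise ValueError("one pocket depth per pocket required")
        if any(d >= 0 for d in self.pocket_depths):
            raise ValueError("pocket depths must be negative (attractive)")


_BOND_LENGTH = 1.5
_BOND_ANGLE = np.deg2rad(109.47)


def _chain_coords(n: int) -> np.ndarray:
    """Extended zigzag chain in the xy plane, first atom at the origin."""
    coords = np.zeros((n, 3))
    direction = np.array([1.0, 0.0, 0.0])
    for i in range(1, n):
        if i == 1:
            step = direction
        else:
            # alternate up/down by the tetrahedral angle, staying in-plane
            sign = 1.0 if i % 2 == 0 else -1.0
            ang = sign * (np.pi - _BOND_ANGLE)
            rot = rotation_about_axis(np.array([0.0, 0.0, 1.0]), ang)
            step = rot @ (coords[i - 1] - coords[i - 2])
            step /= np.linalg.norm(step)
        coords[i] = coords[i - 1] + _BOND_LENGTH * step
    return coords


def _make_lid(lid_length: int, anchor_seq_id: int) -> Structure:
    coords = _chain_coords(lid_length)
    residues = [Residue("GLY", i + 1, "L",
                        [Atom("CA", "C", coords[i], epsilon=0.2, sigma=3.2)])
                for i in range(lid_length)]
    bonds = [(i, i + 1) for i in range(lid_length - 1)]
    torsions = [Torsion(i, i + 1, i + 2, i + 3, rotatable=True,
                        barrier=1.0, periodicity=3, phase=np.pi)
                for i in range(lid_length - 3)]
    lid = Structure(residues, bonds, torsions,
                    metadata={"anchor": (anchor_seq_id, "CA")})
    return assign_atom_classes(lid)


def make_toy_complex(spec: ToyComplexSpec | None = None
                     ) -> tuple[Structure, Structure, PoseState]:
    """(rigid receptor, flexible anchored lid, known low-energy pose).

    The receptor carries `n_pockets` attraction sites placed at the
    Lennard-Jones optimum distance from evenly spaced lid atoms of a
    reference pose; that pose is returned as `known_minimum` and its energy
    under default docking parameters beats uniformly random poses. Pocket
    atom indices are flagged in ``receptor.metadata["pockets"]``.
    """
    spec = spec or ToyComplexSpec()
    lid = _make_lid(spec.lid_length, spec.anchor_seq_id)
    anchor_idx = lid.atom_index(spec.anchor_seq_id, "CA")
    n_tors = len(lid.rotatable_torsions())
    known = PoseState(translation=lid.get_coords()[anchor_idx],
                      orientation=np.array([1.0, 0.0, 0.0, 0.0]),
                      torsions=np.full(n_tors, np.pi),
                      anchor=(spec.anchor_seq_id, "CA"))
    ref_coords = realize_pose(known, lid)
    # target lid atoms: evenly spread over the chain, skipping the anchor
    candidates = [i for i in range(spec.lid_length) if i != anchor_idx]
    picks = np.linspace(0, len(candidates) - 1, spec.n_pockets)
    targets = [candidates[int(round(p))] for p in picks]
    if len(set(targets)) != spec.n_pockets:
        raise GenerationError("lid too short for the requested pocket count")
    pocket_res = []
    normal = np.array([0.0, 0.0, 1.0])  # out of the chain plane
    for k, (t, depth) in enumerate(zip(targets, spec.pocket_depths)):
        eps_p = -float(depth)
        sigma_pair = 3.2
        r_min = 2.0 ** (1.0 / 6.0) * sigma_pair
        pos = ref_coords[t] + r_min * normal
        pocket_res.append(Residue("ALA", k + 1, "R",
                                  [Atom("CA", "C", pos, epsilon=eps_p,
                                        sigma=3.2)]))
    receptor = Structure(pocket_res,
                         metadata={"pockets": list(range(spec.n_pockets)),
                                   "pocket_targets": targets,
                                   "rng_seed": spec.rng_seed})
    assign_atom_classes(receptor)
    # polish the constructed pose into a true local minimum of the full
    # many-body energy so the planted optimum is unambiguous
    known = _polish_pose(receptor, lid, known)
    return receptor, lid, known


def _polish_pose(receptor: Structure, lid: Structure,
                 pose: PoseState) -> PoseState:
    from dataclasses import replace as _replace

    from scipy.optimize import minimize as _min
    from scipy.spatial.transform import Rotation

    params = EnergyParams()
    n_tors = len(pose.torsions)
    q0 = pose.orientation

    def build(x):
        rv = Rotation.from_rotvec(x[:3])
        w, xx, yy, zz = q0
        qx, qy, qz, qw = (rv * Rotation.from_quat([xx, yy, zz, w])).as_quat()
        q = np.array([qw, qx, qy, qz])
        q /= np.linalg.norm(q)
        return _replace(pose, orientation=q, torsions=np.array(x[3:]),
                        energy=None)

    def fun(x):
        p = build(x)
        return total_docking_energy(lid, receptor, params,
                                    lid_coords=realize_pose(p, lid)).total

    x0 = np.concatenate([np.zeros(3), pose.torsions])
    # deterministic multistart: the constructed pose plus torsion kinks and
    # a flip about the chain axis, each refined by Nelder-Mead
    starts = [x0]
    for delta in (-1.0, 1.0):
        x = x0.copy()
        x[3:] += delta
        starts.append(x)
    flip = x0.copy()
    flip[0] += np.pi
    starts.append(flip)
    best_x, best_f = x0, fun(x0)
    for s in starts:
        res = _min(fun, s, method="Nelder-Mead",
                   options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-12})
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun
    return build(best_x)


def random_poses(lid: Structure, anchor_position: np.ndarray, n: int,
                 seed: int) -> list[PoseState]:
    """Uniformly random orientations/torsions about the anchor (reference grid)."""
    rng = np.random.default_rng(seed)
    anchor = lid.metadata["anchor"]
    n_tors = len(lid.rotatable_torsions())
    out = []
    for _ in range(n):
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        out.append(PoseState(anchor_position, q,
                             rng.uniform(-np.pi, np.pi, size=n_tors), anchor))
    return out


def grid_search_optimum(receptor: Structure, lid: Structure,
                        params: EnergyParams | None = None,
                        n_orientation: int = 10, n_torsion: int = 8
                        ) -> tuple[PoseState, float]:
    """Brute-force pose optimum over an orientation x torsion grid.

    Independent reference for the stochastic search: enumerates Euler
    angles (n_orientation each) and torsion values (n_torsion each).
    """
    from scipy.spatial.transform import Rotation
    params = params or EnergyParams()
    anchor = lid.metadata["anchor"]
    ai = lid.atom_index(*anchor)
    anchor_pos = lid.get_coords()[ai]
    n_tors = len(lid.rotatable_torsions())
    angles = np.linspace(-np.pi, np.pi, n_orientation, endpoint=False)
    tors_grid = np.linspace(-np.pi, np.pi, n_torsion, endpoint=False)
    best_pose, best_e = None, np.inf
    tors_sets = [np.array(t) for t in
                 np.stack(np.meshgrid(*([tors_grid] * n_tors)),
                          axis=-1).reshape(-1, n_tors)] if n_tors else [np.array([])]
    for a in angles:
        for b in np.linspace(0, np.pi, max(n_orientation // 2, 2)):
            for c in angles:
                x, y, z, w = Rotation.from_euler("zyz", [a, b, c]).as_quat()
                q = np.array([w, x, y, z])
                for tors in tors_sets:
                    pose = PoseState(anchor_pos, q, tors, anchor)
                    e = total_docking_energy(
                        lid, receptor, params,
                        lid_coords=realize_pose(pose, lid)).total
                    if e < best_e:
                        best_pose, best_e = pose, e
    return best_pose, float(best_e)


# -- planted trajectories --------------------------------------------------

@dataclass(frozen=True)
class PlantedTrajectorySpec:
    n_frames: int = 200
    frame_interval: float = 2.0  # ps
    planted_pairs: tuple = ()    # ((donor seq_id, name), (acceptor seq_id, name), occupancy)
    fluctuation_amplitudes: tuple = ()  # (seq_id, amplitude A)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        for *_, occ in self.planted_pairs:
            if not 0.0 <= occ <= 1.0:
                raise ValueError("occupancy fractions must lie in [0, 1]")


def make_synthetic_trajectory(base: Structure,
                              spec: PlantedTrajectorySpec) -> Trajectory:
    """Trajectory with exact planted H-bond occupancies and RMSF amplitudes.

    For each planted (donor, acceptor, occupancy) the acceptor atom is placed
    each frame either inside the default hydrogen-bond criterion (2.9 A,
    collinear) or well outside it (5.5 A), so that exactly
    round(occupancy * n_frames) frames qualify. Residues with planted
    fluctuation amplitudes are jittered isotropically about the base
    coordinates (per-component sigma = amplitude / sqrt(3)); everything else
    stays static, so frames share one coordinate frame.
    """
    rng = np.random.default_rng(spec.rng_seed)
    base_coords = base.get_coords()
    crit = HBondCriteria()
    # resolve planted atoms and per-pair qualifying frames
    planted = []
    used_acceptors = set()
    for (dsq, dname), (asq, aname), occ in spec.planted_pairs:
        di = base.atom_index(dsq, dname)
        ai = base.atom_index(asq, aname)
        if ai in used_acceptors:
            raise GenerationError(
                "an acceptor atom cannot serve two planted pairs")
        used_acceptors.add(ai)
        n_on = int(round(occ * spec.n_frames))
        on_frames = set(rng.permutation(spec.n_frames)[:n_on].tolist())
        # direction from donor through its hydrogen if one exists
        hyd = [k for k, a in enumerate(base.atoms)
               if a.element == "H"
               and np.linalg.norm(base_coords[k] - base_coords[di]) <= 1.25]
        planted.append((di, ai, hyd[0] if hyd else None, on_frames))
    fluct = {}
    for seq_id, amp in spec.fluctuation_amplitudes:
        fluct[seq_id] = float(amp)
    override_atoms = {ai for _, ai, _, _ in planted}
    frames = []
    for fi in range(spec.n_frames):
        coords = base_coords.copy()
        idx = 0
        for res in base.residues:
            amp = fluct.get(res.seq_id, 0.0)
            for k in range(len(res.atoms)):
                if amp > 0 and (idx + k) not in override_atoms:
                    coords[idx + k] += rng.normal(
                        scale=amp / np.sqrt(3.0), size=3)
            idx += len(res.atoms)
        for di, ai, hi, on_frames in planted:
            if hi is not None:
                u = coords[hi] - coords[di]
            else:
                # heavy-atom fallback: place the acceptor anti to the donor's
                # antecedent so the fallback angle criterion reads 180 degrees
                heavy = [k for k, a in enumerate(base.atoms)
                         if a.is_heavy and k != di
                         and np.linalg.norm(base_coords[k] - base_coords[di]) < 1.8]
                u = (coords[di] - coords[heavy[0]] if heavy
                     else np.array([1.0, 0.0, 0.0]))
            nu = np.linalg.norm(u)
            if nu == 0:
                raise GenerationError("degenerate donor-hydrogen geometry")
            u = u / nu
            dist = 2.9 if fi in on_frames else crit.max_distance + 2.0
            coords[ai] = coords[di] + dist * u
        frames.append(coords)
    times = np.arange(spec.n_frames) * spec.frame_interval
    if spec.n_frames == 1:
        times = np.array([0.0])
    return Trajectory(base.copy(), frames, times)


# -- planted conformer sets ------------------------------------------------

@dataclass(frozen=True)
class PlantedConformerSpec:
    k_clusters: int = 3
    members_per_cluster: tuple[int, ...] = (5, 3, 2)
    within_spread: float = 0.25      # A
    between_separation: float = 20.0  # A
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.members_per_cluster) != self.k_clusters:
            raise ValueError("one member count per cluster required")
        if self.between_separation <= self.within_spread:
            raise ValueError("between_separation must exceed within_spread")


def make_planted_conformers(base: Structure, spec: PlantedConformerSpec,
                            threshold: float = 0.85,
                            params: ProximityParams | None = None
                            ) -> tuple[list[np.ndarray], np.ndarray]:
    """(conformations, true labels) with verified planted cluster structure.

    Cluster centers are translates of the base conformation separated by
    `between_separation`; members jitter atoms by `within_spread`. The
    planted structure is verified by exhaustive pairwise similarity: every
    within-cluster similarity must exceed `threshold` and every
    between-cluster similarity must fall below it, else a GenerationError.
    """
    params = params or ProximityParams()
    rng = np.random.default_rng(spec.rng_seed)
    base_coords = base.get_coords()
    confs, labels = [], []
    for c in range(spec.k_clusters):
        center = base_coords + np.array([c * spec.between_separation, 0.0, 0.0])
        for _ in range(spec.members_per_cluster[c]):
            jitter = rng.normal(scale=spec.within_spread / np.sqrt(3.0),
                                size=base_coords.shape)
            confs.append(center + jitter)
            labels.append(c)
    labels = np.array(labels)
    sim = similarity_matrix(base, confs, params)
    same = labels[:, None] == labels[None, :]
    off_diag = ~np.eye(len(labels), dtype=bool)
    within = sim[same & off_diag]
    between = sim[~same]
    if len(within) and within.min() <= threshold:
        raise GenerationError(
            f"within-cluster similarity {within.min():.3f} not above "
            f"threshold {threshold}; reduce within_spread")
    if len(between) and between.max() > threshold:
        raise GenerationError(
            f"between-cluster similarity {between.max():.3f} above threshold; "
            f"increase between_separation")
    return confs, labels


# -- harmonic systems ------------------------------------------------------

def make_harmonic_system(force_constants, masses,
                         bonds: list[tuple[int, int]] | None = None,
                         r0: float = 1.5) -> Structure:
    """Structure with purely quadratic bond terms and analytic normal modes.

    `force_constants[k]` (kcal/mol/A^2) belongs to `bonds[k]`; bonds default
    to the consecutive chain (i, i+1). Atoms are placed at their equilibrium
    separations, so the analytic Hessian at the input geometry is exactly
    sum_k k_b (u u^T) over bond unit vectors u. Mode angular frequencies in
    internal units sqrt(kcal/mol/amu)/A are stored in
    ``metadata["mode_frequencies"]`` (nonzero modes, ascending).
    """
    force_constants = [float(k) for k in np.atleast_1d(force_constants)]
    masses = [float(m) for m in np.atleast_1d(masses)]
    if any(k <= 0 for k in force_constants) or any(m <= 0 for m in masses):
        raise ValueError("force constants and masses must be positive")
    n = len(masses)
    if bonds is None:
        bonds = [(i, i + 1) for i in range(n - 1)]
    if len(bonds) != len(force_constants):
        raise ValueError("one force constant per bond required")
    # place bonded components as disjoint collinear chains along x,
    # separated by 50 A in y so components do not interact
    adj = {i: [] for i in range(n)}
    for i, j in bonds:
        adj[i].append(j)
        adj[j].append(i)
    coords = np.zeros((n, 3))
    seen = set()
    comp_id = 0
    for start in range(n):
        if start in seen:
            continue
        stack = [start]
        seen.add(start)
        coords[start] = [0.0, 50.0 * comp_id, 0.0]
        order = 0
        while stack:
            node = stack.pop()
            for nb in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    order += 1
                    coords[nb] = coords[node] + [r0, 0.0, 0.0]
                    stack.append(nb)
        comp_id += 1
    residues = [Residue("HRM", i + 1, "A",
                        [Atom(f"A{i + 1}", "X", coords[i], epsilon=0.0,
                              sigma=3.0, mass=masses[i],
                              hbond_class="nonpolar")])
                for i in range(n)]
    harm = [HarmonicBond(i, j, k, r0)
            for (i, j), k in zip(bonds, force_constants)]
    s = Structure(residues, bonds=list(bonds), harmonic_bonds=harm)
    # analytic Hessian at equilibrium: per bond, k * (u u^T) blocks
    hess = np.zeros((3 * n, 3 * n))
    for hb in harm:
        u = (coords[hb.j] - coords[hb.i])
        u /= np.linalg.norm(u)
        block = hb.k * np.outer(u, u)
        si, sj = 3 * hb.i, 3 * hb.j
        hess[si:si + 3, si:si + 3] += block
        hess[sj:sj + 3, sj:sj + 3] += block
        hess[si:si + 3, sj:sj + 3] -= block
        hess[sj:sj + 3, si:si + 3] -= block
    mw = np.repeat(masses, 3)
    evals = np.linalg.eigvalsh(hess / np.sqrt(np.outer(mw, mw)))
    nonzero = np.sort(evals[evals > 1e-9 * max(evals.max(), 1.0)])
    s.metadata["mode_frequencies"] = np.sqrt(nonzero)
    return s
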