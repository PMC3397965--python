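"""Replica-exchange Monte Carlo docking of an anchored flexible lid.

The lid is anchored at one atom (fixed in space, zero displacement under any
move); its degrees of freedom are a rigid-body orientation about the anchor
plus the rotatable torsions. Replicas run independent Metropolis chains on a
temperature ladder and periodically attempt configuration swaps between
adjacent levels. Exact transition-matrix helpers for small discrete state
spaces are provided so the sampling kernel can be validated against the
Boltzmann distribution analytically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .energy import EnergyBreakdown, EnergyParams, total_docking_energy
from .geometry import (compose_quaternion, quaternion_to_matrix,
                       small_random_rotation)
from .structure import SelectionError, Structure, apply_torsions

#: Gas constant in kcal/mol/K.
KB = 0.0019872041


@dataclass(frozen=True)
class TemperatureLadder:
    levels: tuple[float, ...]

    def __post_init__(self) -> None:
        lv = tuple(float(t) for t in self.levels)
        if len(lv) < 1 or any(t <= 0 for t in lv):
            raise ValueError("ladder needs >= 1 positive temperature")
        if any(b <= a for a, b in zip(lv, lv[1:])):
            raise ValueError("ladder temperatures must be strictly increasing")
        object.__setattr__(self, "levels", lv)

    def __len__(self) -> int:
        return len(self.levels)


def make_temperature_ladder(t_min: float, t_max: float, n: int,
                            spacing: str = "arithmetic") -> TemperatureLadder:
    """Ladder of n temperatures from t_min to t_max inclusive.

    "Uniformly distributed" is interpreted as arithmetic spacing; a geometric
    option is available. n = 1 requires t_min == t_max.
    """
    if n < 1:
        raise ValueError("ladder length must be >= 1")
    if t_min > t_max:
        raise ValueError("t_min must be <= t_max")
    if n == 1:
        if t_min != t_max:
            raise ValueError("n=1 ladder requires t_min == t_max")
        return TemperatureLadder((t_min,))
    if spacing == "arithmetic":
        levels = np.linspace(t_min, t_max, n)
    elif spacing == "geometric":
        levels = np.geomspace(t_min, t_max, n)
    else:
        raise ValueError(f"unknown spacing {spacing!r}")
    return TemperatureLadder(tuple(levels))


@dataclass(frozen=True)
class SearchBox:
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, float)
        hi = np.asarray(self.upper, float)
        if lo.shape != (3,) or hi.shape != (3,) or np.any(hi <= lo):
            raise ValueError("search box must have positive extent on each axis")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    def contains(self, coords: np.ndarray) -> bool:
        c = np.atleast_2d(coords)
        return bool(np.all(c >= self.lower) and np.all(c <= self.upper))

    @property
    def volume(self) -> float:
        return float(np.prod(self.upper - self.lower))


def define_search_box(reference: Structure | np.ndarray,
                      cushion: float = 10.0) -> SearchBox:
    """Axis-aligned bounding box of the reference, padded on all six faces."""
    coords = (reference.get_coords() if isinstance(reference, Structure)
              else np.atleast_2d(np.asarray(reference, float)))
    if coords.size == 0:
        raise SelectionError("empty selection for search box")
    return SearchBox(coords.min(axis=0) - cushion, coords.max(axis=0) + cushion)


@dataclass
class PoseState:
    """Anchored-lid pose: orientation about a fixed anchor + torsion vector.

    `translation` is the world position of the anchor atom; it never changes
    under Monte Carlo moves (the anchoring constraint), so the sampled
    variables are the orientation quaternion (w, x, y, z) and the rotatable
    torsion angles in radians.
    """

    translation: np.ndarray
    orientation: np.ndarray
    torsions: np.ndarray
    anchor: tuple[int, str]
    energy: EnergyBreakdown | None = None
    replica_id: int = -1
    temperature_id: int = -1

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, float)
        q = np.asarray(self.orientation, float)
        n = np.linalg.norm(q)
        if abs(n - 1.0) > 1e-9:
            raise ValueError("orientation quaternion must be normalized")
        self.orientation = q / n
        self.torsions = np.asarray(self.torsions, float)


def realize_pose(pose: PoseState, lid: Structure) -> np.ndarray:
    """Cartesian lid coordinates for a pose (anchor exactly at translation)."""
    coords = apply_torsions(lid, pose.torsions)
    ai = lid.atom_index(*pose.anchor)
    rot = quaternion_to_matrix(pose.orientation)
    coords = (coords - coords[ai]) @ rot.T + pose.translation
    coords[ai] = pose.translation  # exact, not up to rounding
    return coords


@dataclass(frozen=True)
class MoveSteps:
    """Maximum move amplitudes (uniform symmetric proposals)."""

    rotation: float = np.deg2rad(4.0)
    torsion: float = np.deg2rad(10.0)
    translation: float = 0.3  # only used for unanchored poses


def propose_move(pose: PoseState, lid: Structure, box: SearchBox | None,
                 steps: MoveSteps, rng: np.random.Generator) -> PoseState | None:
    """Symmetric torsion-space / orientation proposal; None = out-of-box reject.

    The anchor atom never moves; bond lengths and angles are preserved by
    construction (internal-coordinate moves only).
    """
    n_tors = len(pose.torsions)
    if n_tors > 0 and rng.random() < 0.5:
        torsions = pose.torsions.copy()
        k = rng.integers(n_tors)
        torsions[k] = torsions[k] + rng.uniform(-steps.torsion, steps.torsion)
        new = replace(pose, torsions=torsions, energy=None)
    else:
        rot = small_random_rotation(rng, steps.rotation)
        new = replace(pose, orientation=compose_quaternion(pose.orientation, rot),
                      energy=None)
    if box is not None and not box.contains(realize_pose(new, lid)):
        return None
    return new


def metropolis_probability(delta_e: float, t: float) -> float:
    """min(1, exp(-dE / kT)) with k the gas constant in kcal/mol/K."""
    if t <= 0:
        raise ValueError("temperature must be positive")
    if delta_e <= 0:
        return 1.0
    return float(np.exp(-delta_e / (KB * t)))


def metropolis_accept(delta_e: float, t: float, rng: np.random.Generator) -> bool:
    return rng.random() < metropolis_probability(delta_e, t)


def swap_probability(e_i: float, e_j: float, t_i: float, t_j: float) -> float:
    """min(1, exp(dBeta * dE)) with dBeta = 1/kTi - 1/kTj, dE = Ei - Ej."""
    dbeta = 1.0 / (KB * t_i) - 1.0 / (KB * t_j)
    arg = dbeta * (e_i - e_j)
    return 1.0 if arg >= 0 else float(np.exp(arg))


@dataclass
class Replica:
    pose: PoseState
    temperature: float
    energy: float

    def __repr__(self) -> str:  # keep diagnostics readable
        return f"Replica(T={self.temperature:.1f} K, E={self.energy:.3f})"


def swap_attempt(replica_i: Replica, replica_j: Replica,
                 rng: np.random.Generator) -> bool:
    """Attempt a configuration exchange; on success poses swap, temperatures stay."""
    p = swap_probability(replica_i.energy, replica_j.energy,
                         replica_i.temperature, replica_j.temperature)
    if rng.random() < p:
        replica_i.pose, replica_j.pose = replica_j.pose, replica_i.pose
        replica_i.energy, replica_j.energy = replica_j.energy, replica_i.energy
        return True
    return False


@dataclass
class RemcResult:
    cold_poses: list[PoseState]
    cold_energies: np.ndarray
    best_pose: PoseState
    best_energy: float
    acceptance_rates: np.ndarray     # per ladder level
    swap_acceptance: float
    diagnostics: dict = field(default_factory=dict)


def run_remc_docking(receptor: Structure, lid: Structure, params: EnergyParams,
                     ladder: TemperatureLadder, cycles: int,
                     moves_per_cycle: int = 200, swaps_per_cycle: int = 100,
                     seed: int = 0, anchor: tuple[int, str] | None = None,
                     anchor_position: np.ndarray | None = None,
                     box: SearchBox | None = None,
                     steps: MoveSteps | None = None,
                     scale_steps_with_temperature: bool = True,
                     initial_poses: list[PoseState] | None = None) -> RemcResult:
    """Replica-exchange Monte Carlo docking of the anchored lid.

    One replica per ladder level; each cycle runs `moves_per_cycle` Metropolis
    moves per replica followed by `swaps_per_cycle` random adjacent-pair swap
    attempts. The pose held at the coldest level is recorded each cycle.
    Fully reproducible from `seed`. With `scale_steps_with_temperature`
    (default) the angular move amplitudes grow as sqrt(T / T_min), capped at
    pi, so hot replicas explore globally while cold replicas refine locally.
    """
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    steps = steps or MoveSteps()
    rng = np.random.default_rng(seed)
    n_levels = len(ladder)
    if anchor is None:
        anchor = lid.metadata.get("anchor")
        if anchor is None:
            raise ValueError("no anchor given and none in lid metadata")
    anchor = (int(anchor[0]), str(anchor[1]))
    ai = lid.atom_index(*anchor)
    if anchor_position is None:
        anchor_position = lid.get_coords()[ai]
    if box is None:
        box = define_search_box(receptor, cushion=10.0)
    n_tors = len(lid.rotatable_torsions())
    level_steps = []
    for t in ladder.levels:
        if scale_steps_with_temperature:
            f = np.sqrt(t / ladder.levels[0])
            level_steps.append(MoveSteps(
                rotation=min(steps.rotation * f, np.pi),
                torsion=min(steps.torsion * f, np.pi),
                translation=steps.translation))
        else:
            level_steps.append(steps)

    def random_pose() -> PoseState:
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        return PoseState(anchor_position, q,
                         rng.uniform(-np.pi, np.pi, size=n_tors), anchor)

    def pose_energy(pose: PoseState) -> float:
        bd = total_docking_energy(lid, receptor, params,
                                  lid_coords=realize_pose(pose, lid))
        pose.energy = bd
        return bd.total

    replicas: list[Replica] = []
    for level in range(n_levels):
        if initial_poses is not None:
            pose = replace(initial_poses[rng.integers(len(initial_poses))],
                           energy=None)
        else:
            pose = random_pose()
            for _ in range(200):  # keep drawing until inside the box
                if box.contains(realize_pose(pose, lid)):
                    break
                pose = random_pose()
        pose.replica_id = level
        pose.temperature_id = level
        replicas.append(Replica(pose, ladder.levels[level], pose_energy(pose)))

    accepted = np.zeros(n_levels)
    attempted = np.zeros(n_levels)
    swaps_ok = 0
    swaps_tried = 0
    cold_poses: list[PoseState] = []
    cold_energies: list[float] = []
    best_pose, best_energy = None, np.inf

    for _ in range(cycles):
        for level, rep in enumerate(replicas):
            for _ in range(moves_per_cycle):
                attempted[level] += 1
                prop = propose_move(rep.pose, lid, box, level_steps[level], rng)
                if prop is None:
                    continue
                e_new = pose_energy(prop)
                if metropolis_accept(e_new - rep.energy, rep.temperature, rng):
                    accepted[level] += 1
                    rep.pose, rep.energy = prop, e_new
                if rep.energy < best_energy:
                    best_energy = rep.energy
                    best_pose = replace(rep.pose)
        if n_levels > 1:
            for _ in range(swaps_per_cycle):
                i = int(rng.integers(n_levels - 1))
                swaps_tried += 1
                swaps_ok += swap_attempt(replicas[i], replicas[i + 1], rng)
        cold = replicas[0]
        cold_poses.append(replace(cold.pose))
        cold_energies.append(cold.energy)
        if cold.energy < best_energy:
            best_energy, best_pose = cold.energy, replace(cold.pose)

    return RemcResult(
        cold_poses=cold_poses,
        cold_energies=np.array(cold_energies),
        best_pose=best_pose,
        best_energy=float(best_energy),
        acceptance_rates=accepted / np.maximum(attempted, 1),
        swap_acceptance=swaps_ok / swaps_tried if swaps_tried else 0.0,
        diagnostics={"ladder": ladder.levels, "seed": seed},
    )


# -- exact kernels on discrete toy state spaces ----------------------------

def metropolis_kernel_matrix(energies: np.ndarray, t: float) -> np.ndarray:
    """Exact single-temperature Metropolis kernel, uniform proposal."""
    e = np.asarray(energies, float)
    n = len(e)
    kern = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                kern[i, j] = metropolis_probability(e[j] - e[i], t) / (n - 1)
        kern[i, i] = 1.0 - kern[i].sum()
    return kern


def boltzmann_distribution(energies: np.ndarray, t: float) -> np.ndarray:
    e = np.asarray(energies, float)
    w = np.exp(-(e - e.min()) / (KB * t))
    return w / w.sum()


def remc_kernel_matrix(energies: np.ndarray,
                       ladder: TemperatureLadder) -> np.ndarray:
    """Exact joint kernel for L replicas on a discrete state space.

    One step = an independent Metropolis move at every level followed by one
    swap attempt of a uniformly chosen adjacent pair. The stationary
    distribution is the product of the per-level Boltzmann distributions.
    """
    e = np.asarray(energies, float)
    levels = ladder.levels
    move = metropolis_kernel_matrix(e, levels[0])
    for t in levels[1:]:
        move = np.kron(move, metropolis_kernel_matrix(e, t))
    n = len(e)
    L = len(levels)
    dim = n ** L
    swap = np.zeros((dim, dim))

    def decode(idx: int) -> list[int]:
        out = []
        for _ in range(L):
            out.append(idx % n)
            idx //= n
        return out[::-1]

    def encode(states: list[int]) -> int:
        idx = 0
        for s in states:
            idx = idx * n + s
        return idx

    for idx in range(dim):
        states = decode(idx)
        for pair in range(L - 1):
            p_pick = 1.0 / (L - 1)
            p = swap_probability(e[states[pair]], e[states[pair + 1]],
                                 levels[pair], levels[pair + 1])
            swapped = states.copy()
            swapped[pair], swapped[pair + 1] = swapped[pair + 1], swapped[pair]
            swap[idx, encode(swapped)] += p_pick * p
            swap[idx, idx] += p_pick * (1.0 - p)
    return move @ swap


def stationary_distribution(kernel: np.ndarray) -> np.ndarray:
    """Left eigenvector of the kernel for eigenvalue 1, normalized."""
    vals, vecs = np.linalg.eig(kernel.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    v = np.real(vecs[:, k])
    v = np.abs(v)
    return v / v.sum()


def simulate_discrete_remc(energies: np.ndarray, ladder: TemperatureLadder,
                           n_steps: int, seed: int = 0) -> np.ndarray:
    """Empirical per-level state visit frequencies, shape (L, n_states)."""
    e = np.asarray(energies, float)
    n = len(e)
    levels = ladder.levels
    L = len(levels)
    rng = np.random.default_rng(seed)
    states = rng.integers(n, size=L)
    counts = np.zeros((L, n))
    for _ in range(n_steps):
        for lvl in range(L):
            prop = int(rng.integers(n - 1))
            if prop >= states[lvl]:
                prop += 1
            if metropolis_accept(e[prop] - e[states[lvl]], levels[lvl], rng):
                states[lvl] = prop
        if L > 1:
            pair = int(rng.integers(L - 1))
            p = swap_probability(e[states[pair]], e[states[pair + 1]],
                                 levels[pair], levels[pair + 1])
            if rng.random() < p:
                states[pair], states[pair + 1] = states[pair + 1], states[pair]
        counts[np.arange(L), states] += 1
    return counts / n_steps


# -- self-consistent rotamer optimization ----------------------------------

class RotamerError(ValueError):
    """Raised when a residue has no rotamer entries."""


def residue_chi_torsions(structure: Structure, residue_index: int) -> list[int]:
    """Indices (into rotatable torsions) of the chi torsions of one residue.

    A rotatable torsion belongs to a residue when both central-bond atoms are
    atoms of that residue; ordering follows the structure's torsion list.
    """
    atoms = structure.atoms
    out = []
    for k, t in enumerate(structure.rotatable_torsions()):
        if (atoms[t.b].residue_ref == residue_index
                and atoms[t.c].residue_ref == residue_index):
            out.append(k)
    return out


def self_consistent_rotamer_optimization(
        structure: Structure, residue_indices: list[int],
        rotamers: dict[str, list[tuple[float, ...]]],
        energy_fn=None, params: EnergyParams | None = None,
        max_passes: int = 50) -> tuple[Structure, dict]:
    """Iterative single-residue best-rotamer passes until self-consistent.

    Each pass visits the listed residues in order and, for each, places every
    rotamer (chi angles in degrees) and keeps the lowest-energy one; passes
    repeat until one changes no assignment or `max_passes` is hit. The final
    energy never exceeds the initial energy.
    """
    from .energy import intramolecular_energy
    s = structure.copy()
    if energy_fn is None:
        p = params or EnergyParams(softcore_enabled=False)
        energy_fn = lambda st: intramolecular_energy(st, p).total
    chi_map = {}
    for ri in residue_indices:
        name = s.residues[ri].name
        if name not in rotamers or not rotamers[name]:
            raise RotamerError(f"no rotamers for residue type {name}")
        chi_map[ri] = residue_chi_torsions(s, ri)
    initial_energy = energy_fn(s)
    current_energy = initial_energy
    assignment: dict[int, int] = {}
    passes = 0
    converged = False
    while passes < max_passes:
        passes += 1
        changed = False
        for ri in residue_indices:
            chis = chi_map[ri]
            best_k, best_e, best_coords = None, np.inf, None
            for k, angles in enumerate(rotamers[s.residues[ri].name]):
                tors = s.get_torsion_angles()
                for ci, ang in zip(chis, angles):
                    tors[ci] = np.deg2rad(ang)
                coords = apply_torsions(s, tors)
                s.set_coords(coords)
                e = energy_fn(s)
                if e < best_e:
                    best_k, best_e, best_coords = k, e, coords
            s.set_coords(best_coords)
            current_energy = best_e
            if assignment.get(ri) != best_k:
                assignment[ri] = best_k
                changed = True
        if not changed:
            converged = True
            break
    if current_energy > initial_energy + 1e-9:
        # never worse than the input: no rotamer beat the input conformation
        s = structure.copy()
        current_energy = initial_energy
    report = {"passes": passes, "converged": converged,
              "initial_energy": initial_energy, "final_energy": current_energy,
              "assignment": assignment}
    return s, report
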