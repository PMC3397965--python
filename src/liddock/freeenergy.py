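"""Minimization, knowledge-based scoring, and MM-GB/SA decomposition.

Energies in kcal/mol, distances in Angstroms, temperature in Kelvin. The
GB polar term uses pairwise-descreening (HCT-style) effective Born radii;
the nonpolar term is surface tension times the solvent-accessible surface
area from a deterministic Shrake-Rupley quadrature. Solute entropy combines
classical translational (Sackur-Tetrode), rigid-rotor rotational and
classical harmonic-oscillator vibrational contributions from a
mass-weighted numerical Hessian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import constants as sc
from scipy.optimize import minimize as _scipy_minimize

from .energy import (COULOMB_CONSTANT, EnergyParams, intermolecular_energy,
                     nonbonded_exclusions, torsional_energy)
from .structure import Structure

KB = 0.0019872041  # kcal/mol/K

#: (kcal/mol/A^2/amu) -> (rad/s)^2 conversion for mass-weighted Hessian
#: eigenvalues: 4184 J/kcal * 1e20 A^2/m^2 / (1e-3 kg/mol / N_A / amu...) --
#: N_A * amu = 1e-3 kg exactly, so the factor is 4184e20/1e-3.
_OMEGA2_SI = 4.184e26

#: Intrinsic (Bondi-style) GB radii by element, Angstrom.
GB_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
            "P": 1.80, "X": 1.70}
#: HCT descreening scale factors by element.
GB_SCALE = {"H": 0.85, "C": 0.72, "N": 0.79, "O": 0.85, "S": 0.96,
            "P": 0.86, "X": 0.80}
GB_OFFSET = 0.09


class PreconditionError(ValueError):
    """Raised when an operation's structural precondition is not met."""


@dataclass(frozen=True)
class GBSAParams:
    eps_interior: float = 2.0
    eps_exterior: float = 80.0
    vdw_cutoff: float = 8.0        # residue-based, A
    ele_cutoff: float = 20.0       # residue-based, A
    surface_tension: float = 0.0072  # kcal/mol/A^2
    probe_radius: float = 1.4
    temperature: float = 300.0
    sasa_points: int = 960

    def __post_init__(self) -> None:
        if self.eps_interior < 1 or self.eps_exterior < 1:
            raise ValueError("dielectric constants must be >= 1")
        if self.vdw_cutoff <= 0 or self.ele_cutoff <= 0:
            raise ValueError("cutoffs must be positive")


# -- default differentiable energy ----------------------------------------

def default_energy_function(structure: Structure,
                            params: EnergyParams | None = None):
    """E(flat coords) for minimization / normal modes.

    Harmonic bond terms + torsions, plus intramolecular nonbonded (hard
    12-6 and constant-dielectric Coulomb, 1-2/1-3 excluded) when the
    structure carries Lennard-Jones parameters with nonzero well depths.
    Quadratic toy systems built by make_harmonic_system have eps = 0 and so
    see only their quadratic terms.
    """
    params = params or EnergyParams(softcore_enabled=False,
                                    dielectric_model="constant")
    atoms = structure.atoms
    n = len(atoms)
    eps = np.array([a.epsilon for a in atoms])
    sig = np.array([a.sigma for a in atoms])
    q = np.array([a.partial_charge for a in atoms])
    excluded, scaled = nonbonded_exclusions(structure)
    pair_list = []
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in excluded:
                continue
            e = np.sqrt(eps[i] * eps[j])
            if e == 0.0 and q[i] * q[j] == 0.0:
                continue
            sv, se = (params.scale_14_vdw, params.scale_14_elec) \
                if (i, j) in scaled else (1.0, 1.0)
            pair_list.append((i, j, e * sv, 0.5 * (sig[i] + sig[j]),
                              q[i] * q[j] * se))
    harm = structure.harmonic_bonds
    has_torsions = bool(structure.torsions)

    def fun(x: np.ndarray) -> float:
        coords = x.reshape(n, 3)
        e_total = 0.0
        for hb in harm:
            r = np.linalg.norm(coords[hb.i] - coords[hb.j])
            e_total += 0.5 * hb.k * (r - hb.r0) ** 2
        if has_torsions:
            e_total += torsional_energy(structure, coords)
        for i, j, e, s, qq in pair_list:
            r = np.linalg.norm(coords[i] - coords[j])
            if r > params.cutoff:
                continue
            sr6 = (s / r) ** 6
            e_total += 4.0 * e * (sr6 * sr6 - sr6)
            if qq != 0.0:
                e_total += COULOMB_CONSTANT * qq / (params.dielectric_constant * r)
        return float(e_total)

    return fun


def numerical_gradient(fun, x: np.ndarray, h: float = 1e-6) -> np.ndarray:
    g = np.empty_like(x)
    for k in range(len(x)):
        xp = x.copy(); xp[k] += h
        xm = x.copy(); xm[k] -= h
        g[k] = (fun(xp) - fun(xm)) / (2 * h)
    return g


@dataclass
class MinimizationReport:
    converged: bool
    steps: int
    max_gradient: float
    energy_initial: float
    energy_final: float


def minimize_structure(structure: Structure, energy_fn=None,
                       gradient_cutoff: float = 0.1, max_steps: int = 2000,
                       params: EnergyParams | None = None
                       ) -> tuple[Structure, MinimizationReport]:
    """Truncated-Newton energy minimization to max |gradient| <= cutoff.

    Returns a new Structure plus a report; on non-convergence within
    `max_steps` the best structure found so far is returned with
    ``converged=False``. The output energy never exceeds the input energy.
    """
    fun = energy_fn or default_energy_function(structure, params)
    x0 = structure.get_coords().ravel()
    e0 = fun(x0)
    grad = lambda x: numerical_gradient(fun, x)
    if max_steps <= 0:
        g0 = float(np.max(np.abs(grad(x0))))
        out = structure.copy()
        return out, MinimizationReport(g0 <= gradient_cutoff, 0, g0, e0, e0)
    res = _scipy_minimize(fun, x0, jac=grad, method="TNC",
                          options={"maxfun": max_steps, "gtol": 1e-12,
                                   "ftol": 0.0, "xtol": 1e-12})
    x, steps = res.x, res.nfev
    if fun(x) > e0:
        x = x0
    gmax = float(np.max(np.abs(grad(x))))
    if gmax > gradient_cutoff and steps < max_steps:
        res2 = _scipy_minimize(fun, x, jac=grad, method="L-BFGS-B",
                               options={"maxiter": max_steps - steps,
                                        "gtol": gradient_cutoff * 1e-3,
                                        "ftol": 0.0})
        if fun(res2.x) <= fun(x):
            x = res2.x
        steps += res2.nfev
        gmax = float(np.max(np.abs(grad(x))))
    ef = fun(x)
    out = structure.copy()
    out.set_coords(x.reshape(-1, 3))
    return out, MinimizationReport(gmax <= gradient_cutoff, steps, gmax, e0,
                                   min(ef, e0))


# -- SASA ------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (Fibonacci)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5 ** 0.5) * k
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi), np.cos(phi)])


def sasa_per_atom(coords: np.ndarray, radii: np.ndarray,
                  probe_radius: float = 1.4, n_points: int = 960) -> np.ndarray:
    """Shrake-Rupley solvent-accessible surface area per atom, A^2."""
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float) + probe_radius
    pts = _sphere_points(n_points)
    n = len(coords)
    out = np.zeros(n)
    for i in range(n):
        surf = coords[i] + radii[i] * pts
        accessible = np.ones(n_points, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            d = np.linalg.norm(coords[i] - coords[j])
            if d >= radii[i] + radii[j]:
                continue
            accessible &= (np.linalg.norm(surf - coords[j], axis=1) >= radii[j])
        out[i] = accessible.mean() * 4.0 * np.pi * radii[i] ** 2
    return out


def _atom_radii(structure: Structure) -> np.ndarray:
    return np.array([GB_RADII.get(a.element, GB_RADII["X"])
                     for a in structure.atoms])


def sasa_nonpolar(structure: Structure,
                  params: GBSAParams | None = None) -> tuple[float, float]:
    """(total SASA in A^2, nonpolar term = surface_tension * SASA)."""
    params = params or GBSAParams()
    areas = sasa_per_atom(structure.get_coords(), _atom_radii(structure),
                          params.probe_radius, params.sasa_points)
    total = float(areas.sum())
    return total, params.surface_tension * total


# -- generalized Born ------------------------------------------------------

def effective_born_radii(coords: np.ndarray, elements: list[str]) -> np.ndarray:
    """HCT pairwise-descreening effective Born radii."""
    rho = np.array([GB_RADII.get(e, GB_RADII["X"]) for e in elements]) - GB_OFFSET
    scale = np.array([GB_SCALE.get(e, GB_SCALE["X"]) for e in elements])
    n = len(coords)
    inv_r = 1.0 / rho
    for i in range(n):
        acc = 0.0
        for j in range(n):
            if j == i:
                continue
            r = float(np.linalg.norm(coords[i] - coords[j]))
            sj = scale[j] * rho[j]
            if rho[i] >= r + sj:
                continue
            lij = max(rho[i], abs(r - sj))
            uij = r + sj
            acc += 0.5 * ((1 / lij - 1 / uij)
                          + (r / 4) * (1 / uij ** 2 - 1 / lij ** 2)
                          + (1 / (2 * r)) * np.log(lij / uij)
                          + (sj ** 2 / (4 * r)) * (1 / lij ** 2 - 1 / uij ** 2))
        inv_r[i] -= acc
    inv_r = np.maximum(inv_r, 1e-6)
    return 1.0 / inv_r


def gb_polar_energy(structure: Structure,
                    params: GBSAParams | None = None) -> float:
    """Generalized-Born polar solvation energy, kcal/mol.

    dG = -C/2 (1/eps_in - 1/eps_out) sum_ij q_i q_j / f_GB(r_ij, R_i, R_j)
    with f_GB = sqrt(r^2 + R_i R_j exp(-r^2 / 4 R_i R_j)); i = j gives the
    Born self terms, so a single ion reproduces the Born equation exactly.
    """
    params = params or GBSAParams()
    atoms = structure.atoms
    q = np.array([a.partial_charge for a in atoms])
    if np.all(q == 0):
        return 0.0
    coords = structure.get_coords()
    radii = effective_born_radii(coords, [a.element for a in atoms])
    pref = -0.5 * COULOMB_CONSTANT * (1.0 / params.eps_interior
                                      - 1.0 / params.eps_exterior)
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    rr = radii[:, None] * radii[None, :]
    fgb = np.sqrt(d2 + rr * np.exp(-d2 / (4.0 * rr)))
    return float(pref * np.sum(q[:, None] * q[None, :] / fgb))


# -- molecular mechanics with residue-based cutoffs ------------------------

def _residue_atom_index(structure: Structure) -> list[np.ndarray]:
    out = []
    start = 0
    for res in structure.residues:
        out.append(np.arange(start, start + len(res.atoms)))
        start += len(res.atoms)
    return out


def mm_energy(structure: Structure, params: GBSAParams | None = None,
              dielectric: float = 1.0) -> tuple[float, float, float]:
    """(E_ele, E_vdw, E_int) with residue-based cutoffs.

    A residue pair contributes iff its minimal inter-residue atom distance
    is within the relevant cutoff (8 A for vdW, 20 A for electrostatics).
    E_int is the bonded strain: harmonic bond terms plus torsions.
    """
    params = params or GBSAParams()
    atoms = structure.atoms
    coords = structure.get_coords()
    eps = np.array([a.epsilon for a in atoms])
    sig = np.array([a.sigma for a in atoms])
    q = np.array([a.partial_charge for a in atoms])
    groups = _residue_atom_index(structure)
    excluded, scaled = nonbonded_exclusions(structure)
    e_vdw = 0.0
    e_ele = 0.0
    for gi in range(len(groups)):
        for gj in range(gi + 1, len(groups)):
            ai, aj = groups[gi], groups[gj]
            d = np.linalg.norm(coords[ai][:, None, :] - coords[aj][None, :, :],
                               axis=-1)
            dmin = d.min()
            use_vdw = dmin <= params.vdw_cutoff
            use_ele = dmin <= params.ele_cutoff
            if not (use_vdw or use_ele):
                continue
            for x, i in enumerate(ai):
                for y, j in enumerate(aj):
                    key = (min(i, j), max(i, j))
                    if key in excluded:
                        continue
                    sv, se = (0.5, 1.0 / 1.2) if key in scaled else (1.0, 1.0)
                    r = d[x, y]
                    if use_vdw:
                        e = np.sqrt(eps[i] * eps[j])
                        if e > 0:
                            sr6 = (0.5 * (sig[i] + sig[j]) / r) ** 6
                            e_vdw += sv * 4.0 * e * (sr6 * sr6 - sr6)
                    if use_ele and q[i] * q[j] != 0.0:
                        e_ele += se * COULOMB_CONSTANT * q[i] * q[j] / (dielectric * r)
    e_int = torsional_energy(structure, coords)
    for hb in structure.harmonic_bonds:
        r = np.linalg.norm(coords[hb.i] - coords[hb.j])
        e_int += 0.5 * hb.k * (r - hb.r0) ** 2
    return float(e_ele), float(e_vdw), float(e_int)


# -- normal-mode entropy ---------------------------------------------------

def mass_weighted_hessian(structure: Structure, energy_fn=None,
                          h: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of the energy, mass-weighted (1/sqrt(mi mj))."""
    fun = energy_fn or default_energy_function(structure)
    x0 = structure.get_coords().ravel()
    n = len(x0)
    hess = np.empty((n, n))
    for a in range(n):
        xp = x0.copy(); xp[a] += h
        xm = x0.copy(); xm[a] -= h
        gp = numerical_gradient(fun, xp, h)
        gm = numerical_gradient(fun, xm, h)
        hess[a] = (gp - gm) / (2 * h)
    hess = 0.5 * (hess + hess.T)
    masses = np.repeat([a.mass for a in structure.atoms], 3)
    return hess / np.sqrt(np.outer(masses, masses))


def vibrational_frequencies(structure: Structure, energy_fn=None,
                            zero_tol: float = 1e-6) -> tuple[np.ndarray, int]:
    """(angular frequencies rad/s of the nonzero modes, number removed)."""
    hmw = mass_weighted_hessian(structure, energy_fn)
    evals = np.linalg.eigvalsh(hmw)
    scale = max(abs(evals).max(), 1.0)
    nonzero = evals[np.abs(evals) > zero_tol * scale]
    removed = len(evals) - len(nonzero)
    negative = int(np.sum(nonzero < 0))
    if negative:
        warnings.warn(f"{negative} imaginary frequencies beyond the removed "
                      f"rigid-body modes", stacklevel=2)
        nonzero = nonzero[nonzero > 0]
    return np.sqrt(nonzero * _OMEGA2_SI), removed


def classical_vibrational_entropy(omega_si: np.ndarray, t: float) -> float:
    """T * S_vib of classical harmonic oscillators, kcal/mol.

    S = R (1 + ln(kB T / (hbar omega))) per mode.
    """
    if len(omega_si) == 0:
        return 0.0
    x = sc.k * t / (sc.hbar * omega_si)
    return float(t * KB * np.sum(1.0 + np.log(x)))


def translational_entropy(total_mass_amu: float, t: float,
                          pressure: float = sc.atm) -> float:
    """T * S_trans from the Sackur-Tetrode equation, kcal/mol."""
    m = total_mass_amu * sc.atomic_mass
    v = sc.k * t / pressure
    q = (2 * np.pi * m * sc.k * t / sc.h ** 2) ** 1.5 * v
    return float(t * KB * (np.log(q) + 2.5))


def rotational_entropy(structure: Structure, t: float,
                       sigma_symmetry: float = 1.0) -> float:
    """T * S_rot of a classical rigid rotor, kcal/mol (linear-aware)."""
    coords = structure.get_coords() * 1e-10
    masses = np.array([a.mass for a in structure.atoms]) * sc.atomic_mass
    com = (coords * masses[:, None]).sum(axis=0) / masses.sum()
    x = coords - com
    inertia = np.zeros((3, 3))
    for mi, xi in zip(masses, x):
        inertia += mi * (np.dot(xi, xi) * np.eye(3) - np.outer(xi, xi))
    ev = np.sort(np.linalg.eigvalsh(inertia))
    if len(coords) == 1 or ev[-1] < 1e-60:
        return 0.0
    if ev[0] < 1e-6 * ev[-1]:  # linear molecule
        q = 8 * np.pi ** 2 * ev[-1] * sc.k * t / (sigma_symmetry * sc.h ** 2)
        return float(t * KB * (1.0 + np.log(q)))
    q = (np.sqrt(np.pi) / sigma_symmetry
         * (8 * np.pi ** 2 * sc.k * t / sc.h ** 2) ** 1.5
         * np.sqrt(ev[0] * ev[1] * ev[2]))
    return float(t * KB * (1.5 + np.log(q)))


def normal_mode_entropy(structure: Structure, t: float = 300.0,
                        energy_fn=None, gradient_cutoff: float = 0.1
                        ) -> tuple[float, float, float, float]:
    """(TS_trans, TS_rot, TS_vib, TS_total) at temperature t, kcal/mol.

    Requires a minimized input: max |gradient| must not exceed
    `gradient_cutoff`, otherwise a PreconditionError is raised. Rigid-body
    modes are removed by a near-zero eigenvalue threshold; a warning reports
    any count other than 6 (5 for linear molecules).
    """
    fun = energy_fn or default_energy_function(structure)
    g = numerical_gradient(fun, structure.get_coords().ravel())
    gmax = float(np.max(np.abs(g))) if len(g) else 0.0
    if gmax > gradient_cutoff:
        raise PreconditionError(
            f"normal modes need a minimized structure (max gradient {gmax:.3g} "
            f"> {gradient_cutoff})")
    omega, removed = vibrational_frequencies(structure, fun)
    if removed not in (5, 6) and structure.n_atoms > 1:
        warnings.warn(f"removed {removed} near-zero modes (expected 6, or 5 "
                      f"for a linear molecule)", stacklevel=2)
    ts_vib = classical_vibrational_entropy(omega, t)
    ts_trans = translational_entropy(sum(a.mass for a in structure.atoms), t)
    ts_rot = rotational_entropy(structure, t)
    return ts_trans, ts_rot, ts_vib, ts_trans + ts_rot + ts_vib


# -- knowledge-based score -------------------------------------------------

DEFAULT_KB_WEIGHTS = {
    "hydrophobic": -0.025,   # kcal/mol per A^2 of buried nonpolar surface
    "hydrogen_bond": -0.5,   # kcal/mol per interface hydrogen bond
    "vdw": 0.2,              # scales the intermolecular 12-6 energy
    "electrostatic": 0.2,    # scales the screened Coulomb energy
    "desolvation": 0.5,      # scales the pairwise desolvation sum
    "entropy_trans_rot": 2.5,  # kcal/mol penalty, rigid-body freezing
    "entropy_per_rotor": 0.4,  # kcal/mol per frozen rotatable torsion
}


@dataclass(frozen=True)
class KBScoreBreakdown:
    dG_hydrophobic: float
    dG_hydrogen_bond: float
    dG_vdW: float
    dG_electrostatic: float
    dG_desolvation: float
    dG_entropy: float
    dG_total: float

    def __post_init__(self) -> None:
        s = (self.dG_hydrophobic + self.dG_hydrogen_bond + self.dG_vdW
             + self.dG_electrostatic + self.dG_desolvation + self.dG_entropy)
        if abs(s - self.dG_total) > 1e-9:
            raise ValueError("KB score total does not equal component sum")


def _interface_hbond_count(receptor: Structure, ligand: Structure,
                           lig_coords: np.ndarray, max_distance: float = 3.5
                           ) -> int:
    rc = receptor.get_coords()
    count = 0
    for i, a in enumerate(ligand.atoms):
        for j, b in enumerate(receptor.atoms):
            pair = {a.hbond_class, b.hbond_class}
            ok = pair == {"donor", "acceptor"} or "both" in pair and pair != {"both", "nonpolar"}
            if not ok or not (a.is_heavy and b.is_heavy):
                continue
            if np.linalg.norm(lig_coords[i] - rc[j]) <= max_distance:
                count += 1
    return count


def kb_score(receptor: Structure, ligand: Structure,
             lig_coords: np.ndarray | None = None,
             weights: dict | None = None,
             energy_params: EnergyParams | None = None,
             gbsa_params: GBSAParams | None = None) -> KBScoreBreakdown:
    """Six-term knowledge-based binding score (linear in its weights).

    Components: buried-nonpolar-surface hydrophobic term, interface
    hydrogen-bond term, intermolecular van der Waals and screened
    electrostatics, pairwise desolvation, and a rigid-body + frozen-rotor
    entropy penalty. Weights are package defaults, editable per call.
    """
    w = dict(DEFAULT_KB_WEIGHTS)
    if weights:
        missing = set(weights) - set(w)
        if missing:
            raise ValueError(f"unknown KB weight(s): {sorted(missing)}")
        w.update(weights)
    ep = energy_params or EnergyParams(softcore_enabled=False)
    gp = gbsa_params or GBSAParams()
    if lig_coords is None:
        lig_coords = ligand.get_coords()
    inter = intermolecular_energy(ligand, receptor, ep, lid_coords=lig_coords)
    # buried nonpolar surface: parts minus complex, nonpolar atoms only
    np_rec = _nonpolar_sasa(receptor, receptor.get_coords(), gp)
    np_lig = _nonpolar_sasa(ligand, lig_coords, gp)
    all_coords = np.vstack([receptor.get_coords(), lig_coords])
    all_radii = np.concatenate([_atom_radii(receptor), _atom_radii(ligand)])
    areas = sasa_per_atom(all_coords, all_radii, gp.probe_radius, gp.sasa_points)
    mask = np.array([a.hbond_class == "nonpolar" for a in
                     receptor.atoms + ligand.atoms])
    np_complex = float(areas[mask].sum())
    buried = max(np_rec + np_lig - np_complex, 0.0)
    n_hb = _interface_hbond_count(receptor, ligand, lig_coords)
    n_rotors = len(ligand.rotatable_torsions())
    comp = {
        "dG_hydrophobic": w["hydrophobic"] * buried,
        "dG_hydrogen_bond": w["hydrogen_bond"] * n_hb,
        "dG_vdW": w["vdw"] * inter.vdw_inter,
        "dG_electrostatic": w["electrostatic"] * inter.electrostatic,
        "dG_desolvation": w["desolvation"] * inter.solvation,
        "dG_entropy": w["entropy_trans_rot"] + w["entropy_per_rotor"] * n_rotors,
    }
    return KBScoreBreakdown(**comp, dG_total=sum(comp.values()))


def _nonpolar_sasa(structure: Structure, coords: np.ndarray,
                   gp: GBSAParams) -> float:
    areas = sasa_per_atom(coords, _atom_radii(structure),
                          gp.probe_radius, gp.sasa_points)
    mask = np.array([a.hbond_class == "nonpolar" for a in structure.atoms])
    return float(areas[mask].sum())


# -- MM-GB/SA single-trajectory protocol -----------------------------------

@dataclass(frozen=True)
class GBSABreakdown:
    """Component decomposition of an MM-GB/SA binding free energy.

    Sign conventions: every dE/dG term is complex minus (receptor + ligand);
    TdS_total is reported as a positive penalty added to dG_total.
    """

    dE_ele: float
    dE_vdw: float
    dE_int: float
    dE_MM_gas: float
    dG_gb_nb: float
    dG_gb_pol: float
    dG_gb_total: float
    TdS_total: float
    dG_total: float

    def __post_init__(self) -> None:
        checks = (
            abs(self.dE_MM_gas - (self.dE_ele + self.dE_vdw + self.dE_int)),
            abs(self.dG_gb_total - (self.dG_gb_nb + self.dG_gb_pol)),
            abs(self.dG_total - (self.dE_MM_gas + self.dG_gb_total
                                 + self.TdS_total)),
        )
        if max(checks) > 1e-9:
            raise ValueError("GBSA breakdown identities violated")

    @classmethod
    def build(cls, dE_ele, dE_vdw, dE_int, dG_gb_nb, dG_gb_pol, TdS_total):
        gas = dE_ele + dE_vdw + dE_int
        gb = dG_gb_nb + dG_gb_pol
        return cls(dE_ele, dE_vdw, dE_int, gas, dG_gb_nb, dG_gb_pol, gb,
                   TdS_total, gas + gb + TdS_total)


def _split_structure(structure: Structure, coords: np.ndarray,
                     receptor_residues: list[int], ligand_residues: list[int]
                     ) -> tuple[Structure, Structure]:
    groups = _residue_atom_index(structure)
    parts = []
    for residue_ids in (receptor_residues, ligand_residues):
        keep_atoms = np.concatenate([groups[ri] for ri in residue_ids])
        remap = {int(old): k for k, old in enumerate(keep_atoms)}
        import copy as _copy
        res = [_copy.deepcopy(structure.residues[ri]) for ri in residue_ids]
        part = Structure(
            res,
            bonds=[(remap[i], remap[j]) for i, j in structure.bonds
                   if i in remap and j in remap],
            torsions=[type(t)(remap[t.a], remap[t.b], remap[t.c], remap[t.d],
                              t.rotatable, t.barrier, t.periodicity, t.phase)
                      for t in structure.torsions
                      if all(k in remap for k in (t.a, t.b, t.c, t.d))],
            harmonic_bonds=[type(h)(remap[h.i], remap[h.j], h.k, h.r0)
                            for h in structure.harmonic_bonds
                            if h.i in remap and h.j in remap],
        )
        part.set_coords(coords[keep_atoms])
        parts.append(part)
    return parts[0], parts[1]


def _frame_terms(structure: Structure, params: GBSAParams):
    ele, vdw, e_int = mm_energy(structure, params)
    sasa, nonpolar = sasa_nonpolar(structure, params)
    pol = gb_polar_energy(structure, params)
    return np.array([ele, vdw, e_int, nonpolar, pol])


def mmgbsa_binding(traj, receptor_residues: list[int],
                   ligand_residues: list[int],
                   params: GBSAParams | None = None,
                   entropy_stride: int = 0, minimize_parts: bool = False,
                   minimize_max_steps: int = 200) -> GBSABreakdown:
    """Single-trajectory MM-GB/SA binding decomposition, frame-averaged.

    Each frame's complex is split into receptor and ligand parts (optionally
    re-minimized); every Delta term is complex - receptor - ligand, averaged
    over frames. The entropy penalty is estimated on every
    `entropy_stride`-th frame (0 disables it). `traj` is any object with a
    `topology` Structure and a `frames` list of coordinate arrays.
    """
    params = params or GBSAParams()
    frames = list(traj.frames)
    if not frames:
        raise ValueError("trajectory has no frames")
    n_res = len(traj.topology.residues)
    for ids in (receptor_residues, ligand_residues):
        if not ids or any(not 0 <= r < n_res for r in ids):
            raise ValueError("receptor/ligand residue split invalid for trajectory")
    deltas = []
    tds_samples = []
    ep = EnergyParams(softcore_enabled=False, dielectric_model="distance",
                      dielectric_slope=4.0)
    for fi, coords in enumerate(frames):
        complex_s = traj.topology.copy()
        complex_s.set_coords(coords)
        rec, lig = _split_structure(traj.topology, coords,
                                    receptor_residues, ligand_residues)
        if minimize_parts:
            rec, _ = minimize_structure(rec, params=ep,
                                        max_steps=minimize_max_steps)
            lig, _ = minimize_structure(lig, params=ep,
                                        max_steps=minimize_max_steps)
        tc = _frame_terms(complex_s, params)
        tr = _frame_terms(rec, params)
        tl = _frame_terms(lig, params)
        deltas.append(tc - tr - tl)
        if entropy_stride and fi % entropy_stride == 0:
            tds = 0.0
            for part, sign in ((complex_s, 1.0), (rec, -1.0), (lig, -1.0)):
                mini, _ = minimize_structure(part, params=ep,
                                             max_steps=minimize_max_steps)
                tds += sign * normal_mode_entropy(mini, params.temperature,
                                                  gradient_cutoff=np.inf)[3]
            tds_samples.append(-tds)  # loss of entropy -> positive penalty
    mean = np.mean(deltas, axis=0)
    tds_total = float(np.mean(tds_samples)) if tds_samples else 0.0
    return GBSABreakdown.build(dE_ele=float(mean[0]), dE_vdw=float(mean[1]),
                               dE_int=float(mean[2]), dG_gb_nb=float(mean[3]),
                               dG_gb_pol=float(mean[4]), TdS_total=tds_total)
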