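"""Composite docking energy model.

Intramolecular lid terms (torsional + nonbonded with 1-2/1-3 exclusions),
intermolecular lid-receptor terms (soft-core Lennard-Jones, screened Coulomb,
pairwise Gaussian desolvation), all in kcal/mol with distances in Angstroms.

The soft-core form is a Beutler-style modification with a single softness
parameter alpha applied to both the dispersion-repulsion and the
electrostatic term:

    E_vdw(r)  = 4*eps * [ sigma^12 / (alpha*sigma^6 + r^6)^2
                          - sigma^6 / (alpha*sigma^6 + r^6) ]
    E_elec(r) = C q_i q_j / D(sqrt(alpha*sigma^2 + r^2))

where D(.) is the configured dielectric screening (constant eps, or
distance-dependent eps(r) = k*r so the denominator becomes k*r^2). Both
reduce exactly to the unmodified 12-6 and Coulomb potentials at alpha = 0
and are finite at r = 0 for alpha > 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import Structure

#: Electrostatic conversion constant, kcal*A/(mol*e^2).
COULOMB_CONSTANT = 332.06371


class ParameterError(ValueError):
    """Raised when an energy term lacks required parameters."""


@dataclass
class EnergyParams:
    """Parameters of the composite docking energy model.

    dielectric_model: "constant" (D = dielectric_constant) or
        "distance" (D = dielectric_slope * r, the docking default).
    softcore_alpha: dimensionless softness; 0 recovers the hard potentials.
    desolvation_weights: per hydrogen-bond class; pairwise products weight a
        Gaussian envelope of width desolvation_sigma.
    scale_14_*: scaling of 1-4 nonbonded pairs (1-2 and 1-3 are excluded).
    """

    dielectric_model: str = "distance"
    dielectric_constant: float = 1.0
    dielectric_slope: float = 4.0
    softcore_alpha: float = 0.5
    softcore_enabled: bool = True
    cutoff: float = 12.0
    desolvation_sigma: float = 3.5
    desolvation_weights: dict = field(default_factory=lambda: {
        "donor": 0.30, "acceptor": 0.30, "both": 0.40, "nonpolar": -0.05,
    })
    scale_14_vdw: float = 0.5
    scale_14_elec: float = 1.0 / 1.2

    def __post_init__(self) -> None:
        if self.dielectric_model not in ("constant", "distance"):
            raise ValueError(f"unknown dielectric model {self.dielectric_model!r}")
        if self.dielectric_constant < 1.0:
            raise ValueError("dielectric constant must be >= 1")
        if self.softcore_alpha < 0:
            raise ValueError("softcore alpha must be >= 0")

    @property
    def alpha(self) -> float:
        return self.softcore_alpha if self.softcore_enabled else 0.0


@dataclass(frozen=True)
class EnergyBreakdown:
    """Component terms of a docking energy evaluation (kcal/mol)."""

    torsional: float = 0.0
    vdw_intra: float = 0.0
    vdw_inter: float = 0.0
    electrostatic: float = 0.0
    solvation: float = 0.0
    total: float = 0.0

    def __post_init__(self) -> None:
        s = (self.torsional + self.vdw_intra + self.vdw_inter
             + self.electrostatic + self.solvation)
        if abs(s - self.total) > 1e-9:
            raise ValueError("energy breakdown total does not equal component sum")

    @classmethod
    def build(cls, torsional=0.0, vdw_intra=0.0, vdw_inter=0.0,
              electrostatic=0.0, solvation=0.0) -> "EnergyBreakdown":
        return cls(torsional, vdw_intra, vdw_inter, electrostatic, solvation,
                   torsional + vdw_intra + vdw_inter + electrostatic + solvation)

    def __add__(self, other: "EnergyBreakdown") -> "EnergyBreakdown":
        return EnergyBreakdown.build(
            self.torsional + other.torsional,
            self.vdw_intra + other.vdw_intra,
            self.vdw_inter + other.vdw_inter,
            self.electrostatic + other.electrostatic,
            self.solvation + other.solvation,
        )


def softcore_pair(r: float, epsilon: float, sigma: float,
                  qi: float, qj: float, params: EnergyParams) -> tuple[float, float]:
    """Soft-core (vdw, coulomb) energies of one atom pair at separation r (A)."""
    if r < 0:
        raise ValueError("pair distance must be nonnegative")
    alpha = params.alpha
    s6 = sigma ** 6
    denom = alpha * s6 + r ** 6
    vdw = 4.0 * epsilon * (s6 * s6 / denom ** 2 - s6 / denom)
    r_eff = np.sqrt(alpha * sigma ** 2 + r ** 2)
    if params.dielectric_model == "constant":
        screen = params.dielectric_constant * r_eff
    else:
        screen = params.dielectric_slope * r_eff ** 2
    coul = COULOMB_CONSTANT * qi * qj / screen if screen > 0 else np.inf
    if qi == 0.0 or qj == 0.0:
        coul = 0.0
    return float(vdw), float(coul)


def _pair_arrays(atoms):
    eps = np.array([a.epsilon for a in atoms])
    sig = np.array([a.sigma for a in atoms])
    q = np.array([a.partial_charge for a in atoms])
    return eps, sig, q


def _classes(atoms, params):
    w = params.desolvation_weights
    out = np.empty(len(atoms))
    for i, a in enumerate(atoms):
        if a.hbond_class is None:
            raise ParameterError(
                f"atom {a.name} has no hydrogen-bond class; run assign_atom_classes")
        out[i] = w[a.hbond_class]
    return out


def _nonbonded_terms(dist, eps, sig, q, params, scale_vdw=None, scale_elec=None):
    """Vectorised soft-core vdw + screened coulomb over a distance matrix."""
    alpha = params.alpha
    s6 = sig ** 6
    denom = alpha * s6 + dist ** 6
    vdw = 4.0 * eps * (s6 * s6 / denom ** 2 - s6 / denom)
    r_eff2 = alpha * sig ** 2 + dist ** 2
    if params.dielectric_model == "constant":
        screen = params.dielectric_constant * np.sqrt(r_eff2)
    else:
        screen = params.dielectric_slope * r_eff2
    with np.errstate(divide="ignore", invalid="ignore"):
        coul = np.where(screen > 0, COULOMB_CONSTANT * q / screen, np.inf)
    coul = np.where(q == 0.0, 0.0, coul)
    mask = dist <= params.cutoff
    vdw = np.where(mask, vdw, 0.0)
    coul = np.where(mask, coul, 0.0)
    if scale_vdw is not None:
        vdw = vdw * scale_vdw
        coul = coul * scale_elec
    return vdw, coul


def torsional_energy(structure: Structure, coords: np.ndarray | None = None) -> float:
    """Sum of 0.5*V*(1 - cos(n*(phi - phi0))) over all torsion terms."""
    from .geometry import dihedral_angle
    if coords is None:
        coords = structure.get_coords()
    e = 0.0
    for t in structure.torsions:
        phi = dihedral_angle(coords[t.a], coords[t.b], coords[t.c], coords[t.d])
        e += 0.5 * t.barrier * (1.0 - np.cos(t.periodicity * (phi - t.phase)))
    return float(e)


def nonbonded_exclusions(structure: Structure) -> tuple[set, set]:
    """(excluded 1-2/1-3 pairs, scaled 1-4 pairs) as frozen index pairs."""
    cached = getattr(structure, "_exclusion_cache", None)
    if cached is not None and cached[0] == len(structure.bonds):
        return cached[1], cached[2]
    adj: dict[int, set[int]] = {}
    for i, j in structure.bonds:
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    excluded, scaled = set(), set()
    for i in adj:
        for j in adj[i]:
            if i < j:
                excluded.add((i, j))
            for k in adj[j]:
                if k != i:
                    excluded.add((min(i, k), max(i, k)))
                    for l in adj[k]:
                        if l not in (i, j):
                            scaled.add((min(i, l), max(i, l)))
    scaled -= excluded
    scaled = {p for p in scaled if p[0] != p[1]}
    structure._exclusion_cache = (len(structure.bonds), excluded, scaled)
    return excluded, scaled


def intramolecular_energy(lid: Structure, params: EnergyParams,
                          coords: np.ndarray | None = None) -> EnergyBreakdown:
    """Torsional + intra-lid nonbonded energy (1-2/1-3 excluded, 1-4 scaled)."""
    if coords is None:
        coords = lid.get_coords()
    atoms = lid.atoms
    tors = torsional_energy(lid, coords)
    excluded, scaled = nonbonded_exclusions(lid)
    eps, sig, q = _pair_arrays(atoms)
    vdw_sum = 0.0
    elec_sum = 0.0
    n = len(atoms)
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in excluded:
                continue
            r = float(np.linalg.norm(coords[i] - coords[j]))
            if r > params.cutoff:
                continue
            e = np.sqrt(eps[i] * eps[j])
            s = 0.5 * (sig[i] + sig[j])
            v, c = softcore_pair(r, e, s, q[i], q[j], params)
            if (i, j) in scaled:
                v *= params.scale_14_vdw
                c *= params.scale_14_elec
            vdw_sum += v
            elec_sum += c
    return EnergyBreakdown.build(torsional=tors, vdw_intra=vdw_sum,
                                 electrostatic=elec_sum)


def intermolecular_energy(lid: Structure, receptor: Structure,
                          params: EnergyParams,
                          lid_coords: np.ndarray | None = None) -> EnergyBreakdown:
    """Cross lid-receptor vdW + electrostatics + pairwise desolvation."""
    lc = lid.get_coords() if lid_coords is None else np.asarray(lid_coords, float)
    rc = receptor.get_coords()
    la, ra = lid.atoms, receptor.atoms
    le, ls, lq = _pair_arrays(la)
    re_, rs, rq = _pair_arrays(ra)
    dist = np.linalg.norm(lc[:, None, :] - rc[None, :, :], axis=-1)
    eps = np.sqrt(le[:, None] * re_[None, :])
    sig = 0.5 * (ls[:, None] + rs[None, :])
    qq = lq[:, None] * rq[None, :]
    vdw, coul = _nonbonded_terms(dist, eps, sig, qq, params)
    wl = _classes(la, params)
    wr = _classes(ra, params)
    gauss = np.exp(-dist ** 2 / (2.0 * params.desolvation_sigma ** 2))
    solv = np.where(dist <= params.cutoff,
                    wl[:, None] * wr[None, :] * gauss, 0.0)
    return EnergyBreakdown.build(vdw_inter=float(vdw.sum()),
                                 electrostatic=float(coul.sum()),
                                 solvation=float(solv.sum()))


def total_docking_energy(lid: Structure, receptor: Structure,
                         params: EnergyParams,
                         lid_coords: np.ndarray | None = None) -> EnergyBreakdown:
    """Intramolecular lid energy plus lid-receptor intermolecular energy."""
    return (intramolecular_energy(lid, params, lid_coords)
            + intermolecular_energy(lid, receptor, params, lid_coords))
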