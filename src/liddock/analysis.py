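"""Trajectory and ensemble analyses.

RMSD/RMSF, hydrogen-bond and salt-bridge occupancy, residue contact maps,
per-residue accessible-surface changes, side-chain movements and
molecular-mimicry pairing. Geometric conventions (pinned by tests): the
hydrogen-bond rule uses donor-acceptor distance <= 3.50 A AND
donor-H-acceptor angle >= 120 degrees (for heavy-atom-only structures the
angle falls back to antecedent-donor-acceptor with the same cutoff); the
residue contact rule uses minimum heavy-atom distance strictly < 4.2 A.
"""

from __future__ import annotations

from dataclasses import dataclass

import copy

import numpy as np
import pandas as pd

from .geometry import bond_angle, kabsch
from .structure import SelectionError, Structure
from . import freeenergy

BACKBONE_ATOMS = {"N", "CA", "C", "O", "H", "HN", "OXT"}


@dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed atom set, times in ps."""

    topology: Structure
    frames: list[np.ndarray]
    times: np.ndarray

    def __post_init__(self) -> None:
        n = self.topology.n_atoms
        self.frames = [np.asarray(f, float) for f in self.frames]
        for f in self.frames:
            if f.shape != (n, 3):
                raise ValueError("every frame must cover the fixed atom set")
        self.times = np.asarray(self.times, float)
        if len(self.times) != len(self.frames):
            raise ValueError("one time stamp per frame required")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class HBondCriteria:
    max_distance: float = 3.50   # donor-acceptor, A (inclusive)
    min_angle: float = 120.00    # degrees (inclusive)

    def __post_init__(self) -> None:
        if self.max_distance <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0 < self.min_angle <= 180:
            raise ValueError("angle cutoff must lie in (0, 180]")


# -- RMSD / RMSF -----------------------------------------------------------

def rmsd_series(traj: Trajectory, reference: Structure,
                atom_names: set[str] | None = None,
                fit_names: set[str] | None = None) -> np.ndarray:
    """Per-frame best-fit RMSD (A) over the selection after superposition.

    The rigid fit uses `fit_names` (defaults to the analysis selection).
    """
    sel = traj.topology.select(atom_names)
    if len(sel) == 0:
        raise SelectionError("empty RMSD selection")
    fit = traj.topology.select(fit_names) if fit_names is not None else sel
    ref = reference.get_coords()
    out = np.empty(traj.n_frames)
    for k, frame in enumerate(traj.frames):
        tr, _ = kabsch(frame[fit], ref[fit])
        moved = tr.apply(frame[sel])
        out[k] = float(np.sqrt(np.mean(np.sum((moved - ref[sel]) ** 2, axis=1))))
    return out


def rmsf_profile(traj: Trajectory, atom_names: set[str] | None = None,
                 fit_names: set[str] | None = None,
                 superpose_frames: bool = True) -> pd.Series:
    """Per-residue RMSF (A) about the mean structure.

    Frames are optionally superposed (on `fit_names`, default all atoms)
    before the fluctuation is computed; per-residue values are the RMS over
    the selected atoms of the residue.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least two frames")
    top = traj.topology
    fit = top.select(fit_names)
    frames = [f.copy() for f in traj.frames]
    if superpose_frames:
        ref = frames[0]
        for k in range(1, len(frames)):
            tr, _ = kabsch(frames[k][fit], ref[fit])
            frames[k] = tr.apply(frames[k])
    stack = np.stack(frames)
    mean = stack.mean(axis=0)
    msf = np.mean(np.sum((stack - mean) ** 2, axis=2), axis=0)  # per atom
    sel = set(top.select(atom_names).tolist())
    labels, values = [], []
    idx = 0
    for res in top.residues:
        atom_ids = [idx + k for k in range(len(res.atoms)) if idx + k in sel]
        idx += len(res.atoms)
        if not atom_ids:
            continue
        labels.append(res.seq_id)
        values.append(float(np.sqrt(np.mean(msf[atom_ids]))))
    return pd.Series(values, index=pd.Index(labels, name="seq_id"), name="rmsf")


# -- hydrogen bonds and salt bridges --------------------------------------

def _donor_hydrogens(top: Structure, donor_idx: int) -> list[int]:
    """Hydrogens within covalent range (1.25 A) of the donor, frame 0 geometry."""
    coords = top.get_coords()
    atoms = top.atoms
    return [i for i, a in enumerate(atoms)
            if a.element == "H" and i != donor_idx
            and np.linalg.norm(coords[i] - coords[donor_idx]) <= 1.25]


def _donor_antecedent(top: Structure, donor_idx: int) -> int | None:
    """Nearest bonded heavy atom of the donor (heavy-atom angle fallback)."""
    coords = top.get_coords()
    atoms = top.atoms
    best, best_d = None, 1.8
    for i, a in enumerate(atoms):
        if i == donor_idx or not a.is_heavy:
            continue
        d = np.linalg.norm(coords[i] - coords[donor_idx])
        if d < best_d:
            best, best_d = i, d
    return best


def _hbond_satisfied(coords: np.ndarray, donor: int, acceptor: int,
                     hydrogens: list[int], antecedent: int | None,
                     criteria: HBondCriteria) -> bool:
    d = float(np.linalg.norm(coords[donor] - coords[acceptor]))
    if d > criteria.max_distance:
        return False
    min_angle = np.deg2rad(criteria.min_angle)
    if hydrogens:
        return any(bond_angle(coords[donor], coords[h], coords[acceptor])
                   >= min_angle for h in hydrogens)
    if antecedent is not None:
        return bond_angle(coords[antecedent], coords[donor],
                          coords[acceptor]) >= min_angle
    return True  # isolated donor: distance-only criterion


def _default_pairs(top: Structure) -> list[tuple[int, int]]:
    donors = [i for i, a in enumerate(top.atoms)
              if a.is_heavy and a.hbond_class in ("donor", "both")]
    acceptors = [i for i, a in enumerate(top.atoms)
                 if a.is_heavy and a.hbond_class in ("acceptor", "both")]
    atoms = top.atoms
    return [(d, a) for d in donors for a in acceptors
            if d != a and atoms[d].residue_ref != atoms[a].residue_ref]


def hbond_satisfaction(traj: Trajectory, pairs, criteria: HBondCriteria
                       ) -> np.ndarray:
    """Boolean (n_pairs, n_frames) satisfaction matrix for donor/acceptor pairs."""
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    top = traj.topology
    out = np.zeros((len(pairs), traj.n_frames), dtype=bool)
    for pi, (donor, acceptor) in enumerate(pairs):
        hyd = _donor_hydrogens(top, donor)
        ante = _donor_antecedent(top, donor) if not hyd else None
        for fi, frame in enumerate(traj.frames):
            out[pi, fi] = _hbond_satisfied(frame, donor, acceptor, hyd, ante,
                                           criteria)
    return out


def hbond_occupancy(traj: Trajectory, criteria: HBondCriteria | None = None,
                    pairs: list[tuple[int, int]] | None = None) -> pd.DataFrame:
    """Occupancy table: (donor, acceptor, n_frames_satisfied, occupancy).

    Occupancy is the exact fraction of analyzed frames satisfying both the
    distance and the angle criterion. Pairs default to every classified
    donor x acceptor combination across different residues.
    """
    criteria = criteria or HBondCriteria()
    top = traj.topology
    if pairs is None:
        pairs = _default_pairs(top)
    sat = hbond_satisfaction(traj, pairs, criteria)
    atoms = top.atoms

    def label(i):
        res = top.residues[atoms[i].residue_ref]
        return f"{res.name}{res.seq_id}:{atoms[i].name}"

    rows = [{"donor": label(d), "acceptor": label(a), "donor_index": d,
             "acceptor_index": a, "n_frames_satisfied": int(sat[k].sum()),
             "occupancy": sat[k].sum() / traj.n_frames}
            for k, (d, a) in enumerate(pairs)]
    return pd.DataFrame(rows)


def salt_bridge_series(traj: Trajectory, pairs: list[tuple[int, int]],
                       criteria: HBondCriteria | None = None) -> np.ndarray:
    """Per-frame boolean series for charged-group pairs (H-bond geometry).

    Pairs are (donor atom, acceptor atom) indices of oppositely charged
    groups; a same-sign pair raises a ValueError.
    """
    criteria = criteria or HBondCriteria()
    atoms = traj.topology.atoms
    for d, a in pairs:
        qd, qa = atoms[d].partial_charge, atoms[a].partial_charge
        if qd * qa > 0:
            raise ValueError(f"pair ({d}, {a}) is not oppositely charged")
    if not pairs:
        return np.zeros((0, traj.n_frames), dtype=bool)
    return hbond_satisfaction(traj, pairs, criteria)


# -- contact maps ----------------------------------------------------------

@dataclass
class ContactMap:
    """Residue-pair minimum heavy-atom distances and ensemble contact frequency."""

    pairs: pd.DataFrame  # res_i, res_j, min_distance, contact, frequency
    cutoff: float

    def contact(self, seq_i: int, seq_j: int) -> bool:
        i, j = min(seq_i, seq_j), max(seq_i, seq_j)
        row = self.pairs[(self.pairs.res_i == i) & (self.pairs.res_j == j)]
        return bool(row.contact.iloc[0]) if len(row) else False


def contact_map(ensemble, partner_split: tuple[list[int], list[int]] | None = None,
                cutoff: float = 4.2) -> ContactMap:
    """Residue contact map: contact iff min heavy-atom distance < cutoff.

    `ensemble` is a Structure or list of Structures sharing a residue set;
    frequency is the fraction of members in contact. With `partner_split`
    (two residue-index lists) only cross-partner pairs are reported.
    """
    members = [ensemble] if isinstance(ensemble, Structure) else list(ensemble)
    top = members[0]
    heavy = [np.array([i for i, a in enumerate(r.atoms) if a.is_heavy])
             for r in top.residues]
    if all(len(h) == 0 for h in heavy):
        raise ValueError("no heavy atoms present")
    n_res = len(top.residues)
    offsets = np.cumsum([0] + [len(r.atoms) for r in top.residues])
    if partner_split is None:
        pair_ids = [(i, j) for i in range(n_res) for j in range(i + 1, n_res)]
    else:
        left, right = partner_split
        pair_ids = [(min(i, j), max(i, j)) for i in left for j in right]
    rows = []
    for i, j in pair_ids:
        hi, hj = heavy[i] + offsets[i], heavy[j] + offsets[j]
        if len(hi) == 0 or len(hj) == 0:
            continue
        dmins, contacts = [], []
        for s in members:
            c = s.get_coords()
            d = np.linalg.norm(c[hi][:, None, :] - c[hj][None, :, :], axis=-1)
            dmin = float(d.min())
            dmins.append(dmin)
            contacts.append(dmin < cutoff)
        rows.append({"res_i": top.residues[i].seq_id,
                     "res_j": top.residues[j].seq_id,
                     "min_distance": min(dmins),
                     "contact": any(contacts),
                     "frequency": float(np.mean(contacts))})
    return ContactMap(pd.DataFrame(rows), cutoff)


# -- accessible surface area changes ---------------------------------------

#: Theoretical maximum ASA of residue X in an extended Gly-X-Gly tripeptide
#: (A^2); residues outside the table are normalized by their own isolated
#: SASA computed on the fly.
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


def _percent_asa(structure: Structure, params) -> pd.Series:
    areas = freeenergy.sasa_per_atom(
        structure.get_coords(), freeenergy._atom_radii(structure),
        params.probe_radius, params.sasa_points)
    idx = 0
    labels, values = [], []
    for ri, res in enumerate(structure.residues):
        n = len(res.atoms)
        area = float(areas[idx:idx + n].sum())
        idx += n
        ref = MAX_ASA.get(res.name)
        if ref is None:
            alone = Structure([copy.deepcopy(res)])
            ref = freeenergy.sasa_nonpolar(alone, params)[0]
        labels.append(res.seq_id)
        values.append(100.0 * area / ref if ref > 0 else 0.0)
    return pd.Series(values, index=pd.Index(labels, name="seq_id"))


def delta_asa(bound: Structure, reference_complex: Structure,
              params=None) -> pd.Series:
    """Per-residue change in %ASA, bound minus reference.

    Positive values mean the residue is more exposed in `bound`; negative
    means more buried. Both structures must carry the same residue set.
    """
    params = params or freeenergy.GBSAParams()
    pa = _percent_asa(bound, params)
    pb = _percent_asa(reference_complex, params)
    if not pa.index.equals(pb.index):
        raise ValueError("residue sets differ between bound and reference")
    out = pa - pb
    out.name = "delta_pct_asa"
    return out


# -- side-chain movement ---------------------------------------------------

def sidechain_movement(pose: Structure, reference: Structure,
                       threshold: float = 2.0) -> tuple[pd.Series, list[int]]:
    """Per-residue side-chain heavy-atom RMSD after backbone superposition.

    Returns the per-residue series and the residues moving more than
    `threshold` A. Residues with no shared side-chain heavy atoms are
    reported as NaN, not as failures.
    """
    fit_m = pose.select(BACKBONE_ATOMS)
    fit_r = reference.select(BACKBONE_ATOMS)
    if len(fit_m) < 3 or len(fit_m) != len(fit_r):
        fit_m = pose.select(None)
        fit_r = reference.select(None)
    if len(fit_m) == 0 or len(fit_m) != len(fit_r):
        raise SelectionError("cannot pair backbone atoms for superposition")
    tr, _ = kabsch(pose.get_coords()[fit_m], reference.get_coords()[fit_r])
    moved = tr.apply(pose.get_coords())
    ref = reference.get_coords()
    ref_index = {(r.chain_id, r.seq_id): r for r in reference.residues}
    ref_offsets = {}
    idx = 0
    for r in reference.residues:
        ref_offsets[(r.chain_id, r.seq_id)] = idx
        idx += len(r.atoms)
    labels, values = [], []
    idx = 0
    for res in pose.residues:
        atoms = res.atoms
        rres = ref_index.get((res.chain_id, res.seq_id))
        pairs = []
        if rres is not None:
            roff = ref_offsets[(res.chain_id, res.seq_id)]
            rnames = {a.name: roff + k for k, a in enumerate(rres.atoms)}
            for k, a in enumerate(atoms):
                if a.is_heavy and a.name not in BACKBONE_ATOMS and a.name in rnames:
                    pairs.append((idx + k, rnames[a.name]))
        idx += len(atoms)
        labels.append(res.seq_id)
        if not pairs:
            values.append(np.nan)
            continue
        mi = np.array([p[0] for p in pairs])
        ri = np.array([p[1] for p in pairs])
        values.append(float(np.sqrt(np.mean(
            np.sum((moved[mi] - ref[ri]) ** 2, axis=1)))))
    series = pd.Series(values, index=pd.Index(labels, name="seq_id"),
                       name="sidechain_rmsd")
    movers = [int(s) for s, v in series.items() if np.isfinite(v) and v > threshold]
    return series, movers


# -- molecular mimicry pairing ---------------------------------------------

def _interactions(receptor: Structure, partner: Structure,
                  criteria: HBondCriteria, cutoff: float
                  ) -> tuple[dict, dict]:
    """Receptor seq_id -> set of partner seq_ids, for H-bonds and contacts."""
    n_rec = len(receptor.residues)
    combined = Structure(
        [copy.deepcopy(r) for r in
         receptor.residues + partner.residues])
    rec_ids = list(range(n_rec))
    par_ids = list(range(n_rec, n_rec + len(partner.residues)))
    cmap = contact_map(combined, partner_split=(rec_ids, par_ids),
                       cutoff=cutoff)
    contacts: dict[int, set] = {}
    rec_seq = {r.seq_id for r in receptor.residues}
    for _, row in cmap.pairs.iterrows():
        if not row.contact:
            continue
        a, b = int(row.res_i), int(row.res_j)
        rec_side, par_side = (a, b) if a in rec_seq else (b, a)
        contacts.setdefault(rec_side, set()).add(par_side)
    traj = Trajectory(combined, [combined.get_coords()], np.array([0.0]))
    hb = hbond_occupancy(traj, criteria)
    hbonds: dict[int, set] = {}
    atoms = combined.atoms
    for _, row in hb[hb.occupancy > 0].iterrows():
        rd = combined.residues[atoms[int(row.donor_index)].residue_ref]
        ra = combined.residues[atoms[int(row.acceptor_index)].residue_ref]
        d_is_rec = combined.residues.index(rd) < n_rec
        a_is_rec = combined.residues.index(ra) < n_rec
        if d_is_rec == a_is_rec:
            continue
        rec_side = rd.seq_id if d_is_rec else ra.seq_id
        par_side = ra.seq_id if d_is_rec else rd.seq_id
        hbonds.setdefault(rec_side, set()).add(par_side)
    return hbonds, contacts


def mimicry_map(receptor: Structure, lid: Structure,
                reference_peptide: Structure,
                criteria: HBondCriteria | None = None,
                contact_cutoff: float = 4.2) -> pd.DataFrame:
    """Pair lid and reference-peptide interactions per receptor residue.

    For every receptor residue interacting with either partner, lists the
    reference-peptide residues and the lid residues it hydrogen-bonds or
    contacts, side by side. Empty when there are no interactions.
    """
    criteria = criteria or HBondCriteria()
    ref_hb, ref_ct = _interactions(receptor, reference_peptide, criteria,
                                   contact_cutoff)
    lid_hb, lid_ct = _interactions(receptor, lid, criteria, contact_cutoff)
    seqs = sorted(set(ref_hb) | set(ref_ct) | set(lid_hb) | set(lid_ct))

    def fmt(d, s):
        return ",".join(str(x) for x in sorted(d.get(s, ()))) or ""

    rows = [{"receptor_residue": s,
             "reference_hbond": fmt(ref_hb, s), "lid_hbond": fmt(lid_hb, s),
             "reference_contact": fmt(ref_ct, s), "lid_contact": fmt(lid_ct, s)}
            for s in seqs]
    return pd.DataFrame(rows, columns=["receptor_residue", "reference_hbond",
                                       "lid_hbond", "reference_contact",
                                       "lid_contact"])
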