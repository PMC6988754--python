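"""Pigment geometry: structure reading and the descriptor set.

Reads pigment structures (real LH2 PDB entries or the synthetic files
written by :mod:`lh2exciton.synthetic_ring`) and computes macrocycle
centers, center-center distances, the Forster orientation factor kappa,
torsion angles and hydrogen-bond distances, plus their distributions over
disorder ensembles.

Conventions: the macrocycle center is the arithmetic mean of the four
macrocycle nitrogen positions; the Q_y dipole axis is the unit vector from
N_B to N_D (standard BChl a convention; overridable per residue mapping);
torsions follow the IUPAC sign convention (cis = 0 deg, trans = 180 deg,
value in (-180, 180]).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic_ring import Ensemble, Frame, PigmentSite, pair_class

__all__ = [
    "SelectionRules",
    "GeometryDescriptors",
    "TorsionRecord",
    "read_structure",
    "macrocycle_center",
    "orientation_factor",
    "dihedral",
    "hbond_distance",
    "descriptor_distributions",
    "histogram_table",
]


@dataclass(frozen=True)
class GeometryDescriptors:
    """Distance/orientation descriptors of one pigment pair."""

    pair_id: tuple[int, int]
    distance: float                 # Angstrom, > 0
    kappa: float                    # dimensionless, in [-2, 2]
    pair_cls: str                   # inter_chain | intra_chain | other


@dataclass(frozen=True)
class TorsionRecord:
    """A signed torsion of one pigment, in degrees in (-180, 180]."""

    site_id: int
    dihedral_deg: float
    atom_quad: tuple[str, str, str, str]


@dataclass
class SelectionRules:
    """How pigment residues are selected and interpreted in a PDB file.

    ``resname_to_role`` maps residue names to the three site classes (the
    defaults cover the synthetic writer and the BCL/BCH heteroatom names of
    crystallographic LH2 entries, where roles must then be assigned by
    chain/sequence context via ``role_by_resseq``).  ``nitrogen_atoms`` are
    the four macrocycle N atom names; the dipole axis runs from
    ``dipole_atoms[0]`` to ``dipole_atoms[1]``.
    """

    resname_to_role: Mapping[str, str] = field(default_factory=lambda: {
        "BCA": "alpha", "BCB": "beta", "BC8": "b800"})
    nitrogen_atoms: tuple[str, str, str, str] = ("NA", "NB", "NC", "ND")
    dipole_atoms: tuple[str, str] = ("NB", "ND")
    dipole_magnitude: float = 6.3
    role_by_resseq: Mapping[int, str] | None = None


def macrocycle_center(n_positions: Sequence[np.ndarray]) -> np.ndarray:
    """Arithmetic mean of the four macrocycle nitrogen positions."""
    pos = np.asarray(n_positions, dtype=float)
    if pos.shape != (4, 3):
        raise ValueError(f"need exactly four 3-vectors, got shape {pos.shape}")
    return pos.mean(axis=0)


def orientation_factor(mu1: np.ndarray, mu2: np.ndarray,
                       r_vec: np.ndarray) -> float:
    """Forster orientation factor kappa = m1.m2 - 3 (m1.r)(m2.r).

    Inputs are normalized internally; the result lies in [-2, 2], is
    symmetric under swapping the dipoles and invariant to flipping r.
    """
    r = np.asarray(r_vec, dtype=float)
    rn = np.linalg.norm(r)
    if rn <= 0:
        raise ValueError("zero separation vector")
    m1 = np.asarray(mu1, float) / np.linalg.norm(mu1)
    m2 = np.asarray(mu2, float) / np.linalg.norm(mu2)
    rhat = r / rn
    return float(m1 @ m2 - 3.0 * (m1 @ rhat) * (m2 @ rhat))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed IUPAC torsion angle p1-p2-p3-p4 in degrees, in (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if b2n < 1e-12 or np.linalg.norm(b1) < 1e-12 or np.linalg.norm(b3) < 1e-12:
        raise ValueError("consecutive points coincide")
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("undefined torsion: three consecutive points are colinear")
    x = float(n1 @ n2)
    y = float(np.cross(n1, n2) @ b2) / b2n
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:      # atan2 returns [-180, 180]; wrap to (-180, 180]
        ang += 360.0
    return ang


def hbond_distance(donor_heavy: np.ndarray, acceptor_heavy: np.ndarray) -> float:
    """Heavy-atom donor-acceptor distance in Angstrom."""
    return float(np.linalg.norm(np.asarray(donor_heavy, float)
                                - np.asarray(acceptor_heavy, float)))


# --------------------------------------------------------------------------
# structure reading
# --------------------------------------------------------------------------

def read_structure(path: str | Path, selection_rules: SelectionRules | None = None,
                   site_energy_table: Mapping[str, float] | None = None,
                   n_units: int | None = None) -> Frame:
    """Read a PDB file into a Frame of pigment sites.

    One :class:`PigmentSite` per residue whose name appears in the
    selection rules: center from the four macrocycle N atoms, dipole along
    the configured axis.  Residues lacking any of the four N atoms raise a
    per-residue error naming the missing atoms; a file with no matching
    residues raises as well.  Site energies are not stored in PDB files;
    they are filled from ``site_energy_table`` (by role) or zero.
    """
    from Bio.PDB import PDBParser

    rules = selection_rules or SelectionRules()
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("x", str(path))

    records = []   # (resseq, role, center, dipole)
    for residue in structure.get_residues():
        resname = residue.get_resname().strip()
        if resname not in rules.resname_to_role:
            continue
        resseq = residue.get_id()[1]
        role = rules.resname_to_role[resname]
        if rules.role_by_resseq is not None:
            role = rules.role_by_resseq.get(resseq, role)
        atoms = {a.get_name(): np.array(a.get_coord(), dtype=float)
                 for a in residue.get_atoms()}
        missing = [n for n in rules.nitrogen_atoms if n not in atoms]
        if missing:
            raise ValueError(
                f"residue {resname} {resseq}: missing macrocycle atoms {missing}")
        center = macrocycle_center([atoms[n] for n in rules.nitrogen_atoms])
        axis = atoms[rules.dipole_atoms[1]] - atoms[rules.dipole_atoms[0]]
        norm = np.linalg.norm(axis)
        if norm < 1e-9:
            raise ValueError(f"residue {resname} {resseq}: degenerate dipole axis")
        dipole = rules.dipole_magnitude * axis / norm
        records.append((resseq, role, center, dipole))

    if not records:
        raise ValueError(f"{path}: no pigment residues matched the selection rules")

    records.sort(key=lambda r: r[0])
    energies = site_energy_table or {}
    sites = []
    n_b850 = sum(1 for r in records if r[1] in ("alpha", "beta"))
    if n_units is None:
        n_units = max(n_b850 // 2, 1)
    counters = {"b850": 0, "b800": 0}
    for resseq, role, center, dipole in records:
        if role in ("alpha", "beta"):
            unit = counters["b850"] // 2
            counters["b850"] += 1
        else:
            unit = counters["b800"]
            counters["b800"] += 1
        sites.append(PigmentSite(len(sites), unit, role, center, dipole,
                                 float(energies.get(role, 0.0))))
    return Frame(sites=sites, n_units=n_units)


# --------------------------------------------------------------------------
# ensemble descriptor distributions
# --------------------------------------------------------------------------

def pair_descriptors(frame: Frame, i: int, j: int) -> GeometryDescriptors:
    si, sj = frame.sites[i], frame.sites[j]
    r = sj.center - si.center
    return GeometryDescriptors(
        pair_id=(si.site_id, sj.site_id),
        distance=float(np.linalg.norm(r)),
        kappa=orientation_factor(si.dipole, sj.dipole, r),
        pair_cls=pair_class(si, sj, frame.n_units))


def descriptor_distributions(
        ensemble: Ensemble | Iterable[Frame],
        pair_classes: Sequence[str] = ("inter_chain", "intra_chain"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distance / kappa distributions of the adjacent B850 pairs.

    One row per frame per symmetry-equivalent pair of each requested class;
    returns ``(rows, summary)`` where ``summary`` holds per-class mean, SD
    and count for both descriptors.
    """
    known = {"inter_chain", "intra_chain", "other"}
    bad = set(pair_classes) - known
    if bad:
        raise ValueError(f"unknown pair class labels: {sorted(bad)}")
    frames = ensemble.frames if isinstance(ensemble, Ensemble) else list(ensemble)
    if not frames:
        raise ValueError("empty ensemble")

    rows = []
    for f_idx, frame in enumerate(frames):
        for i, j, cls in frame.adjacent_b850_pairs():
            if cls not in pair_classes:
                continue
            d = pair_descriptors(frame, i, j)
            rows.append((f_idx, d.pair_id[0], d.pair_id[1], cls,
                         d.distance, d.kappa))
    table = pd.DataFrame(rows, columns=["frame", "site_i", "site_j",
                                        "pair_cls", "distance", "kappa"])
    summary = table.groupby("pair_cls")[["distance", "kappa"]].agg(
        ["mean", "std", "count"])
    return table, summary


def histogram_table(values: np.ndarray, bins: int = 40,
                    value_range: tuple[float, float] | None = None) -> pd.DataFrame:
    """Histogram as a (bin_left, bin_right, count) table."""
    counts, edges = np.histogram(np.asarray(values, float), bins=bins,
                                 range=value_range)
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                         "count": counts})
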