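"""Synthetic LH2-like ring generator.

Builds ideal and statically disordered nonameric double rings (an 18-site
alternating alpha/beta B850-like ring plus a 9-site B800-like ring, 27
pigments in total), with per-class Gaussian site-energy disorder,
optionally correlated orientational jitter of the transition dipoles, and a
synthetic charge-transfer (CT) manifold over adjacent B850 pairs.  Every
downstream stage of the package (geometry descriptors, couplings, exciton
Hamiltonians, spectra, statistics) can be exercised on these ensembles
without any external structure file.

Geometry conventions: coordinates in Angstrom, right-handed axes, ring axis
along z; transition dipoles in Debye, in-plane and near-tangential with
alternating +/- offsets for the alpha/beta sites (the head-to-tail
arrangement that makes the k=+-1 pair of the 18-ring bright and red-most).

Random numbers: one ``numpy.random.Generator`` per ensemble, seeded once;
draws are made frame-by-frame, and within a frame in the documented order
(site energies site-major, then B850 jitter angles, then B800 jitter
angles, then radial displacements), so fixtures are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .parameters import CT_ALIGNMENT_SHIFT, ROLES, COMPLEX_PARAMS

__all__ = [
    "PigmentSite",
    "Frame",
    "Ensemble",
    "DisorderModel",
    "CTManifold",
    "build_ideal_ring",
    "sample_ensemble",
    "make_ct_manifold",
    "select_dimer_geometries",
    "plant_regression_data",
    "noise_sd_for_r2",
    "pair_class",
    "write_site_table",
    "read_site_table",
    "write_pdb",
    "write_manifest",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class PigmentSite:
    """One chromophore site of the ring aggregate.

    ``role`` determines ring membership: ``alpha``/``beta`` sites alternate
    on the 18-ring, ``b800`` sites form the 9-ring.  ``center`` is the
    macrocycle center (Angstrom), ``dipole`` the Q_y transition dipole
    (Debye) and ``site_energy`` the local excitation energy (cm^-1).
    """

    site_id: int
    unit: int
    role: str
    center: np.ndarray
    dipole: np.ndarray
    site_energy: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.dipole = np.asarray(self.dipole, dtype=float)
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if not np.linalg.norm(self.dipole) > 0:
            raise ValueError(f"site {self.site_id}: transition dipole must be non-zero")


@dataclass
class Frame:
    """A geometric + energetic snapshot of the pigment aggregate.

    Sites are stored in the canonical basis order used throughout the
    package: 18 B850 sites unit-major (alpha before beta), then the 9 B800
    sites.
    """

    sites: list[PigmentSite]
    n_units: int

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def centers(self) -> np.ndarray:
        return np.array([s.center for s in self.sites])

    @property
    def dipoles(self) -> np.ndarray:
        return np.array([s.dipole for s in self.sites])

    @property
    def site_energies(self) -> np.ndarray:
        return np.array([s.site_energy for s in self.sites])

    @property
    def roles(self) -> list[str]:
        return [s.role for s in self.sites]

    @property
    def b850_indices(self) -> list[int]:
        return [i for i, s in enumerate(self.sites) if s.role in ("alpha", "beta")]

    @property
    def b800_indices(self) -> list[int]:
        return [i for i, s in enumerate(self.sites) if s.role == "b800"]

    def b850_subframe(self) -> "Frame":
        """The 18-ring (or 2n-ring) alone, keeping site order."""
        sites = [replace(self.sites[i]) for i in self.b850_indices]
        return Frame(sites=sites, n_units=self.n_units)

    def adjacent_b850_pairs(self) -> list[tuple[int, int, str]]:
        """Adjacent pairs of the 2n-ring as (index_i, index_j, class).

        For every unit u there is one intra-chain pair (alpha_u, beta_u)
        and one inter-chain pair (beta_u, alpha_{u+1 mod n}).
        """
        n = self.n_units
        pairs = []
        for u in range(n):
            pairs.append((2 * u, 2 * u + 1, "intra_chain"))
            pairs.append((2 * u + 1, 2 * ((u + 1) % n), "inter_chain"))
        return pairs


def pair_class(site_i: PigmentSite, site_j: PigmentSite, n_units: int) -> str:
    """Classify a pigment pair as inter_chain / intra_chain / other.

    Intra-chain: the alpha and beta BChl of the same alpha/beta unit.
    Inter-chain: the beta BChl of unit u with the alpha BChl of unit u+1.
    Everything else (non-adjacent, or involving the B800 ring) is "other".
    """
    a, b = site_i, site_j
    if {a.role, b.role} != {"alpha", "beta"}:
        return "other"
    if a.role == "beta":
        a, b = b, a
    # a is alpha, b is beta
    if a.unit == b.unit:
        return "intra_chain"
    if a.unit == (b.unit + 1) % n_units:
        return "inter_chain"
    return "other"


@dataclass
class DisorderModel:
    """Static-disorder model for a ring ensemble.

    ``sigma_by_role`` are Gaussian site-energy standard deviations (cm^-1);
    defaults are the per-complex values observed over 50 trajectory frames.
    ``orient_jitter_deg`` is the SD of the azimuthal rigid jitter of each
    pigment: a rotation about the ring axis applied to both its center and
    its transition dipole.  On the 18-ring the jitter angles of the two
    partners of an intra-chain pair correlate with ``corr_intra`` and those
    of an inter-chain pair with ``corr_inter`` (emulating the tethering
    effect of the H-bond that links a beta BChl to the neighbouring unit:
    a perfectly correlated pair co-rotates rigidly, leaving its distance
    and orientation factor untouched, while uncorrelated partners change
    their mutual geometry).  ``radial_jitter_A`` is the SD of independent
    radial center displacement.
    """

    sigma_by_role: Mapping[str, float] = field(
        default_factory=lambda: dict(COMPLEX_PARAMS["LL"].site_energy_sd))
    orient_jitter_deg: float = 3.0
    radial_jitter_A: float = 0.3
    corr_intra: float = 1.0
    corr_inter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for role, sig in self.sigma_by_role.items():
            if sig < 0:
                raise ValueError(f"sigma for role {role!r} must be >= 0")
        for name in ("corr_intra", "corr_inter"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class CTManifold:
    """Synthetic charge-transfer manifold over adjacent B850 pairs.

    One CT state per transfer direction of every adjacent alpha/beta pair
    (alpha->beta and beta->alpha), i.e. 4n states for an n-unit ring.
    ``ct_energies`` already include ``alignment_shift``;
    ``le_ct_couplings`` maps (LE site_id, CT index) -> coupling (cm^-1).
    """

    ct_labels: list[tuple[int, int]]            # (donor site_id, acceptor site_id)
    ct_energies: np.ndarray                     # cm^-1, shape (n_ct,)
    le_ct_couplings: dict[tuple[int, int], float]
    alignment_shift: float = CT_ALIGNMENT_SHIFT

    @property
    def n_ct(self) -> int:
        return len(self.ct_labels)


# --------------------------------------------------------------------------
# ideal ring construction
# --------------------------------------------------------------------------

def build_ideal_ring(
    n_units: int = 9,
    radius_b850: float = 26.0,
    radius_b800: float = 31.0,
    dipole_magnitude: float = 6.3,
    tangent_offsets_deg: tuple[float, float] = (10.0, -10.0),
    site_energy_table: Mapping[str, float] | None = None,
    z_b800: float = -16.0,
    include_b800: bool = True,
) -> Frame:
    """Build an ideal C_n double ring of 3*n_units pigments.

    The 2n B850-like sites alternate alpha/beta on a circle of radius
    ``radius_b850`` in the z=0 plane, equally spaced; their dipoles are
    in-plane, tangential, rotated in-plane by ``tangent_offsets_deg[0]``
    (alpha) or ``[1]`` (beta).  The n B800-like sites sit on a circle of
    radius ``radius_b800`` displaced along z, with tangential dipoles.
    The construction has exact n-fold rotational symmetry about z.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    if radius_b850 <= 0 or radius_b800 <= 0:
        raise ValueError("ring radii must be positive")
    if dipole_magnitude <= 0:
        raise ValueError("dipole magnitude must be positive")
    energies = dict(COMPLEX_PARAMS["HL"].site_energies)
    if site_energy_table is not None:
        energies.update(site_energy_table)

    sites: list[PigmentSite] = []
    dphi = 2.0 * math.pi / (2 * n_units)      # angular spacing on the 2n-ring
    for u in range(n_units):
        for sub, (role, off_deg) in enumerate(
                zip(("alpha", "beta"), tangent_offsets_deg)):
            k = 2 * u + sub
            phi = k * dphi
            center = np.array([radius_b850 * math.cos(phi),
                               radius_b850 * math.sin(phi), 0.0])
            ang = phi + math.pi / 2.0 + math.radians(off_deg)
            dipole = dipole_magnitude * np.array(
                [math.cos(ang), math.sin(ang), 0.0])
            sites.append(PigmentSite(k, u, role, center, dipole, energies[role]))
    if include_b800:
        for u in range(n_units):
            phi = u * 2.0 * math.pi / n_units
            center = np.array([radius_b800 * math.cos(phi),
                               radius_b800 * math.sin(phi), z_b800])
            ang = phi + math.pi / 2.0
            dipole = dipole_magnitude * np.array(
                [math.cos(ang), math.sin(ang), 0.0])
            sites.append(PigmentSite(2 * n_units + u, u, "b800",
                                     center, dipole, energies["b800"]))
    return Frame(sites=sites, n_units=n_units)


# --------------------------------------------------------------------------
# disordered ensembles
# --------------------------------------------------------------------------

def _jitter_correlation_matrix(n_units: int, rho_intra: float,
                               rho_inter: float) -> np.ndarray:
    """Correlation matrix of the 2n B850 jitter angles.

    Alternating intra/inter correlations on the ring, zero elsewhere.  Not
    every (rho_intra, rho_inter) pair is positive semidefinite; negative
    eigenvalues are clipped to zero (nearest-PSD projection) before the
    matrix square root is taken.
    """
    n = 2 * n_units
    corr = np.eye(n)
    for u in range(n_units):
        a, b, a_next = 2 * u, 2 * u + 1, 2 * ((u + 1) % n_units)
        corr[a, b] = corr[b, a] = rho_intra
        corr[b, a_next] = corr[a_next, b] = rho_inter
    return corr


def _correlated_normal_transform(corr: np.ndarray) -> np.ndarray:
    """Matrix L with L L^T = corr (after PSD projection)."""
    w, v = np.linalg.eigh(corr)
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


def _rotate_inplane(vec: np.ndarray, angle_rad: float) -> np.ndarray:
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    x, y, z = vec
    return np.array([c * x - s * y, s * x + c * y, z])


@dataclass
class Ensemble:
    """A set of disorder realizations of a base frame, with provenance."""

    frames: list[Frame]
    base_frame: Frame
    disorder: DisorderModel
    seed: int
    jitter_angles_deg: np.ndarray = field(default=None, repr=False)  # (n_frames, n_sites)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_units(self) -> int:
        return self.base_frame.n_units


def sample_ensemble(base_frame: Frame, disorder: DisorderModel,
                    n_frames: int = 50, seed: int | None = None) -> Ensemble:
    """Draw ``n_frames`` independent static-disorder realizations.

    Per frame: site energies from role-specific Gaussians (independent,
    site-major order), azimuthal rigid-jitter angles with the configured
    intra/inter correlation on the B850 ring (B800 angles independent),
    and independent radial center displacements.  Deterministic under a
    fixed seed.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    used_seed = disorder.seed if seed is None else seed
    rng = np.random.default_rng(used_seed)

    n_sites = len(base_frame)
    nb850 = len(base_frame.b850_indices)
    transform = _correlated_normal_transform(
        _jitter_correlation_matrix(base_frame.n_units,
                                   disorder.corr_intra, disorder.corr_inter))
    sigma_rot = math.radians(disorder.orient_jitter_deg)

    frames: list[Frame] = []
    all_angles = np.zeros((n_frames, n_sites))
    for f in range(n_frames):
        energies = np.array([
            s.site_energy + rng.normal(0.0, disorder.sigma_by_role.get(s.role, 0.0))
            if disorder.sigma_by_role.get(s.role, 0.0) > 0 else s.site_energy
            for s in base_frame.sites])
        angles = np.zeros(n_sites)
        if sigma_rot > 0:
            angles[:nb850] = sigma_rot * (transform @ rng.standard_normal(nb850))
            angles[nb850:] = sigma_rot * rng.standard_normal(n_sites - nb850)
        radial = (rng.normal(0.0, disorder.radial_jitter_A, size=n_sites)
                  if disorder.radial_jitter_A > 0 else np.zeros(n_sites))

        sites = []
        for i, s in enumerate(base_frame.sites):
            # azimuthal rigid jitter: rotate center and dipole together
            center = _rotate_inplane(s.center, angles[i])
            rho = np.hypot(center[0], center[1])
            if rho > 0 and radial[i] != 0.0:
                center[:2] *= (rho + radial[i]) / rho
            dipole = _rotate_inplane(s.dipole, angles[i])
            sites.append(PigmentSite(s.site_id, s.unit, s.role,
                                     center, dipole, float(energies[i])))
        frames.append(Frame(sites=sites, n_units=base_frame.n_units))
        all_angles[f] = np.degrees(angles)
    return Ensemble(frames=frames, base_frame=base_frame, disorder=disorder,
                    seed=used_seed, jitter_angles_deg=all_angles)


# --------------------------------------------------------------------------
# CT manifold
# --------------------------------------------------------------------------

def make_ct_manifold(
    ring: Frame,
    energy_mean: float | None = None,
    energy_sd: float = 0.0,
    coupling_table: Mapping[tuple[int, int], float] | None = None,
    default_coupling: float = 250.0,
    alignment_shift: float = CT_ALIGNMENT_SHIFT,
    seed: int | None = None,
) -> CTManifold:
    """Build the synthetic CT manifold of a ring frame.

    Two CT states per adjacent alpha/beta pair of the 2n-ring (both
    transfer directions), i.e. 4n states for an n-unit ring.  Unless
    overridden, ``energy_mean`` is chosen so the shifted CT energies sit
    2000 cm^-1 above the highest LE site energy (CT states lie above the
    Q_y excitations).  ``coupling_table`` maps (LE site_id, CT index) to a
    coupling; by default each CT state couples to its donor and acceptor LE
    with ``default_coupling``.  Entries referencing a non-adjacent pair
    raise a ValueError.
    """
    b850 = ring.b850_indices
    if len(b850) < 2:
        raise ValueError("ring must contain an alpha/beta subring")
    adj = ring.adjacent_b850_pairs()
    labels: list[tuple[int, int]] = []
    for i, j, _cls in adj:
        di, dj = ring.sites[i].site_id, ring.sites[j].site_id
        labels.append((di, dj))
        labels.append((dj, di))

    max_le = float(np.max(ring.site_energies))
    if energy_mean is None:
        energy_mean = max_le + 2000.0 - alignment_shift
    rng = np.random.default_rng(seed)
    energies = energy_mean + alignment_shift + (
        rng.normal(0.0, energy_sd, size=len(labels)) if energy_sd > 0
        else np.zeros(len(labels)))

    couplings: dict[tuple[int, int], float] = {}
    if coupling_table is None:
        for m, (don, acc) in enumerate(labels):
            couplings[(don, m)] = default_coupling
            couplings[(acc, m)] = default_coupling
    else:
        for (le_id, m), v in coupling_table.items():
            if not (0 <= m < len(labels)):
                raise ValueError(f"CT index {m} out of range")
            if le_id not in labels[m]:
                raise ValueError(
                    f"coupling table entry ({le_id}, {m}) does not reference "
                    f"the adjacent pair {labels[m]}")
            couplings[(le_id, m)] = float(v)
    return CTManifold(ct_labels=labels, ct_energies=np.asarray(energies),
                      le_ct_couplings=couplings, alignment_shift=alignment_shift)


def select_dimer_geometries(ensemble: Ensemble, pair_cls: str,
                            n_frames: int = 10) -> list[tuple[np.ndarray, np.ndarray]]:
    """All symmetry copies of one adjacent-dimer class over the first frames.

    Returns one (centers, dipoles) coordinate pair per symmetry-equivalent
    dimer per frame: an n-unit ring contributes n copies per class, so 10
    frames of a nonameric ring give 90 dimer geometries per class.
    """
    if pair_cls not in ("inter_chain", "intra_chain"):
        raise ValueError(f"unknown pair class {pair_cls!r}")
    if n_frames > ensemble.n_frames:
        raise ValueError("ensemble has fewer frames than requested")
    out = []
    for frame in ensemble.frames[:n_frames]:
        for i, j, cls in frame.adjacent_b850_pairs():
            if cls == pair_cls:
                out.append((np.array([frame.sites[i].center, frame.sites[j].center]),
                            np.array([frame.sites[i].dipole, frame.sites[j].dipole])))
    return out


# --------------------------------------------------------------------------
# planted regression data
# --------------------------------------------------------------------------

def plant_regression_data(
    n_bonds: int,
    coeffs: Sequence[float],
    noise_sd: float,
    n_samples: int,
    seed: int | None = None,
    intercept: float = 13500.0,
    length_mean: float = 1.40,
    length_sd: float = 0.02,
):
    """Plant a linear bond-length -> excitation-energy dataset.

    Bond lengths are independent Gaussians (Angstrom); energies are
    ``intercept + X @ coeffs + N(0, noise_sd)`` (cm^-1).  Returns the data
    as a pandas DataFrame (columns ``bond_00.. , energy``) together with
    the generating parameters, for recovery tests.
    """
    import pandas as pd

    coeffs = np.asarray(coeffs, dtype=float)
    if len(coeffs) != n_bonds:
        raise ValueError("need one coefficient per bond")
    if n_samples <= n_bonds:
        raise ValueError("n_samples must exceed n_bonds")
    rng = np.random.default_rng(seed)
    X = rng.normal(length_mean, length_sd, size=(n_samples, n_bonds))
    noise = rng.normal(0.0, noise_sd, size=n_samples) if noise_sd > 0 else 0.0
    y = intercept + X @ coeffs + noise
    cols = [f"bond_{b:02d}" for b in range(n_bonds)]
    table = pd.DataFrame(X, columns=cols)
    table["energy"] = y
    truth = {"intercept": intercept, "coeffs": coeffs,
             "noise_sd": noise_sd, "length_sd": length_sd}
    return table, truth


def noise_sd_for_r2(coeffs: Sequence[float], length_sd: float,
                    r2: float) -> float:
    """Noise SD giving an asymptotic planted R^2 for independent bonds.

    var(signal) = length_sd^2 * sum(coeff^2); R^2 = var(signal)/var(total).
    """
    if not 0 < r2 < 1:
        raise ValueError("r2 must be in (0, 1)")
    var_signal = float(length_sd**2 * np.sum(np.square(coeffs)))
    return math.sqrt(var_signal * (1.0 - r2) / r2)


# --------------------------------------------------------------------------
# plain-text writers / readers
# --------------------------------------------------------------------------

_SITE_COLS = ("site_id", "unit", "role", "x", "y", "z",
              "mux", "muy", "muz", "E")


def write_site_table(frame: Frame, path: str | Path) -> None:
    """Tab-separated site table: site_id, unit, role, center, dipole, E."""
    lines = ["\t".join(_SITE_COLS)]
    for s in frame.sites:
        lines.append("\t".join(
            [str(s.site_id), str(s.unit), s.role]
            + [f"{v:.6f}" for v in (*s.center, *s.dipole, s.site_energy)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_site_table(path: str | Path, n_units: int | None = None) -> Frame:
    text = Path(path).read_text().strip().splitlines()
    if text[0].split("\t") != list(_SITE_COLS):
        raise ValueError(f"{path}: not a site table")
    sites = []
    for line in text[1:]:
        f = line.split("\t")
        sites.append(PigmentSite(int(f[0]), int(f[1]), f[2],
                                 np.array([float(v) for v in f[3:6]]),
                                 np.array([float(v) for v in f[6:9]]),
                                 float(f[9])))
    if n_units is None:
        n_units = max(s.unit for s in sites) + 1
    return Frame(sites=sites, n_units=n_units)


# Residue names used for the synthetic PDB representation of each role.
PDB_RESNAMES = {"alpha": "BCA", "beta": "BCB", "b800": "BC8"}

#: half-diagonal of the pseudo macrocycle square (Angstrom)
_N_HALF_SPAN = 2.05


def _macrocycle_pseudo_atoms(site: PigmentSite) -> list[tuple[str, np.ndarray]]:
    """Pseudo-atom positions encoding center and dipole axis.

    Four N pseudo-atoms at center +- span along the dipole axis (NB -> ND)
    and the in-plane perpendicular (NA/NC), so that their mean is the
    macrocycle center and the NB->ND axis is the Q_y direction; plus two
    explicit dipole-axis markers DX1/DX2.
    """
    mu_hat = site.dipole / np.linalg.norm(site.dipole)
    # in-plane perpendicular; fall back to any perpendicular for axial dipoles
    perp = np.array([-mu_hat[1], mu_hat[0], 0.0])
    if np.linalg.norm(perp) < 1e-12:
        perp = np.array([1.0, 0.0, 0.0])
    perp = perp / np.linalg.norm(perp)
    c = site.center
    return [
        ("NA", c + _N_HALF_SPAN * perp),
        ("NB", c - _N_HALF_SPAN * mu_hat),
        ("NC", c - _N_HALF_SPAN * perp),
        ("ND", c + _N_HALF_SPAN * mu_hat),
        ("DX1", c - 3.0 * mu_hat),
        ("DX2", c + 3.0 * mu_hat),
    ]


def write_pdb(frame: Frame, path: str | Path) -> None:
    """Write the frame as a standard PDB of HETATM pseudo-atom records.

    One residue per pigment (resname BCA/BCB/BC8 by role, resSeq =
    site_id + 1), holding the four macrocycle N pseudo-atoms and two
    dipole-axis pseudo-atoms.  Site energies are not representable in PDB
    fields; use the site table for energy round-trips.
    """
    lines = []
    serial = 1
    for s in frame.sites:
        resname = PDB_RESNAMES[s.role]
        for name, pos in _macrocycle_pseudo_atoms(s):
            element = name[0] if name[0] != "D" else "X"
            lines.append(
                f"HETATM{serial:5d} {name:<4s} {resname:>3s} A{s.site_id + 1:4d}"
                f"    {pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {element:>2s}")
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_manifest(path: str | Path, **params) -> None:
    """Plain-text key=value manifest recording generator parameters."""
    lines = [f"{k}={v}" for k, v in sorted(params.items())]
    Path(path).write_text("\n".join(lines) + "\n")
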