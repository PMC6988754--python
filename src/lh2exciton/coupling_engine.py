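"""Pairwise electronic couplings with classical polarizable screening.

Three levels of coupling between pigment Q_y transitions are provided:

* the point-dipole (Forster) estimate ``V = C kappa |mu_i||mu_j| / r^3``;
* the Coulomb interaction of transition-charge sets (point charges
  standing in for the transition densities of the two pigments);
* an environment term from a classical induced-point-dipole model: the
  transition charges of one pigment polarize a set of isotropic
  polarizable sites and the induced dipoles interact with the partner's
  transition field, screening (or enhancing) the bare Coulomb coupling.

Unit system: charges in elementary charges, positions in Angstrom, dipoles
in Debye, polarizabilities in Angstrom^3, couplings in cm^-1.  The
conversion constants are derived from CODATA values at import time.

Sign convention for the environment term (documented, not universal):
``v_env = -sum_k mu_ind,k(rho_j) . E_i(r_k)``, which reduces the coupling
for two parallel transition dipoles with polarizable matter between them.
Only the reciprocity (i <-> j symmetry) of the term is guaranteed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import constants as _const

from .synthetic_ring import Frame, PigmentSite, pair_class

__all__ = [
    "K_EE_CM1", "K_DD_CM1", "DEBYE_EA",
    "TransitionChargeSet", "PolarizableSite", "CouplingRecord",
    "point_dipole_coupling", "transition_charge_coupling",
    "solve_induced_dipoles", "solve_induced_dipoles_direct",
    "environment_screening", "couple_frame",
]

# e^2/(4 pi eps0) over 1 Angstrom, expressed in cm^-1  (~116141)
K_EE_CM1 = (_const.e**2 / (4.0 * math.pi * _const.epsilon_0)
            / 1e-10 / (_const.h * _const.c * 100.0))
# 1 Debye in e*Angstrom (~0.20819)
DEBYE_EA = 1e-21 / _const.c / _const.e / 1e-10
# dipole-dipole prefactor, cm^-1 * Angstrom^3 / Debye^2  (~5034.1)
K_DD_CM1 = K_EE_CM1 * DEBYE_EA**2


@dataclass
class TransitionChargeSet:
    """Point charges approximating one pigment's transition density."""

    site_id: int
    positions: np.ndarray          # (n, 3) Angstrom
    charges: np.ndarray            # (n,) elementary charges

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        self.charges = np.atleast_1d(np.asarray(self.charges, float))
        if len(self.positions) != len(self.charges):
            raise ValueError("positions and charges must have equal length")
        if not np.all(np.isfinite(self.charges)):
            raise ValueError("charges must be finite")

    @classmethod
    def from_site(cls, site: PigmentSite, separation: float = 1.0
                  ) -> "TransitionChargeSet":
        """A +/-q pair along the dipole axis reproducing |mu|.

        q = |mu| (in e*Angstrom) / separation; the pair is centered on the
        macrocycle center.
        """
        mu = np.linalg.norm(site.dipole)
        mu_hat = site.dipole / mu
        q = mu * DEBYE_EA / separation
        half = 0.5 * separation * mu_hat
        return cls(site_id=site.site_id,
                   positions=np.array([site.center + half, site.center - half]),
                   charges=np.array([q, -q]))

    def field_at(self, points: np.ndarray) -> np.ndarray:
        """Electric field (e / Angstrom^2) of the charge set at points."""
        pts = np.atleast_2d(np.asarray(points, float))
        dr = pts[:, None, :] - self.positions[None, :, :]      # (m, n, 3)
        r = np.linalg.norm(dr, axis=-1)
        if np.any(r < 1e-9):
            raise ValueError("field requested at a charge position")
        return np.einsum("mn,mnk->mk", self.charges / r**3, dr)


@dataclass
class PolarizableSite:
    """An isotropically polarizable point, optionally carrying a charge."""

    position: np.ndarray           # Angstrom
    alpha: float                   # Angstrom^3
    charge: float = 0.0            # e

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.alpha < 0:
            raise ValueError("polarizability must be >= 0")


@dataclass(frozen=True)
class CouplingRecord:
    """One pigment pair's coupling decomposition (cm^-1)."""

    pair_id: tuple[int, int]
    v_coul: float
    v_env: float
    pair_cls: str

    @property
    def v_total(self) -> float:
        return self.v_coul + self.v_env


# --------------------------------------------------------------------------
# bare Coulomb couplings
# --------------------------------------------------------------------------

def point_dipole_coupling(site_i: PigmentSite, site_j: PigmentSite) -> float:
    """Point-dipole coupling C kappa |mu_i||mu_j| / r^3 in cm^-1."""
    r_vec = site_j.center - site_i.center
    r = np.linalg.norm(r_vec)
    if r <= 0:
        raise ValueError("coincident pigment centers")
    mi, mj = np.linalg.norm(site_i.dipole), np.linalg.norm(site_j.dipole)
    m1, m2, rhat = site_i.dipole / mi, site_j.dipole / mj, r_vec / r
    kappa = float(m1 @ m2 - 3.0 * (m1 @ rhat) * (m2 @ rhat))
    return K_DD_CM1 * kappa * mi * mj / r**3


def transition_charge_coupling(tq_i: TransitionChargeSet,
                               tq_j: TransitionChargeSet) -> float:
    """Coulomb coupling sum_ab q_a q_b / r_ab of two charge sets, in cm^-1."""
    if tq_i.site_id == tq_j.site_id:
        raise ValueError("charge sets must belong to distinct pigments")
    dr = tq_i.positions[:, None, :] - tq_j.positions[None, :, :]
    r = np.linalg.norm(dr, axis=-1)
    if np.any(r < 1e-9):
        raise ValueError("coincident positions across the two charge sets")
    return K_EE_CM1 * float(np.sum(np.outer(tq_i.charges, tq_j.charges) / r))


# --------------------------------------------------------------------------
# induced-dipole solver
# --------------------------------------------------------------------------

def _dipole_field_tensor(positions: np.ndarray, thole_a: float | None = None
                         ) -> np.ndarray:
    """Pairwise dipole-field tensor T with T[k, l] a 3x3 block (l != k).

    E_at_k = T[k, l] @ mu_l.  Optional Thole-style exponential damping for
    numerically close site pairs (``thole_a`` is the dimensionless damping
    length in units of the separation; None disables damping).
    """
    n = len(positions)
    T = np.zeros((n, n, 3, 3))
    for k in range(n):
        for l in range(n):
            if l == k:
                continue
            dr = positions[k] - positions[l]
            r = np.linalg.norm(dr)
            if r < 1e-9:
                raise ValueError("coincident polarizable sites")
            nhat = dr / r
            lam3 = lam5 = 1.0
            if thole_a is not None:
                u = r / thole_a
                lam3 = 1.0 - math.exp(-u**3)
                lam5 = 1.0 - (1.0 + u**3) * math.exp(-u**3)
            T[k, l] = (3.0 * lam5 * np.outer(nhat, nhat)
                       - lam3 * np.eye(3)) / r**3
    return T


def _source_field(pol_sites: Sequence[PolarizableSite],
                  sources: Iterable[TransitionChargeSet]) -> np.ndarray:
    pts = np.array([p.position for p in pol_sites])
    E0 = np.zeros((len(pol_sites), 3))
    for src in sources:
        E0 += src.field_at(pts)
    return E0


def solve_induced_dipoles(
    pol_sites: Sequence[PolarizableSite],
    external_field_sources: Iterable[TransitionChargeSet],
    tolerance: float = 1e-8,
    max_iter: int = 500,
    omega: float = 0.7,
    thole_a: float | None = None,
) -> np.ndarray:
    """Self-consistent induced dipoles mu_k = alpha_k E_tot(r_k), in e*Angstrom.

    Jacobi iteration with successive over-relaxation (mixing ``omega``);
    convergence on the maximum per-site dipole change expressed in Debye
    falling below ``tolerance``.  Raises on non-convergence, carrying the
    last residual.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if not pol_sites:
        return np.zeros((0, 3))
    alphas = np.array([p.alpha for p in pol_sites])
    E0 = _source_field(pol_sites, external_field_sources)
    if np.all(alphas == 0):
        return np.zeros((len(pol_sites), 3))
    T = _dipole_field_tensor(np.array([p.position for p in pol_sites]), thole_a)
    mu = alphas[:, None] * E0
    for _ in range(max_iter):
        E_ind = np.einsum("klij,lj->ki", T, mu)
        mu_new = (1.0 - omega) * mu + omega * alphas[:, None] * (E0 + E_ind)
        resid = float(np.max(np.abs(mu_new - mu))) / DEBYE_EA
        mu = mu_new
        if resid < tolerance:
            return mu
    raise RuntimeError(
        f"induced-dipole solver did not converge in {max_iter} iterations "
        f"(last residual {resid:.3e} D)")


def solve_induced_dipoles_direct(
    pol_sites: Sequence[PolarizableSite],
    external_field_sources: Iterable[TransitionChargeSet],
    thole_a: float | None = None,
) -> np.ndarray:
    """Direct dense linear solve of the same self-consistent system.

    Solves (I - A T) mu = A E0 with A = diag(alpha); used as the oracle
    for the iterative solver and for small systems.
    """
    if not pol_sites:
        return np.zeros((0, 3))
    n = len(pol_sites)
    alphas = np.array([p.alpha for p in pol_sites])
    E0 = _source_field(pol_sites, external_field_sources)
    T = _dipole_field_tensor(np.array([p.position for p in pol_sites]), thole_a)
    Tm = T.transpose(0, 2, 1, 3).reshape(3 * n, 3 * n)
    A = np.repeat(alphas, 3)
    M = np.eye(3 * n) - A[:, None] * Tm
    try:
        mu = np.linalg.solve(M, A * E0.ravel())
    except np.linalg.LinAlgError as err:
        raise RuntimeError(f"singular polarization response: {err}") from err
    return mu.reshape(n, 3)


def environment_screening(
    tq_i: TransitionChargeSet,
    tq_j: TransitionChargeSet,
    pol_sites: Sequence[PolarizableSite],
    tolerance: float = 1e-8,
    method: str = "iterative",
    thole_a: float | None = None,
) -> float:
    """Environment (screening) term of the coupling, in cm^-1.

    v_env = -sum_k mu_ind,k(rho_j) . E_i(r_k): the dipoles induced by the
    transition of pigment j interact with the transition field of pigment
    i.  Symmetric under i <-> j to within solver tolerance (linear-response
    reciprocity).
    """
    if not pol_sites:
        return 0.0
    if method == "iterative":
        mu = solve_induced_dipoles(pol_sites, [tq_j], tolerance=tolerance,
                                   thole_a=thole_a)
    elif method == "direct":
        mu = solve_induced_dipoles_direct(pol_sites, [tq_j], thole_a=thole_a)
    else:
        raise ValueError(f"unknown solver method {method!r}")
    pts = np.array([p.position for p in pol_sites])
    E_i = tq_i.field_at(pts)
    return -K_EE_CM1 * float(np.sum(mu * E_i))


# --------------------------------------------------------------------------
# frame driver
# --------------------------------------------------------------------------

def couple_frame(
    frame: Frame,
    method: str = "transition_charge",
    pol_environment: Sequence[PolarizableSite] | None = None,
    cutoff: float | None = None,
    tq_separation: float = 1.0,
) -> list[CouplingRecord]:
    """Couplings for all pigment pairs of a frame within ``cutoff`` Angstrom.

    ``method`` is ``point_dipole`` or ``transition_charge``; with a
    polarizable environment the screening term is evaluated per pair from
    transition-charge fields.  Records are ordered by (i, j) with i < j
    and carry the inter/intra-chain classification.
    """
    if method not in ("point_dipole", "transition_charge"):
        raise ValueError(f"unknown coupling method {method!r}")
    n = len(frame)
    tqs = None
    if method == "transition_charge" or pol_environment:
        tqs = [TransitionChargeSet.from_site(s, separation=tq_separation)
               for s in frame.sites]
    records = []
    for i in range(n):
        for j in range(i + 1, n):
            si, sj = frame.sites[i], frame.sites[j]
            r = float(np.linalg.norm(sj.center - si.center))
            if cutoff is not None and r > cutoff:
                continue
            if method == "point_dipole":
                v_coul = point_dipole_coupling(si, sj)
            else:
                v_coul = transition_charge_coupling(tqs[i], tqs[j])
            v_env = 0.0
            if pol_environment:
                v_env = environment_screening(tqs[i], tqs[j], pol_environment)
            records.append(CouplingRecord(
                pair_id=(si.site_id, sj.site_id), v_coul=v_coul, v_env=v_env,
                pair_cls=pair_class(si, sj, frame.n_units)))
    return records


def write_coupling_table(records: Sequence[CouplingRecord], path,
                         frame_index: int = 0) -> None:
    """Tab-separated coupling table (frame, i, j, class, v_coul, v_env, v_total)."""
    from pathlib import Path

    lines = ["frame\ti\tj\tclass\tv_coul\tv_env\tv_total"]
    for r in records:
        lines.append(f"{frame_index}\t{r.pair_id[0]}\t{r.pair_id[1]}\t"
                     f"{r.pair_cls}\t{r.v_coul:.6f}\t{r.v_env:.6f}\t{r.v_total:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")
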