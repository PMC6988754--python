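"""Frenkel + charge-transfer exciton Hamiltonian of the LH2 rings.

The model Hamiltonian is block-structured: a locally-excited (LE) block
with the site energies eps_i on the diagonal and the electronic couplings
V_ij off-diagonal, a diagonal CT block with the (aligned) CT energies, and
an LE-CT off-diagonal block with the LE-CT couplings; CT-CT couplings are
zero.  This module assembles the matrix per frame, averages it over frames
and over the C_n symmetry orbits of the ring, diagonalizes it, assigns
ring quantum numbers k by Fourier analysis of the eigenvectors, and
derives the exciton observables: the exciton width (energy difference
between the k = +-8 and k = +-1 pairs of the 18-ring), the bright/dark
census, and CT-induced energy shifts.

Basis order (fixed): 2n B850 sites unit-major (alpha before beta), then n
B800 sites, then CT states.

Sign convention for printed coupling tables: published LH2 coupling values
are positive, but the optically bright, red-most pair of the B850 band is
conventionally labelled k = +-1, which requires the band minimum at small
|k|.  The per-site sign of the basis functions is a gauge: flipping every
beta-site sign negates both nearest-neighbor couplings and leaves all
observables except the k labels unchanged.  Builders taking printed
magnitudes therefore apply the physical (negative, head-to-tail) gauge by
default so the k labels match the usual convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .parameters import COMPLEX_PARAMS, ComplexParameters
from .synthetic_ring import CTManifold, Frame
from .coupling_engine import CouplingRecord

__all__ = [
    "ExcitonHamiltonian", "ExcitonStates",
    "assemble_hamiltonian", "hamiltonian_from_frame",
    "nearest_neighbor_ring_hamiltonian", "tabulated_hamiltonian",
    "symmetry_average", "diagonalize", "assign_k",
    "exciton_width", "bright_dark_census", "ct_shift",
    "ring_permutation",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class ExcitonHamiltonian:
    """The LE+CT block Hamiltonian with its basis bookkeeping.

    ``le_meta`` carries (site_id, unit, role) per LE basis index;
    ``ct_labels`` the (donor, acceptor) site ids per CT basis function.
    """

    matrix: np.ndarray
    le_meta: list[tuple[int, int, str]]
    n_units: int
    ct_labels: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.n_le + self.n_ct
        if self.matrix.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match basis size {n}")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-9):
            raise ValueError("Hamiltonian must be symmetric (within 1e-9 cm^-1)")

    @property
    def n_le(self) -> int:
        return len(self.le_meta)

    @property
    def n_ct(self) -> int:
        return len(self.ct_labels)

    @property
    def basis_labels(self) -> list[tuple[str, int]]:
        return ([("LE", sid) for sid, _, _ in self.le_meta]
                + [("CT", m) for m in range(self.n_ct)])

    @property
    def le_block(self) -> np.ndarray:
        return self.matrix[:self.n_le, :self.n_le]

    def copy(self) -> "ExcitonHamiltonian":
        return ExcitonHamiltonian(self.matrix.copy(), list(self.le_meta),
                                  self.n_units, list(self.ct_labels))

    def le_pair_class(self, i: int, j: int) -> str:
        """inter_chain / intra_chain / other for two LE basis indices."""
        (_, ui, ri), (_, uj, rj) = self.le_meta[i], self.le_meta[j]
        if {ri, rj} != {"alpha", "beta"}:
            return "other"
        if ri == "beta":
            ui, ri, uj, rj = uj, rj, ui, ri
        if ui == uj:
            return "intra_chain"
        if ui == (uj + 1) % self.n_units:
            return "inter_chain"
        return "other"

    def write(self, path: str | Path) -> None:
        """Tab-separated dense matrix with a basis-label header line."""
        header = "\t".join(f"{kind}:{idx}" for kind, idx in self.basis_labels)
        body = "\n".join("\t".join(f"{v:.8f}" for v in row)
                         for row in self.matrix)
        Path(path).write_text(header + "\n" + body + "\n")


@dataclass
class ExcitonStates:
    """Eigen-decomposition of an exciton Hamiltonian with observables."""

    energies: np.ndarray              # ascending, cm^-1
    coefficients: np.ndarray          # columns are states, orthonormal
    state_dipoles: np.ndarray         # (n, 3) Debye
    dipole_strengths: np.ndarray      # Debye^2
    hamiltonian: ExcitonHamiltonian
    k_labels: np.ndarray | None = None   # signed ints; -999 marks undefined
    band: list[str] | None = None

    UNDEFINED_K = -999

    @property
    def n_states(self) -> int:
        return len(self.energies)


# --------------------------------------------------------------------------
# assembly
# --------------------------------------------------------------------------

def _default_le_meta(n_units: int, include_b800: bool) -> list[tuple[int, int, str]]:
    meta = []
    for u in range(n_units):
        meta.append((2 * u, u, "alpha"))
        meta.append((2 * u + 1, u, "beta"))
    if include_b800:
        for u in range(n_units):
            meta.append((2 * n_units + u, u, "b800"))
    return meta


def assemble_hamiltonian(
    site_energies: Sequence[float],
    couplings: Mapping[tuple[int, int], float] | Sequence[CouplingRecord],
    ct_manifold: CTManifold | None = None,
    le_meta: Sequence[tuple[int, int, str]] | None = None,
    n_units: int = 9,
) -> ExcitonHamiltonian:
    """Assemble the LE+CT Hamiltonian from energies and couplings.

    ``site_energies`` follow the canonical basis order; ``couplings`` is
    either a mapping (site_id_i, site_id_j) -> V or a sequence of
    :class:`CouplingRecord` (their ``v_total`` is used).  The CT diagonal
    takes the manifold's (already aligned) energies; LE-CT couplings come
    from its mapping; the CT-CT block is zero.  Inconsistent symmetric
    entries raise.
    """
    eps = np.asarray(site_energies, dtype=float)
    n_le = len(eps)
    if le_meta is None:
        if n_le not in (2 * n_units, 3 * n_units):
            raise ValueError(
                f"cannot infer basis metadata for {n_le} sites and "
                f"{n_units} units; pass le_meta explicitly")
        le_meta = _default_le_meta(n_units, include_b800=(n_le == 3 * n_units))
    le_meta = list(le_meta)
    if len(le_meta) != n_le:
        raise ValueError("le_meta length must match the number of site energies")
    id_to_idx = {sid: i for i, (sid, _, _) in enumerate(le_meta)}

    if not isinstance(couplings, Mapping):
        cmap: dict[tuple[int, int], float] = {}
        for rec in couplings:
            cmap[rec.pair_id] = rec.v_total
        couplings = cmap

    n_ct = ct_manifold.n_ct if ct_manifold is not None else 0
    H = np.zeros((n_le + n_ct, n_le + n_ct))
    H[:n_le, :n_le][np.diag_indices(n_le)] = eps
    for (a, b), v in couplings.items():
        if a not in id_to_idx or b not in id_to_idx:
            raise ValueError(f"coupling ({a}, {b}) references unknown site ids")
        i, j = id_to_idx[a], id_to_idx[b]
        if i == j:
            raise ValueError(f"self-coupling for site {a}")
        rev = couplings.get((b, a))
        if rev is not None and not math.isclose(rev, v, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"asymmetric coupling input for pair ({a}, {b})")
        H[i, j] = H[j, i] = v

    ct_labels: list[tuple[int, int]] = []
    if ct_manifold is not None:
        ct_labels = list(ct_manifold.ct_labels)
        for m, e_ct in enumerate(ct_manifold.ct_energies):
            H[n_le + m, n_le + m] = e_ct
        for (le_id, m), v in ct_manifold.le_ct_couplings.items():
            if le_id not in id_to_idx:
                raise ValueError(f"CT coupling references unknown LE site {le_id}")
            i = id_to_idx[le_id]
            H[i, n_le + m] = H[n_le + m, i] = v
    return ExcitonHamiltonian(H, le_meta, n_units, ct_labels)


def hamiltonian_from_frame(frame: Frame,
                           couplings: Sequence[CouplingRecord],
                           ct_manifold: CTManifold | None = None,
                           ) -> ExcitonHamiltonian:
    """Assemble the Hamiltonian of one frame from its coupling records."""
    le_meta = [(s.site_id, s.unit, s.role) for s in frame.sites]
    return assemble_hamiltonian(frame.site_energies, couplings, ct_manifold,
                                le_meta=le_meta, n_units=frame.n_units)


def nearest_neighbor_ring_hamiltonian(
    eps_alpha: float, eps_beta: float,
    v_inter: float, v_intra: float,
    n_units: int = 9,
    coupling_sign: float = -1.0,
) -> ExcitonHamiltonian:
    """Nearest-neighbor-only 2n-site alternating-ring Hamiltonian.

    ``v_inter``/``v_intra`` are coupling magnitudes; ``coupling_sign``
    applies the gauge (default: the physical negative head-to-tail sign,
    which puts the bright k = +-1 pair at the bottom of the band).
    """
    n = 2 * n_units
    H = np.zeros((n, n))
    for u in range(n_units):
        a, b, a_next = 2 * u, 2 * u + 1, 2 * ((u + 1) % n_units)
        H[a, a] = eps_alpha
        H[b, b] = eps_beta
        H[a, b] = H[b, a] = coupling_sign * abs(v_intra)
        H[b, a_next] = H[a_next, b] = coupling_sign * abs(v_inter)
    return ExcitonHamiltonian(H, _default_le_meta(n_units, False), n_units)


def tabulated_hamiltonian(complex_name: str, n_units: int = 9,
                       include_b800: bool = False,
                       b800_nn_coupling: float = 30.0,
                       coupling_sign: float = -1.0) -> ExcitonHamiltonian:
    """NN Hamiltonian from the packaged per-complex mean parameters.

    The B800-ring nearest-neighbor coupling is not tabulated in the main
    parameter set and is exposed as a free parameter (magnitude; the same
    gauge sign is applied); B800-B850 couplings are omitted here.
    """
    p: ComplexParameters = COMPLEX_PARAMS[complex_name]
    base = nearest_neighbor_ring_hamiltonian(
        p.site_energies["alpha"], p.site_energies["beta"],
        p.v1_inter, p.v2_intra, n_units=n_units, coupling_sign=coupling_sign)
    if not include_b800:
        return base
    n_le = 3 * n_units
    H = np.zeros((n_le, n_le))
    H[:2 * n_units, :2 * n_units] = base.matrix
    for u in range(n_units):
        i = 2 * n_units + u
        H[i, i] = p.site_energies["b800"]
        j = 2 * n_units + (u + 1) % n_units
        H[i, j] = H[j, i] = coupling_sign * abs(b800_nn_coupling)
    return ExcitonHamiltonian(H, _default_le_meta(n_units, True), n_units)


# --------------------------------------------------------------------------
# symmetry averaging
# --------------------------------------------------------------------------

def ring_permutation(ham: ExcitonHamiltonian) -> np.ndarray:
    """Index map sigma of the generating C_n rotation on the full basis.

    Basis element b maps to sigma[b]: B850 site (u, role) -> (u+1, role),
    B800 site u -> u+1, CT state (d, a) -> (rot(d), rot(a)).
    """
    n_units, n_le = ham.n_units, ham.n_le
    nb850 = sum(1 for _, _, role in ham.le_meta if role != "b800")
    sigma = np.zeros(n_le + ham.n_ct, dtype=int)
    # site_id -> rotated site_id
    def rot_site(sid: int) -> int:
        if sid < nb850:
            return (sid + 2) % nb850
        return nb850 + ((sid - nb850 + 1) % n_units)
    id_to_idx = {sid: i for i, (sid, _, _) in enumerate(ham.le_meta)}
    for i, (sid, _, _) in enumerate(ham.le_meta):
        sigma[i] = id_to_idx[rot_site(sid)]
    if ham.n_ct:
        label_to_m = {lab: m for m, lab in enumerate(ham.ct_labels)}
        for m, (d, a) in enumerate(ham.ct_labels):
            lab = (rot_site(d), rot_site(a))
            if lab not in label_to_m:
                raise ValueError("CT manifold is not closed under the ring rotation")
            sigma[n_le + m] = n_le + label_to_m[lab]
    return sigma


def symmetry_average(hamiltonians: Sequence[ExcitonHamiltonian],
                     n_units: int | None = None) -> ExcitonHamiltonian:
    """Mean Hamiltonian over frames and over C_n symmetry orbits.

    Every matrix element is replaced by the mean over all frames and over
    its orbit under simultaneous row/column rotation; orbit members are
    assigned the identical float, so the result commutes exactly with the
    ring-rotation permutation.
    """
    if not hamiltonians:
        raise ValueError("no Hamiltonians given")
    ref = hamiltonians[0]
    if n_units is None:
        n_units = ref.n_units
    for h in hamiltonians[1:]:
        if (h.le_meta != ref.le_meta or h.ct_labels != ref.ct_labels
                or h.n_units != ref.n_units):
            raise ValueError("all Hamiltonians must share the same basis")
    M = np.mean([h.matrix for h in hamiltonians], axis=0)

    sigma = ring_permutation(ref)
    n = M.shape[0]
    out = np.empty_like(M)
    visited = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            if visited[i, j]:
                continue
            orbit = []
            a, b = i, j
            while True:
                orbit.append((a, b))
                a, b = sigma[a], sigma[b]
                if (a, b) == (i, j):
                    break
            mean = float(np.mean([M[a, b] for a, b in orbit]))
            for a, b in orbit:
                out[a, b] = mean
                visited[a, b] = True
    out = 0.5 * (out + out.T)
    return ExcitonHamiltonian(out, list(ref.le_meta), n_units,
                              list(ref.ct_labels))


# --------------------------------------------------------------------------
# diagonalization and observables
# --------------------------------------------------------------------------

def diagonalize(ham: ExcitonHamiltonian,
                site_dipoles: np.ndarray | None = None,
                band_split: float | None = None) -> ExcitonStates:
    """Eigenstates, transition dipoles and band labels of the Hamiltonian.

    ``site_dipoles`` is an (n_le, 3) array in Debye (zero used when
    omitted; CT basis functions carry no transition dipole).  The state
    dipole is mu_s = sum_i c_is mu_i and the dipole strength |mu_s|^2.
    Band labels: ``ct-dominated`` (CT weight > 1/2), ``b800`` (B800 weight
    > 1/2), otherwise ``lower``/``upper`` split at the mean B850 site
    energy (or at ``band_split``).
    """
    if not np.allclose(ham.matrix, ham.matrix.T, atol=1e-9):
        raise ValueError("Hamiltonian must be symmetric")
    energies, coeff = np.linalg.eigh(ham.matrix)
    n_le = ham.n_le
    if site_dipoles is None:
        site_dipoles = np.zeros((n_le, 3))
    site_dipoles = np.asarray(site_dipoles, dtype=float)
    if site_dipoles.shape != (n_le, 3):
        raise ValueError("site_dipoles must be (n_le, 3)")
    state_dipoles = coeff[:n_le].T @ site_dipoles
    strengths = np.sum(state_dipoles**2, axis=1)

    b850_idx = [i for i, (_, _, r) in enumerate(ham.le_meta) if r != "b800"]
    b800_idx = [i for i, (_, _, r) in enumerate(ham.le_meta) if r == "b800"]
    if band_split is None:
        ref_idx = b850_idx if b850_idx else list(range(n_le))
        band_split = float(np.mean(np.diag(ham.matrix)[ref_idx]))
    band = []
    for s in range(len(energies)):
        c2 = coeff[:, s]**2
        w_ct = float(np.sum(c2[n_le:]))
        w_b800 = float(np.sum(c2[b800_idx])) if b800_idx else 0.0
        if w_ct > 0.5:
            band.append("ct-dominated")
        elif w_b800 > 0.5:
            band.append("b800")
        else:
            band.append("lower" if energies[s] < band_split else "upper")
    return ExcitonStates(energies=energies, coefficients=coeff,
                         state_dipoles=state_dipoles,
                         dipole_strengths=strengths,
                         hamiltonian=ham, band=band)


def assign_k(states: ExcitonStates, n_units: int | None = None,
             power_threshold: float = 0.5) -> np.ndarray:
    """Ring quantum numbers from Fourier analysis of the B850 coefficients.

    For each state the spectral power at mode k of the 2n-site ring is
    P_k = |sum_m c_m exp(2 pi i k m / 2n)|^2 / 2n; the state is labelled by
    the |k| with maximal paired power P_k + P_-k, degenerate partners
    receiving +k and -k.  States whose maximal paired power is below
    ``power_threshold`` (strong disorder or CT character) are flagged
    undefined (label -999).  Labels run in {-(n-1) .. n}, e.g. {-8..9} for
    the 18-site ring.
    """
    ham = states.hamiltonian
    if n_units is None:
        n_units = ham.n_units
    ring_idx = [i for i, (_, _, r) in enumerate(ham.le_meta) if r != "b800"]
    N = len(ring_idx)
    if N != 2 * n_units or N < 2:
        raise ValueError("k assignment requires the full 2n-site ring basis")
    modes = np.arange(N)
    phases = np.exp(2j * np.pi * np.outer(modes, np.arange(N)) / N) / math.sqrt(N)
    ks = np.zeros(states.n_states, dtype=int)
    half = N // 2
    seen_of_absk: dict[int, int] = {}
    for s in range(states.n_states):
        c = states.coefficients[ring_idx, s]
        P = np.abs(phases @ c)**2                     # power at modes 0..N-1
        paired = np.empty(half + 1)
        for k in range(half + 1):
            paired[k] = P[k] + (P[N - k] if 0 < k < half else 0.0)
        k_best = int(np.argmax(paired))
        if paired[k_best] < power_threshold:
            ks[s] = ExcitonStates.UNDEFINED_K
            continue
        if k_best in (0, half):
            ks[s] = half if k_best == half else 0
        else:
            seen = seen_of_absk.get(k_best, 0)
            ks[s] = k_best if seen % 2 == 0 else -k_best
            seen_of_absk[k_best] = seen + 1
    states.k_labels = ks
    return ks


def exciton_width(states: ExcitonStates) -> float:
    """Energy difference between the k = +-(n-1) and k = +-1 pairs.

    Computed as mean energy of the outer (+-8 for a nonameric ring) pair
    minus the mean energy of the +-1 pair, on k labels assigned by
    :func:`assign_k` (run automatically when missing).
    """
    if states.k_labels is None:
        assign_k(states)
    n_units = states.hamiltonian.n_units
    k_hi = n_units - 1
    ks = states.k_labels
    e_hi = states.energies[np.abs(ks) == k_hi]
    e_lo = states.energies[(np.abs(ks) == 1) & (ks != ExcitonStates.UNDEFINED_K)]
    if len(e_hi) == 0 or len(e_lo) == 0:
        raise ValueError(
            f"k = +-1 / +-{k_hi} labels are not defined for these states")
    return float(np.mean(e_hi) - np.mean(e_lo))


def bright_dark_census(states: ExcitonStates, threshold_rel: float = 1e-6,
                       degeneracy_tol: float = 1e-4) -> dict[str, int]:
    """Counts of bright/dark states and (near-)degenerate pairs.

    Bright: dipole strength above ``threshold_rel`` times the maximum.
    Degenerate pairs are counted greedily on consecutive energies within
    ``degeneracy_tol`` cm^-1; remaining states are singlets.
    """
    strengths = states.dipole_strengths
    max_s = float(np.max(strengths)) if len(strengths) else 0.0
    bright = strengths > threshold_rel * max_s if max_s > 0 else np.zeros(
        len(strengths), dtype=bool)
    e = states.energies
    pairs = 0
    singlets = 0
    i = 0
    while i < len(e):
        if i + 1 < len(e) and abs(e[i + 1] - e[i]) <= degeneracy_tol:
            pairs += 1
            i += 2
        else:
            singlets += 1
            i += 1
    return {"n_bright": int(np.sum(bright)),
            "n_dark": int(len(e) - np.sum(bright)),
            "n_degenerate_pairs": pairs,
            "n_singlets": singlets}


def ct_shift(ham_with_ct: ExcitonHamiltonian,
             ham_without_ct: ExcitonHamiltonian,
             site_dipoles: np.ndarray | None = None):
    """Per-state CT-induced energy shifts, exact and second order.

    Both Hamiltonians must share the LE basis.  Each LE-manifold eigenstate
    of the CT-free Hamiltonian is matched to the eigenstate of the full
    Hamiltonian with maximal LE-block overlap (ties broken by energy
    proximity; squared overlap below 1/2 flags the match ambiguous).  The
    perturbative estimate for state s is sum_m |W_sm|^2 / (E_s - eps_m)
    with W_sm = sum_i c_is V_i,m.

    Returns a dict with ``exact``, ``perturbative``, ``matched_index`` and
    ``ambiguous`` arrays over the CT-free states.
    """
    if ham_with_ct.le_meta != ham_without_ct.le_meta:
        raise ValueError("Hamiltonians must share the LE basis")
    if ham_without_ct.n_ct != 0:
        raise ValueError("reference Hamiltonian must be CT-free")
    n_le = ham_without_ct.n_le
    bare = diagonalize(ham_without_ct, site_dipoles)
    full = diagonalize(ham_with_ct)

    V_lect = ham_with_ct.matrix[:n_le, n_le:]
    eps_ct = np.diag(ham_with_ct.matrix)[n_le:]

    exact = np.zeros(n_le)
    pert = np.zeros(n_le)
    matched = np.zeros(n_le, dtype=int)
    ambiguous = np.zeros(n_le, dtype=bool)
    for s in range(n_le):
        c = bare.coefficients[:, s]
        ov = (c @ full.coefficients[:n_le])**2
        best = int(np.argmax(ov))
        matched[s] = best
        ambiguous[s] = ov[best] < 0.5
        exact[s] = full.energies[best] - bare.energies[s]
        W = c @ V_lect
        denom = bare.energies[s] - eps_ct
        pert[s] = float(np.sum(W**2 / denom))
    return {"exact": exact, "perturbative": pert,
            "matched_index": matched, "ambiguous": ambiguous}
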