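"""Statistical layer: regressions, class statistics, contribution ledger.

Three analyses sit on top of the geometric and excitonic machinery:

* an ordinary-least-squares regression of Q_y excitation energies on the
  macrocycle bond lengths (the conjugation pattern of the ring is the main
  determinant of the site energy);
* class-wise coupling statistics (mean, SD, 95% t confidence intervals)
  for inter-chain vs intra-chain dimers;
* a classical per-residue contribution ledger: the first-order
  electrostatic shift of a pigment's excitation energy attributed to each
  environment residue, obtained from the pigment's ground-to-excited
  difference charges — an explicit classical stand-in for switching
  residues off in a full quantum recomputation.  It reproduces signs and
  distance trends, not quantum magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .coupling_engine import K_EE_CM1

__all__ = [
    "RegressionModel", "ClassStatistics", "EnvironmentResidue",
    "fit_bond_length_regression", "predict_site_energy",
    "class_statistics", "contribution_ledger",
]


@dataclass
class RegressionModel:
    """OLS bond-length model for site energies (cm^-1 per Angstrom)."""

    coefficients: pd.Series
    intercept: float
    r_squared: float
    n_samples: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")

    def write(self, path: str | Path) -> None:
        lines = [f"intercept={self.intercept!r}",
                 f"r_squared={self.r_squared!r}",
                 f"n_samples={self.n_samples}"]
        lines += [f"coef:{name}={val!r}"
                  for name, val in self.coefficients.items()]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class ClassStatistics:
    """Summary statistics of one coupling class (cm^-1)."""

    label: str
    mean: float
    sd: float
    ci95: tuple[float, float]
    n: int


def fit_bond_length_regression(table: pd.DataFrame,
                               target: str = "energy") -> RegressionModel:
    """OLS fit of the target energy on every bond-length column.

    All columns except ``target`` are explanatory variables.  Exactly
    collinear designs fail loudly, naming the dependent columns, rather
    than falling back to a pseudo-inverse.
    """
    import statsmodels.api as sm

    if target not in table.columns:
        raise ValueError(f"table has no target column {target!r}")
    X = table.drop(columns=[target])
    y = table[target].to_numpy(dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need more samples than descriptors")
    design = sm.add_constant(X.to_numpy(dtype=float))
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name the offending columns via QR diagonal of the design
        r_diag = np.abs(np.diag(np.linalg.qr(design, mode="r")))
        bad = [X.columns[i - 1] for i in range(1, design.shape[1])
               if r_diag[i] < 1e-10 * r_diag.max()]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    fit = sm.OLS(y, design).fit()
    return RegressionModel(
        coefficients=pd.Series(fit.params[1:], index=list(X.columns)),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        n_samples=n)


def predict_site_energy(model: RegressionModel,
                        bond_lengths: Sequence[float] | Mapping[str, float]
                        ) -> float:
    """intercept + coefficients . bond_lengths (cm^-1)."""
    if isinstance(bond_lengths, Mapping):
        x = np.array([bond_lengths[name] for name in model.coefficients.index])
    else:
        x = np.asarray(bond_lengths, dtype=float)
    if len(x) != len(model.coefficients):
        raise ValueError(
            f"expected {len(model.coefficients)} bond lengths, got {len(x)}")
    return float(model.intercept + model.coefficients.to_numpy() @ x)


def class_statistics(records: pd.DataFrame, value_key: str,
                     class_key: str = "pair_cls",
                     grouping: Sequence[str] | None = None,
                     ) -> list[ClassStatistics]:
    """Per-class mean, SD (n-1) and 95% Student-t CI of a value column."""
    keys = [class_key] + list(grouping or [])
    out = []
    for label, grp in records.groupby(keys[0] if len(keys) == 1 else keys):
        vals = grp[value_key].to_numpy(dtype=float)
        n = len(vals)
        if n < 2:
            raise ValueError(f"group {label!r} needs >= 2 records for a CI")
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1))
        if sd > 0:
            lo, hi = sps.t.interval(0.95, df=n - 1, loc=mean,
                                    scale=sd / np.sqrt(n))
        else:
            lo = hi = mean
        out.append(ClassStatistics(label=str(label), mean=mean, sd=sd,
                                   ci95=(float(lo), float(hi)), n=n))
    return out


@dataclass
class EnvironmentResidue:
    """A named environment residue as classical charges (+ polarizabilities)."""

    name: str
    positions: np.ndarray          # (n, 3) Angstrom
    charges: np.ndarray            # (n,) e
    alphas: np.ndarray | None = None   # (n,) Angstrom^3

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        self.charges = np.atleast_1d(np.asarray(self.charges, float))
        if self.alphas is not None:
            self.alphas = np.atleast_1d(np.asarray(self.alphas, float))


def contribution_ledger(
    pigment_diff_charges: tuple[np.ndarray, np.ndarray],
    environment_residues: Sequence[EnvironmentResidue],
    include_polarization: bool = False,
) -> pd.DataFrame:
    """First-order per-residue shifts of a pigment's excitation energy.

    ``pigment_diff_charges`` is (positions, delta_q): the atomic charge
    changes from ground to excited state.  The shift attributed to residue
    R is Delta_eps_R = K sum_a sum_k dq_a q_k / r_ak (cm^-1), i.e. the
    electrostatic interaction lost when R is switched off; with
    ``include_polarization`` an induced-dipole response term
    -K/2 sum_k alpha_k |E_dq(r_k)|^2 is added per site.  Both modes are
    additive over residues by construction.
    """
    pig_pos, dq = (np.atleast_2d(np.asarray(pigment_diff_charges[0], float)),
                   np.atleast_1d(np.asarray(pigment_diff_charges[1], float)))
    if len(pig_pos) != len(dq):
        raise ValueError("difference-charge table: positions/charges mismatch")
    if len(dq) == 0:
        raise ValueError("missing difference-charge table")
    rows = []
    for res in environment_residues:
        dr = pig_pos[:, None, :] - res.positions[None, :, :]
        r = np.linalg.norm(dr, axis=-1)
        if np.any(r < 1e-9):
            raise ValueError(f"residue {res.name}: coincides with pigment atom")
        delta = K_EE_CM1 * float(np.sum(np.outer(dq, res.charges) / r))
        if include_polarization and res.alphas is not None:
            # field of the difference charges at each polarizable site
            E = np.einsum("an,ank->nk", (dq[:, None] / r**3) * -1.0, dr)
            delta += -0.5 * K_EE_CM1 * float(
                np.sum(res.alphas * np.sum(E**2, axis=1)))
        rows.append({"residue": res.name, "delta_eps_cm1": delta})
    return pd.DataFrame(rows)
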