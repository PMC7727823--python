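"""Geometric sensitivity of ¹³C chemical shifts to C-C bond lengths.

The central object is the significance-filtered linear sensitivity matrix
M (atoms × bonds, ppm/Å): the pattern of how each carbon's isotropic shift
responds to stretching each bond of the conjugated chain. Two estimates are
provided:

* **pairwise** simple regressions of one shift on one bond length
  (:func:`pairwise_regression`, :func:`pair_table`) — the per-pair
  correlation view, including Pearson r, suitable for display;
* **joint** multivariate regression of each shift on all bond lengths
  (:func:`build_sensitivity_matrix`) — the matrix entries M_ij used for
  inversion, since the shift of an atom responds to several bonds at once
  and the pairwise slope absorbs sample cross-covariance between bonds.

Significance of each entry is assessed by a t-test on its slope with an
optional lag-1 autocorrelation correction of the standard error (snapshots
from MD are serially correlated), followed by multiple-testing correction
across the whole atoms × bonds family (Benjamini–Hochberg by default).
Entries that fail the test are set to exactly zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .trajectory_io import BondSeries, ShiftSeries

__all__ = [
    "PairRegression",
    "SensitivityMatrix",
    "AsymmetryRow",
    "pairwise_regression",
    "pair_table",
    "build_sensitivity_matrix",
    "sign_pattern",
    "asymmetry_report",
    "write_pair_table_csv",
    "write_matrix_csv",
    "write_matrix_metadata_json",
]

DEFAULT_ALPHA = 0.05
DEFAULT_CORRECTION = "bh"


@dataclass(frozen=True)
class PairRegression:
    """OLS of one atom's shift (ppm) on one bond length (Å)."""

    atom_label: str
    bond_label: str
    slope_ppm_per_A: float
    intercept_ppm: float
    stderr_slope: float
    p_value: float
    pearson_r: float
    n: int


@dataclass(frozen=True)
class SensitivityMatrix:
    """Significance-filtered linear sensitivity (atoms × bonds, ppm/Å).

    ``slopes`` holds the joint-regression slopes with non-significant
    entries set to exactly 0; ``raw_slopes`` keeps the unfiltered values.
    """

    atom_labels: tuple[str, ...]
    bond_labels: tuple[str, ...]
    slopes: np.ndarray
    significance_mask: np.ndarray
    alpha: float
    correction_method: str
    raw_slopes: np.ndarray
    stderr: np.ndarray
    p_values: np.ndarray
    n_frames: int

    def __post_init__(self) -> None:
        if self.slopes.shape != self.significance_mask.shape:
            raise ValueError("slopes and mask must share shape")
        if np.any(self.slopes[~self.significance_mask] != 0.0):
            raise ValueError("masked-out entries must be exactly 0")


def pairwise_regression(delta, d, atom_label: str = "", bond_label: str = "") -> PairRegression:
    """Simple OLS of shift values *delta* on bond lengths *d*.

    A constant shift series is a degenerate but legal input: slope, r and
    stderr are 0 and p is 1 by convention. A constant bond series is an
    error (the slope is unidentified).
    """
    y = np.asarray(delta, dtype=float)
    x = np.asarray(d, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("delta and d must be 1-d sequences of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points for a pair regression")
    if np.ptp(x) == 0:
        raise ValueError(f"bond {bond_label or 'series'} has zero variance; slope unidentified")
    if np.ptp(y) == 0:
        return PairRegression(atom_label, bond_label, 0.0, float(y.mean()), 0.0, 1.0, 0.0, n)
    res = stats.linregress(x, y)
    return PairRegression(
        atom_label, bond_label,
        float(res.slope), float(res.intercept), float(res.stderr),
        float(res.pvalue), float(res.rvalue), n,
    )


def _check_aligned(s: ShiftSeries, b: BondSeries) -> None:
    if s.n_frames != b.n_frames:
        raise ValueError(
            f"misaligned series: {s.n_frames} shift frames vs {b.n_frames} bond frames")


def _subset(labels, available, kind: str) -> list[int]:
    idx = {lab: i for i, lab in enumerate(available)}
    missing = [lab for lab in labels if lab not in idx]
    if missing:
        raise ValueError(f"{kind} label(s) {missing} not present in series")
    return [idx[lab] for lab in labels]


def pair_table(s: ShiftSeries, b: BondSeries,
               atoms: list[str] | None = None,
               bonds: list[str] | None = None) -> list[PairRegression]:
    """All (atom, bond) pairwise regressions — the per-pair correlation table."""
    _check_aligned(s, b)
    atoms = list(atoms or s.atom_labels)
    bonds = list(bonds or b.bond_labels)
    ai = _subset(atoms, s.atom_labels, "atom")
    bi = _subset(bonds, b.bond_labels, "bond")
    out = []
    for a_lab, a in zip(atoms, ai):
        for b_lab, j in zip(bonds, bi):
            out.append(pairwise_regression(s.shifts[:, a], b.lengths[:, j], a_lab, b_lab))
    return out


def _lag1_inflation(v: np.ndarray) -> float:
    """Statistical inefficiency g = (1+ρ₁)/(1−ρ₁) of a score series, clipped ≥ 1."""
    v = v - v.mean()
    denom = float(v @ v)
    if denom <= 0 or v.size < 3:
        return 1.0
    rho = float(v[:-1] @ v[1:]) / denom
    rho = min(rho, 0.999)
    if rho <= 0:
        return 1.0
    return (1.0 + rho) / (1.0 - rho)


def build_sensitivity_matrix(s: ShiftSeries, b: BondSeries,
                             alpha: float = DEFAULT_ALPHA,
                             correction: str = DEFAULT_CORRECTION,
                             atoms: list[str] | None = None,
                             bonds: list[str] | None = None,
                             autocorr_correction: bool = True) -> SensitivityMatrix:
    """Fit the sensitivity matrix M (atoms × bonds, ppm/Å) with significance mask.

    Each atom's shift is regressed jointly on all bond lengths (OLS with
    intercept). Per-coefficient p-values come from t-tests whose standard
    errors are optionally inflated by the lag-1 statistical inefficiency of
    the per-coefficient score series (Frisch–Waugh residual × regression
    residual), compensating the serial correlation of MD snapshots; the
    effective degrees of freedom are reduced accordingly. ``correction``
    (``none``/``bonferroni``/``bh``) is applied across all entries, and
    entries failing the corrected test at ``alpha`` are zeroed.
    """
    _check_aligned(s, b)
    if correction not in ("none", "bonferroni", "bh"):
        raise ValueError(f"unknown correction {correction!r}")
    atoms = list(atoms or s.atom_labels)
    bonds = list(bonds or b.bond_labels)
    ai = _subset(atoms, s.atom_labels, "atom")
    bi = _subset(bonds, b.bond_labels, "bond")
    Y = s.shifts[:, ai]
    X = b.lengths[:, bi]
    n, nb = X.shape
    na = len(atoms)
    if n < nb + 2:
        raise ValueError(f"need more than {nb + 1} frames to fit {nb} bonds")
    Xc = X - X.mean(axis=0)
    if np.linalg.matrix_rank(Xc) < nb:
        raise ValueError("bond length matrix is rank deficient; slopes unidentified")
    # Frisch–Waugh residuals of each bond column on the others (for score series)
    fw = np.empty_like(Xc)
    for j in range(nb):
        others = np.delete(Xc, j, axis=1)
        if others.shape[1]:
            coef, *_ = np.linalg.lstsq(others, Xc[:, j], rcond=None)
            fw[:, j] = Xc[:, j] - others @ coef
        else:
            fw[:, j] = Xc[:, j]
    XtX_inv = np.linalg.inv(Xc.T @ Xc)
    slopes = np.empty((na, nb))
    stderr = np.empty((na, nb))
    pvals = np.empty((na, nb))
    df_base = n - nb - 1
    for i in range(na):
        y = Y[:, i]
        yc = y - y.mean()
        beta = XtX_inv @ (Xc.T @ yc)
        resid = yc - Xc @ beta
        sigma2 = float(resid @ resid) / df_base if df_base > 0 else 0.0
        se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 0.0))
        slopes[i] = beta
        for j in range(nb):
            g = _lag1_inflation(fw[:, j] * resid) if autocorr_correction else 1.0
            se_j = se[j] * np.sqrt(g)
            df = max(df_base / g, 1.0)
            stderr[i, j] = se_j
            if se_j == 0.0:
                pvals[i, j] = 0.0 if beta[j] != 0 else 1.0
            else:
                t = beta[j] / se_j
                pvals[i, j] = 2.0 * float(stats.t.sf(abs(t), df))
    flat_p = pvals.ravel()
    if alpha <= 0:
        reject = np.zeros_like(flat_p, dtype=bool)
    elif correction == "none":
        reject = flat_p < alpha
    else:
        method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[correction]
        reject, *_ = multipletests(flat_p, alpha=alpha, method=method)
    mask = reject.reshape(na, nb)
    filtered = np.where(mask, slopes, 0.0)
    return SensitivityMatrix(
        tuple(atoms), tuple(bonds), filtered, mask,
        float(alpha), correction, slopes, stderr, pvals, n,
    )


def sign_pattern(m: SensitivityMatrix) -> np.ndarray:
    """Per-entry labels in {``positive``, ``negative``, ``none``} (object array)."""
    out = np.full(m.slopes.shape, "none", dtype=object)
    out[(m.slopes > 0) & m.significance_mask] = "positive"
    out[(m.slopes < 0) & m.significance_mask] = "negative"
    return out


@dataclass(frozen=True)
class AsymmetryRow:
    """Preferred bond of one atom: the bond with the largest |slope|."""

    atom_label: str
    preferred_bond: str | None
    max_abs_slope: float
    ratio_to_second: float  # ∞ if only one significant bond
    independent: bool  # no significant entry at all


def asymmetry_report(m: SensitivityMatrix) -> list[AsymmetryRow]:
    """Per-atom preferred bond and dominance ratio.

    An atom with no significant entry is reported as *independent* of the
    conjugated chain (the amide-like carbon case).
    """
    rows = []
    for i, atom in enumerate(m.atom_labels):
        absrow = np.abs(m.slopes[i]) * m.significance_mask[i]
        if not np.any(absrow > 0):
            rows.append(AsymmetryRow(atom, None, 0.0, 0.0, True))
            continue
        order = np.argsort(absrow)[::-1]
        best = int(order[0])
        second = float(absrow[order[1]]) if absrow.size > 1 else 0.0
        ratio = float(absrow[best] / second) if second > 0 else float("inf")
        rows.append(AsymmetryRow(atom, m.bond_labels[best], float(absrow[best]), ratio, False))
    return rows


# ---------------------------------------------------------------------------
# Writers


def write_pair_table_csv(path: str | Path, table: list[PairRegression]) -> None:
    pd.DataFrame([r.__dict__ for r in table]).to_csv(path, index=False)


def write_matrix_csv(path: str | Path, m: SensitivityMatrix, raw: bool = False) -> None:
    values = m.raw_slopes if raw else m.slopes
    df = pd.DataFrame(values, index=list(m.atom_labels), columns=list(m.bond_labels))
    df.index.name = "atom"
    df.to_csv(path)


def write_matrix_metadata_json(path: str | Path, m: SensitivityMatrix) -> None:
    payload = {
        "atom_labels": list(m.atom_labels),
        "bond_labels": list(m.bond_labels),
        "alpha": m.alpha,
        "correction_method": m.correction_method,
        "n_frames": m.n_frames,
        "significance_mask": m.significance_mask.astype(int).tolist(),
        "p_values": m.p_values.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=2))
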