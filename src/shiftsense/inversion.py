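"""Inverting the shift↔bond-length relationship: Δδ (ppm) → Δd (pm).

The forward model is linear, Δδ_i = Σ_j M_ij Δd_j, with M the geometric
sensitivity matrix (ppm/Å). Prediction of bond-length changes from an
experimental chemical-shift-change vector is done by two routes:

* **PC regression** (the default): PCA of the centred, unscaled per-frame
  shifts (no dimensionality reduction — the component count equals the
  feature count, so PCA is a pure rotation weighting fluctuation
  directions), followed by multivariate OLS of each bond length on the PC
  scores; an experimental Δδ vector is rotated into PC space and mapped
  through the fitted coefficients.
* **pseudoinverse**: Δd = pinv(M)·Δδ, the minimum-norm least-squares
  solution through the forward matrix — an independent cross-check that
  agrees with PC regression in the noiseless square full-rank case.

Uncertainties come from a seeded frame-block bootstrap (refitting the whole
PCA + regression on resampled blocks of frames), or from the analytic OLS
prediction standard error when ``n_boot=0``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .sensitivity import SensitivityMatrix
from .trajectory_io import BondSeries, ShiftSeries

__all__ = [
    "PCAModel",
    "ShiftDelta",
    "InverseModel",
    "BondDeltaPrediction",
    "fit_pca",
    "fit_inverse_model",
    "predict_bond_deltas",
    "pseudoinverse_predict",
    "read_shift_delta",
    "write_shift_delta",
    "write_predictions_csv",
]

PM_PER_ANGSTROM = 100.0
DEFAULT_BOOT_BLOCK = 10  # frames per bootstrap block


@dataclass(frozen=True)
class PCAModel:
    """Full-rank PCA of centred, unscaled shift fluctuations."""

    feature_labels: tuple[str, ...]
    feature_means: np.ndarray  # ppm
    loadings: np.ndarray  # (n_components, n_features), rows orthonormal
    explained_variance: np.ndarray
    n_components: int


@dataclass(frozen=True)
class ShiftDelta:
    """Experimental per-atom chemical-shift change for one state transition."""

    transition_name: str
    atom_labels: tuple[str, ...]
    delta_ppm: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        x = np.asarray(self.delta_ppm, dtype=float)
        object.__setattr__(self, "delta_ppm", x)
        if len(set(self.atom_labels)) != len(self.atom_labels):
            raise ValueError("duplicate atom labels in shift delta")
        if x.shape != (len(self.atom_labels),):
            raise ValueError("delta_ppm shape inconsistent with labels")
        if not np.all(np.isfinite(x)):
            raise ValueError("shift delta values must be finite")


@dataclass(frozen=True)
class InverseModel:
    """Bond lengths regressed on shift PC scores (the inverse regression)."""

    pca: PCAModel
    bond_labels: tuple[str, ...]
    coefficients: np.ndarray  # (n_bonds, n_components), Å per PC unit
    intercepts: np.ndarray  # Å
    residual_variance: np.ndarray  # per bond, Å²
    scores_gram_inv: np.ndarray  # (SᵀS)⁻¹ of training scores
    n_frames: int
    training_shifts: np.ndarray  # (n_frames, n_features), ppm
    training_bonds: np.ndarray  # (n_frames, n_bonds), Å


@dataclass(frozen=True)
class BondDeltaPrediction:
    """Predicted bond-length changes (pm) with uncertainties for a transition."""

    transition_name: str
    bond_labels: tuple[str, ...]
    delta_pm: np.ndarray
    uncertainty_pm: np.ndarray
    method: str  # "pc_regression" | "pseudoinverse"

    def __post_init__(self) -> None:
        d = np.asarray(self.delta_pm, dtype=float)
        u = np.asarray(self.uncertainty_pm, dtype=float)
        object.__setattr__(self, "delta_pm", d)
        object.__setattr__(self, "uncertainty_pm", u)
        if np.any(u < 0):
            raise ValueError("uncertainties must be non-negative")


def fit_pca(s: ShiftSeries, atoms: list[str] | None = None) -> PCAModel:
    """Full-rank PCA of the centred, unscaled shifts of the selected atoms.

    No dimensionality reduction is performed: the number of components
    equals the number of atoms, components ordered by decreasing explained
    variance. A constant shift column makes the covariance singular and is
    rejected with the column named.
    """
    atoms = list(atoms or s.atom_labels)
    idx = {lab: i for i, lab in enumerate(s.atom_labels)}
    missing = [a for a in atoms if a not in idx]
    if missing:
        raise ValueError(f"atom(s) {missing} not present in shift series")
    X = s.shifts[:, [idx[a] for a in atoms]]
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more than {k} frames for a {k}-feature PCA")
    variances = X.var(axis=0)
    for lab, v in zip(atoms, variances):
        if v <= 0:
            raise ValueError(f"shift column {lab!r} is constant; PCA input rank deficient")
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < k:
        raise ValueError("shift fluctuations are rank deficient across atoms")
    pca = PCA(n_components=k)
    pca.fit(X)
    return PCAModel(
        tuple(atoms),
        pca.mean_.copy(),
        pca.components_.copy(),
        pca.explained_variance_.copy(),
        k,
    )


def _scores(p: PCAModel, shifts: np.ndarray) -> np.ndarray:
    return (shifts - p.feature_means) @ p.loadings.T


def fit_inverse_model(p: PCAModel, s: ShiftSeries, b: BondSeries) -> InverseModel:
    """OLS of each bond length on the full PC-score matrix (with intercept)."""
    if s.n_frames != b.n_frames:
        raise ValueError("shift and bond series must be frame-aligned")
    idx = {lab: i for i, lab in enumerate(s.atom_labels)}
    X = s.shifts[:, [idx[a] for a in p.feature_labels]]
    n = X.shape[0]
    if n <= p.n_components + 1:
        raise ValueError("need n_frames > n_components + 1 to fit the inverse model")
    S = _scores(p, X)
    if np.linalg.matrix_rank(S) < p.n_components:
        raise ValueError("collinear PC scores; inverse regression unidentified")
    Sc = S - S.mean(axis=0)
    gram_inv = np.linalg.inv(Sc.T @ Sc)
    D = b.lengths
    Dc = D - D.mean(axis=0)
    coeffs = (gram_inv @ (Sc.T @ Dc)).T  # (n_bonds, n_components)
    intercepts = D.mean(axis=0) - coeffs @ S.mean(axis=0)
    resid = Dc - Sc @ coeffs.T
    dof = n - p.n_components - 1
    resid_var = (resid**2).sum(axis=0) / dof
    return InverseModel(
        p, b.bond_labels, coeffs, intercepts, resid_var, gram_inv, n,
        X.copy(), D.copy(),
    )


def _delta_vector(exp: ShiftDelta, feature_labels: tuple[str, ...]) -> np.ndarray:
    have = dict(zip(exp.atom_labels, exp.delta_ppm))
    missing = [a for a in feature_labels if a not in have]
    if missing:
        raise ValueError(f"shift delta for {exp.transition_name!r} is missing atom(s) {missing}")
    return np.array([have[a] for a in feature_labels], dtype=float)


def _pc_predict(coeffs: np.ndarray, loadings: np.ndarray, delta_ppm: np.ndarray) -> np.ndarray:
    # A difference vector carries no baseline: rotate without mean subtraction.
    return coeffs @ (loadings @ delta_ppm)


def predict_bond_deltas(m: InverseModel, exp: ShiftDelta,
                        n_boot: int = 200, seed: int = 0,
                        block_size: int = DEFAULT_BOOT_BLOCK) -> BondDeltaPrediction:
    """Predict Δd (pm) for every bond from an experimental Δδ vector.

    The Δδ vector is rotated into PC space (no mean subtraction — it is a
    difference), mapped through the fitted coefficients and converted Å→pm.
    With ``n_boot > 0`` the uncertainty is the standard deviation of
    predictions over seeded circular block-bootstrap refits of the whole
    PCA + regression; with ``n_boot = 0`` it is the analytic OLS standard
    error of the predicted mean response.
    """
    if n_boot < 0:
        raise ValueError("n_boot must be >= 0")
    delta = _delta_vector(exp, m.pca.feature_labels)
    dd_A = _pc_predict(m.coefficients, m.pca.loadings, delta)
    if n_boot == 0:
        z = m.pca.loadings @ delta
        quad = float(z @ m.scores_gram_inv @ z)
        unc_A = np.sqrt(np.maximum(m.residual_variance * quad, 0.0))
    else:
        rng = np.random.default_rng(seed)
        n = m.n_frames
        n_blocks = int(np.ceil(n / block_size))
        preds = np.empty((n_boot, len(m.bond_labels)))
        for bi in range(n_boot):
            starts = rng.integers(0, n, size=n_blocks)
            rows = (starts[:, None] + np.arange(block_size)[None, :]).ravel() % n
            rows = rows[:n]
            Xb = m.training_shifts[rows]
            Db = m.training_bonds[rows]
            try:
                sub = _refit(Xb, Db, m.pca.feature_labels, m.bond_labels)
            except np.linalg.LinAlgError:  # pragma: no cover - degenerate resample
                preds[bi] = dd_A
                continue
            preds[bi] = _pc_predict(sub[0], sub[1], delta)
        unc_A = preds.std(axis=0, ddof=1)
    return BondDeltaPrediction(
        exp.transition_name, m.bond_labels,
        dd_A * PM_PER_ANGSTROM, unc_A * PM_PER_ANGSTROM, "pc_regression",
    )


def _refit(X: np.ndarray, D: np.ndarray, feature_labels, bond_labels):
    """Refit PCA + inverse regression on a resampled dataset; returns (coeffs, loadings)."""
    pca = PCA(n_components=X.shape[1])
    pca.fit(X)
    S = (X - pca.mean_) @ pca.components_.T
    Sc = S - S.mean(axis=0)
    Dc = D - D.mean(axis=0)
    coeffs = (np.linalg.solve(Sc.T @ Sc, Sc.T @ Dc)).T
    return coeffs, pca.components_


def pseudoinverse_predict(M: SensitivityMatrix, exp: ShiftDelta) -> BondDeltaPrediction:
    """Minimum-norm least-squares inversion Δd = pinv(M)·Δδ, reported in pm.

    Uses the significance-filtered forward matrix; serves as the
    independent cross-check of the PC-regression route. No uncertainty is
    attached (reported as 0).
    """
    if not np.any(M.significance_mask):
        raise ValueError("sensitivity matrix has no significant entries; nothing to invert")
    delta = _delta_vector(exp, M.atom_labels)
    dd_A = np.linalg.pinv(M.slopes) @ delta
    return BondDeltaPrediction(
        exp.transition_name, M.bond_labels,
        dd_A * PM_PER_ANGSTROM, np.zeros_like(dd_A), "pseudoinverse",
    )


# ---------------------------------------------------------------------------
# Serialisation


def read_shift_delta(path: str | Path) -> ShiftDelta:
    """Read a ShiftDelta from JSON (keys: transition, deltas{atom: ppm}, source)
    or from CSV with columns ``atom,delta_ppm``."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        deltas = payload["deltas"]
        return ShiftDelta(
            payload.get("transition", path.stem),
            tuple(deltas.keys()),
            np.array(list(deltas.values()), dtype=float),
            payload.get("source", ""),
        )
    df = pd.read_csv(path)
    if "atom" not in df.columns or "delta_ppm" not in df.columns:
        raise ValueError(f"{path}: expected columns 'atom' and 'delta_ppm'")
    return ShiftDelta(path.stem, tuple(df["atom"].astype(str)),
                      df["delta_ppm"].to_numpy(dtype=float))


def write_shift_delta(path: str | Path, delta: ShiftDelta) -> None:
    payload = {
        "transition": delta.transition_name,
        "deltas": {a: float(v) for a, v in zip(delta.atom_labels, delta.delta_ppm)},
        "source": delta.source,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_predictions_csv(path: str | Path, predictions: list[BondDeltaPrediction]) -> None:
    rows = []
    for p in predictions:
        for lab, dd, u in zip(p.bond_labels, p.delta_pm, p.uncertainty_pm):
            rows.append({"transition": p.transition_name, "bond": lab,
                         "delta_pm": dd, "uncertainty_pm": u, "method": p.method})
    pd.DataFrame(rows).to_csv(path, index=False)
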