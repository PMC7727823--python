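"""Time averages, fluctuation ranges and block-averaged uncertainties.

Instantaneous MD series are strongly autocorrelated, so the naive standard
error of the mean underestimates the uncertainty of a trajectory average.
Block averaging — the standard error of contiguous block means — is used as
the uncertainty estimator throughout; the default block of 10 snapshots
corresponds to 2 ps at the 200 fs snapshot spacing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SeriesSummary",
    "summarize_series",
    "fluctuation_range",
    "compare_shift_patterns",
    "write_summary_csv",
]

DEFAULT_BLOCK_SIZE = 10  # snapshots; 2 ps at 200 fs spacing


@dataclass(frozen=True)
class SeriesSummary:
    """Mean, spread and block-averaged standard error of one series."""

    label: str
    mean: float
    sem: float
    sd: float
    min: float
    max: float
    n_frames: int
    block_size: int


def summarize_series(values, block_size: int = DEFAULT_BLOCK_SIZE,
                     label: str = "") -> SeriesSummary:
    """Summarise a series with block-averaged uncertainty.

    ``sem`` is the standard error of the means of ``⌊n/block_size⌋``
    contiguous blocks (trailing partial block dropped); ``sd`` is the sample
    standard deviation of the raw values.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("values must be a non-empty 1-d sequence")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    n = x.size
    if block_size > n:
        raise ValueError(f"block_size {block_size} exceeds series length {n}")
    n_blocks = n // block_size
    block_means = x[: n_blocks * block_size].reshape(n_blocks, block_size).mean(axis=1)
    if n_blocks > 1:
        sem = float(block_means.std(ddof=1) / np.sqrt(n_blocks))
    else:
        sem = 0.0
    sd = float(x.std(ddof=1)) if n > 1 else 0.0
    return SeriesSummary(
        label=label,
        mean=float(x.mean()),
        sem=sem,
        sd=sd,
        min=float(x.min()),
        max=float(x.max()),
        n_frames=n,
        block_size=block_size,
    )


def fluctuation_range(values) -> tuple[float, float, float]:
    """Return ``(min, max, span)`` of a series; span = max − min."""
    x = np.asarray(values, dtype=float)
    if x.size < 1:
        raise ValueError("values must be non-empty")
    lo, hi = float(x.min()), float(x.max())
    return lo, hi, hi - lo


def compare_shift_patterns(computed: dict[str, float],
                           reference: dict[str, float]
                           ) -> tuple[float, float, dict[str, float]]:
    """Compare a computed per-atom shift pattern against a reference pattern.

    Statistics are computed over the shared labels only. Returns the RMS
    deviation (ppm), the Pearson correlation, and per-atom residuals
    (computed − reference).
    """
    shared = sorted(set(computed) & set(reference))
    if len(shared) < 2:
        raise ValueError("need at least 2 shared labels to compare patterns")
    c = np.array([computed[k] for k in shared], dtype=float)
    r = np.array([reference[k] for k in shared], dtype=float)
    resid = c - r
    rmsd = float(np.sqrt(np.mean(resid**2)))
    if np.std(c) == 0 or np.std(r) == 0:
        pearson = float("nan")
    else:
        pearson = float(stats.pearsonr(c, r).statistic)
    return rmsd, pearson, dict(zip(shared, resid.tolist()))


def write_summary_csv(path: str | Path, summaries: list[SeriesSummary]) -> None:
    rows = [
        {"label": s.label, "mean": s.mean, "sem": s.sem, "sd": s.sd,
         "min": s.min, "max": s.max, "n_frames": s.n_frames,
         "block_size": s.block_size}
        for s in summaries
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
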