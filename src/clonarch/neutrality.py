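"""Neutral-evolution test on the subclonal mutation frequency spectrum.

Under neutral tumor growth the cumulative number of subclonal mutations
present at allelic frequency >= f is linear in 1/f (Williams model):

    M(f) = mu/beta * (1/f - 1/f_max)

where f is the purity-corrected frequency (VAF / purity), mu the somatic
mutation rate and beta the fraction of effective cell divisions.  Linearity
of M(f) against 1/f, with the intercept pinned at f_max, is the neutrality
criterion; the slope estimates mu/beta.  No formal p-value is produced:
the through-origin R-squared is reported descriptively.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["NeutralFit", "cumulative_mf", "fit_neutral_model", "fit_neutral"]

#: Default purity-corrected frequency window for the fit. The window is a
#: procedural choice inherited from the cumulative-spectrum methodology;
#: it is configurable everywhere it is used.
DEFAULT_F_MIN = 0.12
DEFAULT_F_MAX = 0.24


@dataclass(frozen=True)
class NeutralFit:
    f_min: float
    f_max: float
    inv_f_grid: np.ndarray
    m_f: np.ndarray
    slope: float  # mu/beta estimate, mutations per effective division
    r_squared: float
    n_subclonal: int


def cumulative_mf(
    vafs: Sequence[float],
    purity: float,
    f_min: float = DEFAULT_F_MIN,
    f_max: float = DEFAULT_F_MAX,
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative mutation count M(f) on the observed frequency grid.

    Frequencies are f = VAF / purity; only variants with f in
    [f_min, f_max] enter. Returns (1/f grid, M(f)) with 1/f ascending
    (f descending), where M(f) counts variants at frequency >= f.
    """
    if not 0 < purity <= 1:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if not 0 < f_min < f_max <= 1:
        raise ValueError(f"require 0 < f_min < f_max <= 1, got [{f_min}, {f_max}]")
    f = np.asarray(vafs, dtype=float) / purity
    f = f[(f >= f_min) & (f <= f_max)]
    if f.size == 0:
        return np.empty(0), np.empty(0, dtype=int)
    grid = np.unique(f)[::-1]  # descending f
    f_sorted = np.sort(f)
    m_f = f.size - np.searchsorted(f_sorted, grid, side="left")
    return 1.0 / grid, m_f


def fit_neutral_model(
    inv_f_grid: np.ndarray,
    m_f: np.ndarray,
    f_max: float = DEFAULT_F_MAX,
    f_min: float = DEFAULT_F_MIN,
) -> NeutralFit:
    """Least-squares fit of M(f) = slope * (1/f - 1/f_max).

    The regression has no intercept (the model passes through zero at
    f = f_max), so R-squared is the uncentered coefficient of
    determination 1 - SS_res / sum(M^2), clipped to [0, 1].
    """
    x = np.asarray(inv_f_grid, dtype=float) - 1.0 / f_max
    y = np.asarray(m_f, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 grid points to fit the neutral model")
    sxx = float(np.dot(x, x))
    if sxx == 0:
        raise ValueError("degenerate grid: all frequencies equal f_max")
    slope = float(np.dot(x, y) / sxx)
    resid = y - slope * x
    ss_tot = float(np.dot(y, y))
    r2 = 1.0 - float(np.dot(resid, resid)) / ss_tot if ss_tot > 0 else 0.0
    return NeutralFit(
        f_min=f_min,
        f_max=f_max,
        inv_f_grid=np.asarray(inv_f_grid, dtype=float),
        m_f=y,
        slope=max(slope, 0.0),
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        n_subclonal=int(y.max()) if y.size else 0,
    )


def fit_neutral(
    vafs: Sequence[float],
    purity: float,
    f_min: float = DEFAULT_F_MIN,
    f_max: float = DEFAULT_F_MAX,
) -> NeutralFit:
    """Convenience wrapper: build the cumulative spectrum and fit it."""
    inv_f, m_f = cumulative_mf(vafs, purity, f_min=f_min, f_max=f_max)
    return fit_neutral_model(inv_f, m_f, f_max=f_max, f_min=f_min)
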