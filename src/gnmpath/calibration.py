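"""Cutoff-scaling scans: contact / triad counts versus cutoff radius.

Counts grow with cutoff; on a log-log plot the upper region is linear (pure
volume scaling) and the working cutoff sits at the boundary where the curve
departs from that line.  The boundary is detected as the largest cutoff whose
log-count deviates from the fitted line by more than a relative tolerance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structure import CalphaChain
from .topology import find_triad_cliques

logger = logging.getLogger(__name__)

__all__ = ["ScanResult", "contact_scan", "clique_scan"]


@dataclass(frozen=True)
class ScanResult:
    cutoffs: np.ndarray
    counts: np.ndarray
    log_slope: float
    log_intercept: float
    fit_range: tuple  # (cutoff_lo, cutoff_hi) used for the fit
    boundary_cutoff: float

    def to_csv(self) -> str:
        lines = ["cutoff,count"]
        for c, n in zip(self.cutoffs, self.counts):
            lines.append(f"{c:.2f},{int(n)}")
        return "\n".join(lines) + "\n"


def _grid(cutoff_min: float, cutoff_max: float, step: float) -> np.ndarray:
    n_steps = int(round((cutoff_max - cutoff_min) / step))
    return cutoff_min + step * np.arange(n_steps + 1)


def _fit_and_boundary(cutoffs, counts, fit_fraction, rel_tol):
    """Least-squares line on the upper log-log region; boundary by departure."""
    positive = counts > 0
    logc = np.full(len(cutoffs), np.nan)
    logc[positive] = np.log10(counts[positive])
    logx = np.log10(cutoffs)

    upper_start = int(np.ceil(len(cutoffs) * (1.0 - fit_fraction)))
    fit_idx = np.arange(upper_start, len(cutoffs))
    fit_idx = fit_idx[positive[fit_idx]]
    if len(fit_idx) < 2:
        logger.warning("not enough positive counts for a log-log fit")
        return 0.0, 0.0, (float(cutoffs[0]), float(cutoffs[-1])), float(cutoffs[0])
    slope, intercept = np.polyfit(logx[fit_idx], logc[fit_idx], 1)

    predicted = slope * logx + intercept
    with np.errstate(invalid="ignore", divide="ignore"):
        rel_dev = np.abs(logc - predicted) / np.maximum(np.abs(predicted), 1e-12)
    departing = np.nonzero(positive & (rel_dev > rel_tol))[0]
    boundary = cutoffs[departing[-1]] if len(departing) else cutoffs[0]
    return (
        float(slope),
        float(intercept),
        (float(cutoffs[fit_idx[0]]), float(cutoffs[fit_idx[-1]])),
        float(boundary),
    )


def contact_scan(
    chains,
    cutoff_min: float = 5.0,
    cutoff_max: float = 15.0,
    step: float = 0.1,
    fit_fraction: float = 0.5,
    rel_tol: float = 0.02,
) -> ScanResult:
    """Total unordered residue-pair contacts per cutoff, summed over chains."""
    chains = list(chains)
    if not chains:
        raise ValueError("need at least one chain")
    cutoffs = _grid(cutoff_min, cutoff_max, step)
    counts = np.zeros(len(cutoffs))
    for chain in chains:
        d = pdist(chain.coords)
        counts += (d[None, :] <= cutoffs[:, None]).sum(axis=1)
    slope, intercept, fit_range, boundary = _fit_and_boundary(
        cutoffs, counts, fit_fraction, rel_tol
    )
    return ScanResult(cutoffs, counts, slope, intercept, fit_range, boundary)


def clique_scan(
    chains,
    cutoff_min: float = 5.0,
    cutoff_max: float = 15.0,
    step: float = 0.1,
    min_separation: int = 4,
    fit_fraction: float = 0.5,
    rel_tol: float = 0.02,
) -> ScanResult:
    """Triad-clique counts per cutoff, summed over chains."""
    chains = list(chains)
    if not chains:
        raise ValueError("need at least one chain")
    cutoffs = _grid(cutoff_min, cutoff_max, step)
    counts = np.zeros(len(cutoffs))
    for chain in chains:
        res_ids = chain.res_ids
        dist = squareform(pdist(chain.coords))
        sep_ok = np.abs(res_ids[:, None] - res_ids[None, :]) >= min_separation
        for c_idx, cutoff in enumerate(cutoffs):
            adj = (dist <= cutoff) & sep_ok
            np.fill_diagonal(adj, False)
            a = adj.astype(np.int64)
            counts[c_idx] += np.trace(a @ a @ a) // 6
    slope, intercept, fit_range, boundary = _fit_and_boundary(
        cutoffs, counts, fit_fraction, rel_tol
    )
    return ScanResult(cutoffs, counts, slope, intercept, fit_range, boundary)
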