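"""Fastest-mode total coupling C_T: per-residue energy-exchange propensity.

For the eigenvector u of the mode_rank-th largest Kirchhoff eigenvalue
lambda, the total coupling of residue i to its surroundings is

    C_T(i) = w(lambda) * sum_j (u_i - u_j)^2

with mode weight w(lambda) = lambda by default (the fast mode carries the
energy exchange; with max-normalization the weight never changes support or
ranking within one mode).  The per-station minimum is subtracted so the
baseline is exactly zero, which makes "non-zero C_T" well defined.  Profiles
are computed at several cutoff stations, max-normalized per station,
averaged, and re-normalized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .structure import CalphaChain
from .gnm import GnmModel, build_model

logger = logging.getLogger(__name__)

__all__ = [
    "CouplingProfile",
    "total_coupling_single",
    "total_coupling_averaged",
    "find_peaks",
    "DEFAULT_STATION_MIN",
    "DEFAULT_STATION_MAX",
    "DEFAULT_N_STATIONS",
]

DEFAULT_STATION_MIN = 6.9
DEFAULT_STATION_MAX = 7.2
DEFAULT_N_STATIONS = 5

_MODE_WEIGHTS = {
    "lambda": lambda lam: lam,
    "inv-lambda": lambda lam: 1.0 / lam,
    "none": lambda lam: 1.0,
}


@dataclass(frozen=True)
class CouplingProfile:
    """Station-averaged, max-normalized total coupling per residue."""

    chain_ref: str
    residue_ids: np.ndarray
    residue_names: tuple
    stations: tuple
    per_station_ct: np.ndarray  # (n_stations, n) raw baseline-subtracted C_T
    averaged_ct: np.ndarray  # (n,) in [0, 1], max exactly 1
    mode_rank: int = 1

    @property
    def n(self) -> int:
        return len(self.residue_ids)

    @property
    def hub(self) -> int:
        """Residue number of the global maximum (lowest number on ties)."""
        top = np.nonzero(self.averaged_ct >= self.averaged_ct.max())[0]
        if len(top) > 1:
            logger.warning("hub tie among residues %s", self.residue_ids[top])
        return int(self.residue_ids[top].min())

    @property
    def peaks(self):
        return find_peaks(self)

    def path_residues(self, ct_threshold: float = 0.02) -> np.ndarray:
        """Author numbers of residues with averaged C_T at/above threshold."""
        return self.residue_ids[self.averaged_ct >= ct_threshold]

    def ct_of(self, res_id: int) -> float:
        idx = np.nonzero(self.residue_ids == res_id)[0]
        if len(idx) == 0:
            raise KeyError(f"residue {res_id} not in profile")
        return float(self.averaged_ct[idx[0]])


def total_coupling_single(
    model: GnmModel, mode_rank: int = 1, mode_weight: str = "lambda"
) -> np.ndarray:
    """Baseline-subtracted C_T vector for one mode of one model.

    Uses the identity sum_j (u_i - u_j)^2 = n u_i^2 + 1 - 2 u_i sum_j u_j
    for a unit eigenvector.
    """
    lam, u = model.fastest_mode(mode_rank)
    weight = _MODE_WEIGHTS[mode_weight](lam)
    ct = weight * (model.n * u**2 + 1.0 - 2.0 * u * u.sum())
    ct -= ct.min()
    # numerical floor: the minimum is exactly zero by construction
    return np.maximum(ct, 0.0)


def station_grid(
    station_min: float = DEFAULT_STATION_MIN,
    station_max: float = DEFAULT_STATION_MAX,
    n_stations: int = DEFAULT_N_STATIONS,
) -> np.ndarray:
    """Equally spaced cutoff stations, both endpoints included."""
    if n_stations < 1:
        raise ValueError("n_stations must be >= 1")
    if n_stations == 1:
        return np.array([station_min])
    if not station_min < station_max:
        raise ValueError("station_min must be < station_max")
    return np.linspace(station_min, station_max, n_stations)


def total_coupling_averaged(
    chain: CalphaChain,
    station_min: float = DEFAULT_STATION_MIN,
    station_max: float = DEFAULT_STATION_MAX,
    n_stations: int = DEFAULT_N_STATIONS,
    mode_rank: int = 1,
    mode_weight: str = "lambda",
) -> CouplingProfile:
    """Station-averaged fastest-mode coupling profile for one chain.

    Each station's C_T vector is max-normalized before averaging so no single
    station's eigenvalue scale dominates; the average is re-normalized to a
    maximum of exactly 1.
    """
    stations = station_grid(station_min, station_max, n_stations)
    per_station = np.zeros((len(stations), chain.n))
    normed = np.zeros_like(per_station)
    for s, cutoff in enumerate(stations):
        model = build_model(chain, cutoff)
        if not model.is_connected:
            logger.warning(
                "station %.3f A: disconnected contact graph (%d zero modes); "
                "proceeding on the largest eigenvalue",
                cutoff,
                model.n_zero_modes,
            )
        ct = total_coupling_single(model, mode_rank, mode_weight)
        per_station[s] = ct
        peak = ct.max()
        # a symmetric (flat) profile is numerical noise; do not amplify it
        normed[s] = ct / peak if peak > 1e-9 else np.zeros_like(ct)
    averaged = normed.mean(axis=0)
    peak = averaged.max()
    if peak > 1e-9:
        averaged = averaged / peak
    return CouplingProfile(
        chain_ref=f"{chain.pdb_id}/{chain.chain_id}",
        residue_ids=chain.res_ids.copy(),
        residue_names=chain.res_names,
        stations=tuple(float(s) for s in stations),
        per_station_ct=per_station,
        averaged_ct=averaged,
        mode_rank=mode_rank,
    )


def _segments(res_ids: np.ndarray):
    """Split observed-residue indices at author-numbering breaks (gap > 1)."""
    breaks = np.nonzero(np.diff(res_ids) > 1)[0]
    start = 0
    for b in breaks:
        yield np.arange(start, b + 1)
        start = b + 1
    yield np.arange(start, len(res_ids))


def find_peaks(profile: CouplingProfile, min_height_fraction: float = 0.02):
    """Local maxima of the averaged profile, highest first.

    A peak is strictly higher than both sequence neighbors; termini and
    residues flanking a chain break are compared to their single neighbor.
    Returns a list of (residue_id, height).
    """
    y = profile.averaged_ct
    found = []
    for seg in _segments(profile.residue_ids):
        v = y[seg]
        if len(v) == 1:
            if v[0] >= min_height_fraction:
                found.append((int(profile.residue_ids[seg[0]]), float(v[0])))
            continue
        left = np.empty(len(v))
        right = np.empty(len(v))
        left[0], left[1:] = -np.inf, v[:-1]
        right[-1], right[:-1] = -np.inf, v[1:]
        is_peak = (v > left) & (v > right) & (v >= min_height_fraction)
        for i in np.nonzero(is_peak)[0]:
            found.append((int(profile.residue_ids[seg[i]]), float(v[i])))
    found.sort(key=lambda p: (-p[1], p[0]))
    return found


def profile_to_tsv(
    profile: CouplingProfile, ct_threshold: float = 0.02
) -> str:
    """Residue-level report: number, name, averaged C_T, path/hub flags."""
    hub = profile.hub
    lines = ["residue_number\tresidue_name\taveraged_ct\tis_path_residue\tis_hub"]
    for rid, name, ct in zip(
        profile.residue_ids, profile.residue_names, profile.averaged_ct
    ):
        lines.append(
            f"{int(rid)}\t{name}\t{ct:.6f}\t{int(ct >= ct_threshold)}\t{int(rid == hub)}"
        )
    return "\n".join(lines) + "\n"
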