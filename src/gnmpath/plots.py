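"""Optional matplotlib conveniences: coupling profile line and fluctuation map."""

from __future__ import annotations

import numpy as np

from .coupling import CouplingProfile
from .gnm import GnmModel


def plot_coupling_profile(profile: CouplingProfile, ax=None, ct_threshold=0.02):
    """Averaged C_T versus residue number, hub marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    ax.plot(profile.residue_ids, profile.averaged_ct, lw=1.0, color="k")
    ax.axhline(ct_threshold, color="0.6", lw=0.8, ls="--")
    hub_ct = profile.ct_of(profile.hub)
    ax.annotate(
        str(profile.hub),
        (profile.hub, hub_ct),
        textcoords="offset points",
        xytext=(0, 4),
        ha="center",
        fontsize=8,
    )
    ax.set_xlabel("residue number")
    ax.set_ylabel("averaged $C_T$")
    ax.set_ylim(bottom=0)
    return ax


def plot_distance_fluctuation_map(model: GnmModel, mode_rank: int = 1, ax=None):
    """Contour-style map of the fastest-mode distance fluctuations."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4))
    fluct = model.distance_fluctuation([model.n - mode_rank])
    im = ax.imshow(fluct, origin="lower", cmap="Greys")
    ax.figure.colorbar(im, ax=ax, label="distance fluctuation")
    ax.set_xlabel("residue index")
    ax.set_ylabel("residue index")
    return ax
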