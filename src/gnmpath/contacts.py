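"""Bound-complex validation: ligand-contacting residues with non-zero coupling.

A holo residue counts as contacting when any of its heavy atoms lies strictly
within 3.5 A of any ligand atom AND the same author residue number carries an
averaged C_T at or above the threshold in the apo profile.  Apo/holo
correspondence is by author residue number (benchmark pairs share numbering).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .coupling import CouplingProfile
from .structure import LigandGroup, load_heavy_atom_residues, load_ligands

logger = logging.getLogger(__name__)

__all__ = ["ContactReport", "annotate_contacts", "annotate_all_ligands"]

DEFAULT_CONTACT_DISTANCE = 3.5


@dataclass(frozen=True)
class ContactReport:
    """Residues touching one ligand copy and predicted by the apo profile."""

    apo_id: str
    holo_id: str
    ligand: str
    contacting_residues: tuple  # of (res_id, res_name, min_atom_distance, averaged_ct)
    mapping_notes: tuple  # messages about residues absent from the apo profile

    @property
    def residue_ids(self) -> tuple:
        return tuple(r[0] for r in self.contacting_residues)

    def to_tsv(self) -> str:
        lines = ["residue\tmin_atom_distance\taveraged_ct"]
        for rid, name, d, ct in self.contacting_residues:
            lines.append(f"{name}{rid}\t{d:.2f}\t{ct:.4f}")
        return "\n".join(lines) + "\n"


def _check_numbering(holo_residues: dict, profile: CouplingProfile) -> list:
    profile_ids = set(int(r) for r in profile.residue_ids)
    holo_ids = {rid for rid, _ in holo_residues}
    shared = profile_ids & holo_ids
    if not shared:
        raise ValueError("numbering mismatch: no shared residue numbers "
                         "between apo profile and holo chain")
    notes = []
    for rid in sorted(holo_ids - profile_ids):
        notes.append(f"holo residue {rid} absent from apo profile")
    return notes


def annotate_contacts(
    holo_source,
    holo_chain: str,
    ligand: LigandGroup,
    apo_profile: CouplingProfile,
    ct_threshold: float = 0.02,
    contact_distance: float = DEFAULT_CONTACT_DISTANCE,
    holo_id: str | None = None,
) -> ContactReport:
    """Contact rule applied to one ligand copy against the apo prediction."""
    holo_residues = load_heavy_atom_residues(holo_source, holo_chain)
    notes = _check_numbering(holo_residues, apo_profile)
    for note in notes:
        logger.info("%s", note)

    lig_coords = ligand.coords
    profile_ids = {int(r): float(c)
                   for r, c in zip(apo_profile.residue_ids, apo_profile.averaged_ct)}
    rows = []
    for (rid, ins), (name, coords) in holo_residues.items():
        dmin = float(cdist(coords, lig_coords).min())
        if dmin >= contact_distance:
            continue
        ct = profile_ids.get(rid)
        if ct is None or ct < ct_threshold:
            continue
        rows.append((rid, name, dmin, ct))
    rows.sort(key=lambda r: r[0])
    return ContactReport(
        apo_id=apo_profile.chain_ref,
        holo_id=holo_id or str(holo_source)[:40],
        ligand=ligand.label,
        contacting_residues=tuple(rows),
        mapping_notes=tuple(notes),
    )


def annotate_all_ligands(
    holo_source,
    holo_chain: str,
    apo_profile: CouplingProfile,
    het_codes=None,
    ct_threshold: float = 0.02,
    contact_distance: float = DEFAULT_CONTACT_DISTANCE,
):
    """Per-copy reports for every (selected) ligand group plus a pooled set.

    Returns (reports, pooled_residue_ids).
    """
    ligands = load_ligands(holo_source, het_codes=het_codes)
    reports = [
        annotate_contacts(
            holo_source, holo_chain, lig, apo_profile,
            ct_threshold=ct_threshold, contact_distance=contact_distance,
        )
        for lig in ligands
    ]
    pooled = sorted({rid for rep in reports for rid in rep.residue_ids})
    return reports, tuple(pooled)
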