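"""Deterministic toy C-alpha chains and complexes for tests and demos.

Geometries are intentionally minimal: a regular polygon (every residue
symmetry-equivalent), an ideal helix, a seeded random coil, and a coil with
one compact sub-cluster of elevated coordination.  A complex writer emits
PDB text with simple backbone stubs plus a HETATM group and returns the
ground-truth contact set alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import CalphaChain, format_atom_line

__all__ = ["ToySpec", "make_chain", "make_complex"]

CA_SPACING = 3.8  # ideal consecutive C-alpha distance in A

# fixed backbone-stub offsets from the C-alpha (roughly bonded geometry)
_STUB_OFFSETS = {
    "N": np.array([-1.46, 0.0, 0.0]),
    "C": np.array([1.52, 0.0, 0.0]),
    "O": np.array([1.52, 1.23, 0.0]),
}


@dataclass(frozen=True)
class ToySpec:
    """Recipe for one toy chain; identical spec + seed is bit-reproducible."""

    kind: str  # ring | helix | random_coil | clustered
    n: int
    seed: int = 0
    spacing: float = CA_SPACING
    radius: float | None = None  # ring override
    rise: float = 1.5  # helix rise per residue
    turn_deg: float = 100.0  # helix rotation per residue
    cluster_size: int = 6
    cluster_tightness: float = 4.0  # max intra-cluster pair distance target
    first_res_id: int = 1
    chain_id: str = "A"


def _ring(spec: ToySpec) -> np.ndarray:
    radius = spec.radius or spec.spacing / (2.0 * np.sin(np.pi / spec.n))
    theta = 2.0 * np.pi * np.arange(spec.n) / spec.n
    return np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), np.zeros(spec.n)]
    )


def _helix(spec: ToySpec) -> np.ndarray:
    # radius chosen so consecutive C-alphas sit spacing apart given rise/turn
    turn = np.deg2rad(spec.turn_deg)
    chord = np.sqrt(max(spec.spacing**2 - spec.rise**2, 1e-6))
    radius = chord / (2.0 * np.sin(turn / 2.0))
    theta = turn * np.arange(spec.n)
    return np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), spec.rise * np.arange(spec.n)]
    )


def _random_coil(spec: ToySpec) -> np.ndarray:
    rng = np.random.default_rng(spec.seed)
    coords = np.zeros((spec.n, 3))
    direction = np.array([1.0, 0.0, 0.0])
    for i in range(1, spec.n):
        # biased random walk with fixed step; bias avoids immediate backtracking
        step = direction + 0.8 * rng.standard_normal(3)
        step /= np.linalg.norm(step)
        coords[i] = coords[i - 1] + spec.spacing * step
        direction = step
    return coords


def _clustered(spec: ToySpec) -> np.ndarray:
    """Extended tails with one dense blob in the middle.

    The chain is built sequentially so consecutive residues always stay in
    contact range: tail residues step ~3.6 A along +x, blob residues are
    confined to a ball of diameter cluster_tightness, which gives them a much
    higher coordination number than the tails.
    """
    if spec.cluster_size > spec.n:
        raise ValueError("cluster_size exceeds n")
    rng = np.random.default_rng(spec.seed)
    start = (spec.n - spec.cluster_size) // 2
    stop = start + spec.cluster_size
    step = spec.spacing * 0.95
    ball_radius = spec.cluster_tightness / 2.0
    # entry/exit stand-off keeps flank residues from out-coordinating the blob
    standoff = 7.3
    coords = np.zeros((spec.n, 3))
    exit_pos = None
    for i in range(1, spec.n):
        if start <= i < stop:
            if i == start:
                center = coords[i - 1] + np.array([standoff, 0.0, 0.0])
                exit_pos = center + np.array([standoff, 0.0, 0.0])
            for _ in range(1024):  # rejection-sample a fresh point in the ball
                candidate = center + ball_radius * rng.uniform(-1, 1, 3)
                if np.linalg.norm(candidate - center) > ball_radius:
                    continue
                gap = np.linalg.norm(candidate - coords[i - 1])
                if not 0.8 < gap <= 6.8:  # stay bonded to the previous residue
                    continue
                if i == stop - 1 and np.linalg.norm(exit_pos - candidate) > 6.8:
                    continue  # last blob residue must also bond to the exit
                coords[i] = candidate
                break
            else:
                raise ValueError("could not place cluster point")
        elif i == stop:
            coords[i] = exit_pos
        else:
            coords[i] = coords[i - 1] + np.array([step, 1.2 * (i % 2) - 0.6, 0.0])
    return coords


_BUILDERS = {
    "ring": _ring,
    "helix": _helix,
    "random_coil": _random_coil,
    "clustered": _clustered,
}


def make_chain(spec: ToySpec) -> CalphaChain:
    """Build the toy chain for a spec; raises on self-coincident geometry."""
    if spec.n < 3:
        raise ValueError("need n >= 3")
    if spec.kind not in _BUILDERS:
        raise ValueError(f"unknown toy kind {spec.kind!r}")
    coords = _BUILDERS[spec.kind](spec)
    from scipy.spatial.distance import pdist

    if pdist(coords).min() < 1e-6:
        raise ValueError("self-coincident points in toy geometry")
    res_ids = np.arange(spec.first_res_id, spec.first_res_id + spec.n)
    return CalphaChain(
        pdb_id=f"toy_{spec.kind}",
        chain_id=spec.chain_id,
        res_ids=res_ids,
        ins_codes=("",) * spec.n,
        res_names=("GLY",) * spec.n,
        coords=coords,
    )


def cluster_residue_ids(spec: ToySpec) -> np.ndarray:
    """Author numbers of the compressed window of a 'clustered' spec."""
    if spec.kind != "clustered":
        raise ValueError("only defined for clustered specs")
    start = (spec.n - spec.cluster_size) // 2
    return spec.first_res_id + start + np.arange(spec.cluster_size)


def make_complex(
    chain: CalphaChain,
    ligand_offset,
    n_ligand_atoms: int = 4,
    seed: int = 0,
    contact_distance: float = 3.5,
    with_backbone_stubs: bool = True,
):
    """PDB text for chain + one HETATM ligand group, with ground truth.

    The ligand atoms are scattered within 0.5 A of ``ligand_offset``.
    Returns (pdb_text, ground_truth) where ground_truth is the sorted tuple
    of residue numbers with any heavy atom strictly within contact_distance
    of any ligand atom.
    """
    rng = np.random.default_rng(seed)
    offset = np.asarray(ligand_offset, dtype=float)
    lig = offset + 0.5 * rng.uniform(-1.0, 1.0, size=(n_ligand_atoms, 3))
    lig[0] = offset  # anchor one atom exactly at the stated offset

    lines = []
    serial = 0
    ground_truth = []
    for rid, ins, name, ca in zip(
        chain.res_ids, chain.ins_codes, chain.res_names, chain.coords
    ):
        atoms = [("CA", ca, "C")]
        if with_backbone_stubs:
            atoms += [
                (aname, ca + off, aname[0]) for aname, off in _STUB_OFFSETS.items()
            ]
        dmin = np.inf
        for aname, xyz, element in atoms:
            serial += 1
            lines.append(
                format_atom_line(
                    "ATOM", serial, aname, name, chain.chain_id,
                    int(rid), *map(float, xyz), element, icode=ins,
                )
            )
            dmin = min(dmin, float(np.linalg.norm(lig - xyz, axis=1).min()))
        if dmin < contact_distance:
            ground_truth.append(int(rid))
    lines.append("TER")
    for a in range(n_ligand_atoms):
        serial += 1
        lines.append(
            format_atom_line(
                "HETATM", serial, f"C{a + 1}", "LIG", chain.chain_id,
                900, *map(float, lig[a]), "C",
            )
        )
    lines.append("END")
    return "\n".join(lines) + "\n", tuple(sorted(ground_truth))
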