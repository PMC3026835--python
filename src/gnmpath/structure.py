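"""PDB input: single-chain C-alpha traces, ligand groups and full-atom residues.

Only the deposited coordinates are used: MODEL 1, highest-occupancy altloc,
heavy atoms, non-zero occupancy.  Residue identity is the author residue
number plus insertion code throughout, since every report this package
produces is indexed that way.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

logger = logging.getLogger(__name__)

__all__ = [
    "CalphaChain",
    "LigandGroup",
    "ChainNotFoundError",
    "ChainTooShortError",
    "PdbFormatError",
    "load_calpha_chain",
    "load_ligands",
    "load_heavy_atom_residues",
    "chain_to_pdb",
]

WATER_CODES = frozenset({"HOH", "DOD", "WAT"})


class ChainNotFoundError(ValueError):
    """Requested chain id is absent from the file."""


class ChainTooShortError(ValueError):
    """Chain holds fewer than two C-alpha records."""


class PdbFormatError(ValueError):
    """Input could not be parsed as PDB."""


@dataclass(frozen=True)
class CalphaChain:
    """Ordered C-alpha trace of one chain.

    ``res_ids`` are author residue numbers; ``ins_codes`` the matching
    insertion codes ('' when none).  ``coords`` is an (n, 3) float array in Å.
    """

    pdb_id: str
    chain_id: str
    res_ids: np.ndarray
    ins_codes: tuple
    res_names: tuple
    coords: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "res_ids", np.asarray(self.res_ids, dtype=int))
        object.__setattr__(
            self, "coords", np.asarray(self.coords, dtype=float).reshape(-1, 3)
        )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinate in chain")
        keys = list(zip(self.res_ids.tolist(), self.ins_codes))
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (residue number, insertion code) in chain")

    @property
    def n(self) -> int:
        return len(self.res_ids)

    def distance_matrix(self) -> np.ndarray:
        from scipy.spatial.distance import squareform, pdist

        return squareform(pdist(self.coords))

    def name_of(self, res_id: int) -> str:
        idx = int(np.nonzero(self.res_ids == res_id)[0][0])
        return self.res_names[idx]


@dataclass(frozen=True)
class LigandGroup:
    """One HETATM group (het code + chain + residue number); never water."""

    het_code: str
    chain_id: str
    res_id: int
    atoms: tuple  # of (atom_name, (x, y, z))

    @property
    def coords(self) -> np.ndarray:
        return np.array([a[1] for a in self.atoms], dtype=float)

    @property
    def label(self) -> str:
        return f"{self.het_code}_{self.chain_id}_{self.res_id}"


def _read_atom_array(pdb_source):
    """Parse PDB text or a path; return the model-1 AtomArray, curated."""
    try:
        if isinstance(pdb_source, (str, os.PathLike)) and (
            not isinstance(pdb_source, str) or "\n" not in pdb_source
        ):
            pdb_file = PDBFile.read(pdb_source)
        else:
            pdb_file = PDBFile.read(io.StringIO(str(pdb_source)))
        arr = pdb_file.get_structure(
            model=1, altloc="occupancy", extra_fields=["occupancy"]
        )
    except Exception as exc:  # biotite raises several parse error types
        raise PdbFormatError(f"format error: {exc}") from exc
    keep = (arr.element != "H") & (arr.element != "D") & (arr.occupancy > 0)
    return arr[keep]


def _source_id(pdb_source) -> str:
    if isinstance(pdb_source, (str, os.PathLike)) and "\n" not in str(pdb_source):
        return os.path.splitext(os.path.basename(str(pdb_source)))[0]
    return "inline"


def load_calpha_chain(pdb_source, chain_id: str) -> CalphaChain:
    """Extract the C-alpha trace of ``chain_id`` (ATOM records, model 1).

    Alternate locations resolve to the highest-occupancy conformer; residues
    lacking a C-alpha are skipped with a warning.
    """
    arr = _read_atom_array(pdb_source)
    on_chain = arr[(arr.chain_id == chain_id) & ~arr.hetero]
    if on_chain.array_length() == 0:
        raise ChainNotFoundError(f"chain not found: {chain_id!r}")

    res_ids, ins_codes, res_names, coords = [], [], [], []
    seen = set()
    for res in struc.residue_iter(on_chain):
        rid = int(res.res_id[0])
        ins = str(res.ins_code[0])
        key = (rid, ins)
        if key in seen:  # altloc remnants collapse to first occurrence
            continue
        ca = res[res.atom_name == "CA"]
        if ca.array_length() == 0:
            logger.warning(
                "residue %s%d%s has no C-alpha; skipped", res.res_name[0], rid, ins
            )
            continue
        seen.add(key)
        res_ids.append(rid)
        ins_codes.append(ins)
        res_names.append(str(res.res_name[0]))
        coords.append(ca.coord[0])

    if len(res_ids) < 2:
        raise ChainTooShortError(
            f"chain too short: {len(res_ids)} C-alpha record(s) in chain {chain_id!r}"
        )
    return CalphaChain(
        pdb_id=_source_id(pdb_source),
        chain_id=chain_id,
        res_ids=np.array(res_ids),
        ins_codes=tuple(ins_codes),
        res_names=tuple(res_names),
        coords=np.array(coords),
    )


def load_ligands(pdb_source, het_codes=None) -> list[LigandGroup]:
    """All non-water HETATM groups, one per (code, chain, residue number).

    Single-atom groups (metal ions) are valid ligands.  ``het_codes``
    restricts the result to the listed codes.
    """
    arr = _read_atom_array(pdb_source)
    het = arr[arr.hetero]
    groups: list[LigandGroup] = []
    if het.array_length() == 0:
        return groups
    for res in struc.residue_iter(het):
        code = str(res.res_name[0])
        if code in WATER_CODES:
            continue
        if het_codes is not None and code not in het_codes:
            continue
        atoms = tuple(
            (str(name), tuple(float(x) for x in xyz))
            for name, xyz in zip(res.atom_name, res.coord)
        )
        groups.append(
            LigandGroup(
                het_code=code,
                chain_id=str(res.chain_id[0]),
                res_id=int(res.res_id[0]),
                atoms=atoms,
            )
        )
    return groups


def load_heavy_atom_residues(pdb_source, chain_id: str) -> dict:
    """Map (res_id, ins_code) -> (res_name, (k, 3) heavy-atom coords) for a chain.

    Full-atom view used by the bound-complex contact rule, which tests every
    heavy atom of a residue, not just the C-alpha.
    """
    arr = _read_atom_array(pdb_source)
    on_chain = arr[(arr.chain_id == chain_id) & ~arr.hetero]
    if on_chain.array_length() == 0:
        raise ChainNotFoundError(f"chain not found: {chain_id!r}")
    out = {}
    for res in struc.residue_iter(on_chain):
        key = (int(res.res_id[0]), str(res.ins_code[0]))
        if key in out:
            continue
        out[key] = (str(res.res_name[0]), np.array(res.coord, dtype=float))
    return out


_ATOM_FMT = (
    "{record:<6s}{serial:>5d} {name:<4s}{altloc:1s}{resname:<3s} {chain:1s}"
    "{resnum:>4d}{icode:1s}   {x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:>6.2f}{b:>6.2f}"
    "          {element:>2s}"
)


def format_atom_line(
    record: str,
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resnum: int,
    x: float,
    y: float,
    z: float,
    element: str,
    icode: str = "",
    occ: float = 1.0,
) -> str:
    # PDB v3 name justification: 1-2 char element names start in column 14
    padded = f" {name}" if len(name) < 4 else name
    return _ATOM_FMT.format(
        record=record,
        serial=serial,
        name=padded,
        altloc=" ",
        resname=resname,
        chain=chain,
        resnum=resnum,
        icode=icode or " ",
        x=x,
        y=y,
        z=z,
        occ=occ,
        b=0.0,
        element=element,
    )


def chain_to_pdb(chain: CalphaChain) -> str:
    """Minimal PDB text for a C-alpha trace (fixture writer)."""
    lines = []
    for serial, (rid, ins, name, xyz) in enumerate(
        zip(chain.res_ids, chain.ins_codes, chain.res_names, chain.coords), start=1
    ):
        lines.append(
            format_atom_line(
                "ATOM", serial, "CA", name, chain.chain_id,
                int(rid), *map(float, xyz), "C", icode=ins,
            )
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"
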