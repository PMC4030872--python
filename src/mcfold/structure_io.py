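"""Multi-model structure I/O and region selections.

Thin, validated layer over biotite's PDB reader/writer that presents
NMR-style multi-model files as an ordered :class:`ModelSet` of
:class:`StructureModel` objects, plus the residue-range selections every
ensemble analysis relies on.  Residue numbering follows the source file
verbatim (no renumbering), and modified residues such as phosphoserine
(SEP) are retained as ordinary residues whether they appear as ATOM or
HETATM records.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import (
    EmptyStructureError,
    InvalidParameterError,
    MissingRegionError,
    PDBParseError,
)

__all__ = [
    "StructureModel",
    "ModelSet",
    "RegionSpec",
    "read_models",
    "write_models",
    "select_region",
    "sidechain_center",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")
#: Atoms never counted as side chain (terminal oxygens included).
NON_SIDECHAIN = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclass
class StructureModel:
    """Atomic coordinates of one model with chain/residue indexing."""

    chain_id: np.ndarray
    res_id: np.ndarray
    res_name: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    coord: np.ndarray
    model_id: int = 0

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        for name in ("chain_id", "res_id", "res_name", "atom_name", "element"):
            setattr(self, name, np.asarray(getattr(self, name)))
        if len(self.coord) == 0:
            raise EmptyStructureError("structure model has no atoms")
        if not np.all(np.isfinite(self.coord)):
            raise PDBParseError(f"non-finite coordinates in model {self.model_id}")
        keys = list(zip(self.chain_id, self.res_id, self.atom_name))
        if len(set(keys)) != len(keys):
            raise PDBParseError(
                f"duplicate (chain, residue, atom) key in model {self.model_id}"
            )

    def __len__(self) -> int:
        return len(self.coord)

    @property
    def n_atoms(self) -> int:
        return len(self.coord)

    def chains(self) -> list[str]:
        seen = []
        for c in self.chain_id:
            if c not in seen:
                seen.append(str(c))
        return seen

    def residues(self, chain: str) -> np.ndarray:
        """Sorted residue numbers present in a chain."""
        return np.unique(self.res_id[self.chain_id == chain])

    def atom_coord(self, chain: str, res: int, atom: str) -> np.ndarray:
        mask = (
            (self.chain_id == chain) & (self.res_id == res) & (self.atom_name == atom)
        )
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise MissingRegionError(
                f"atom {atom} of residue {res} chain {chain} not found"
            )
        return self.coord[idx[0]]

    def to_atom_array(self) -> struc.AtomArray:
        arr = struc.AtomArray(self.n_atoms)
        arr.coord = self.coord.astype(np.float32)
        arr.chain_id = self.chain_id.astype("U4")
        arr.res_id = self.res_id.astype(int)
        arr.res_name = self.res_name.astype("U5")
        arr.atom_name = self.atom_name.astype("U6")
        arr.element = self.element.astype("U2")
        arr.hetero = np.array(
            [rn not in _STANDARD_RESIDUES for rn in self.res_name], dtype=bool
        )
        return arr

    @classmethod
    def from_atom_array(cls, arr: struc.AtomArray, model_id: int = 0) -> "StructureModel":
        return cls(
            chain_id=np.asarray(arr.chain_id),
            res_id=np.asarray(arr.res_id),
            res_name=np.asarray(arr.res_name),
            atom_name=np.asarray(arr.atom_name),
            element=np.asarray(arr.element),
            coord=np.asarray(arr.coord, dtype=float),
            model_id=model_id,
        )


_STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


class ModelSet:
    """An ordered list of models (e.g. the deposited NMR models)."""

    def __init__(self, models: Sequence[StructureModel]):
        if len(models) == 0:
            raise EmptyStructureError("ModelSet requires at least one model")
        self.models = list(models)

    def __len__(self) -> int:
        return len(self.models)

    def __getitem__(self, i) -> StructureModel:
        return self.models[i]

    def __iter__(self):
        return iter(self.models)


@dataclass
class RegionSpec:
    """Residue-range conventions of the flexible ligand chain.

    Defaults follow the pKID numbering of the reference complex: the two
    helical regions alphaA (120-131) and alphaB (134-145), the full
    analysed span 121-144, the orientation vectors alphaA 124->128 and
    alphaB 134->141 (CA to CA), and the phosphoserine marker residue 133.
    """

    chain_id: str = "B"
    alphaA: tuple[int, int] = (120, 131)
    alphaB: tuple[int, int] = (134, 145)
    all_region: tuple[int, int] = (121, 144)
    vectorA: tuple[int, int] = (124, 128)
    vectorB: tuple[int, int] = (134, 141)
    marker: int = 133

    def __post_init__(self):
        for name in ("vectorA", "vectorB"):
            start, end = getattr(self, name)
            if not start < end:
                raise InvalidParameterError(f"{name} needs start < end, got {start}, {end}")


def _prescan_pdb_text(text: str) -> None:
    """Validate MODEL/ENDMDL pairing and reject insertion codes."""
    open_line = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            if open_line is not None:
                raise PDBParseError(
                    f"line {lineno}: MODEL opened while MODEL at line {open_line} "
                    "is unterminated"
                )
            open_line = lineno
        elif rec == "ENDMDL":
            if open_line is None:
                raise PDBParseError(f"line {lineno}: ENDMDL without matching MODEL")
            open_line = None
        elif rec in ("ATOM", "HETATM"):
            if len(line) > 26 and line[26] != " ":
                raise PDBParseError(
                    f"line {lineno}: insertion code {line[26]!r} is not supported; "
                    "renumber the file first"
                )
    if open_line is not None:
        raise PDBParseError(f"MODEL at line {open_line} has no ENDMDL")


def read_models(source) -> ModelSet:
    """Read a (multi-model) PDB file into a :class:`ModelSet`.

    ``source`` is a path or a string of PDB text.  Files without MODEL
    records yield a single-model set.  Altloc conflicts take the first
    location; water and non-residue heteroatoms are kept as parsed.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        text = Path(source).read_text()
    else:
        text = str(source)
    _prescan_pdb_text(text)
    pdb = PDBFile.read(io.StringIO(text))
    n = pdb.get_model_count()
    if n == 0:
        raise EmptyStructureError("no atoms found in PDB source")
    models = []
    for i in range(1, n + 1):
        arr = pdb.get_structure(model=i, altloc="first")
        if arr.array_length() == 0:
            raise EmptyStructureError(f"model {i} contains no atoms")
        models.append(StructureModel.from_atom_array(arr, model_id=i - 1))
    return ModelSet(models)


def write_models(models: ModelSet | Iterable[StructureModel], path) -> None:
    """Write models as a multi-model PDB (MODEL/ENDMDL blocks)."""
    models = list(models)
    pdb = PDBFile()
    if len(models) == 1:
        pdb.set_structure(models[0].to_atom_array())
    else:
        stack = struc.stack([m.to_atom_array() for m in models])
        pdb.set_structure(stack)
    pdb.write(str(path))


def coords_to_csv(models: ModelSet, path) -> None:
    rows = []
    for m in models:
        for i in range(m.n_atoms):
            rows.append(
                (m.model_id, m.chain_id[i], int(m.res_id[i]), m.atom_name[i],
                 m.coord[i, 0], m.coord[i, 1], m.coord[i, 2])
            )
    pd.DataFrame(
        rows, columns=["model_id", "chain", "resnum", "atom", "x", "y", "z"]
    ).to_csv(path, index=False)


def _atom_order_key(name: str) -> tuple[int, str]:
    try:
        return (BACKBONE_ATOMS.index(name), "")
    except ValueError:
        return (len(BACKBONE_ATOMS), name)


def select_region(
    model: StructureModel,
    chain: str,
    res_range: tuple[int, int],
    atom_filter: str = "CA",
) -> np.ndarray:
    """Ordered coordinates of a chain/residue-range selection.

    ``atom_filter`` is one of ``CA``, ``backbone`` (N, CA, C, O),
    ``sidechain_heavy`` (heavy atoms excluding the backbone) or ``heavy``.
    Coordinates are ordered by residue number, then by canonical atom
    order (N, CA, C, O, remaining atoms alphabetically), independent of
    file order.  Residues missing from the range raise
    :class:`MissingRegionError` listing the absent numbers.
    """
    lo, hi = res_range
    wanted = list(range(int(lo), int(hi) + 1))
    present = set(int(r) for r in model.residues(chain))
    absent = [r for r in wanted if r not in present]
    if absent:
        raise MissingRegionError(
            f"chain {chain} is missing residues {absent} in range {lo}-{hi}"
        )
    coords = []
    for res in wanted:
        mask = (model.chain_id == chain) & (model.res_id == res)
        names = model.atom_name[mask]
        xyz = model.coord[mask]
        elem = model.element[mask]
        if atom_filter == "CA":
            keep = names == "CA"
        elif atom_filter == "backbone":
            keep = np.isin(names, BACKBONE_ATOMS)
        elif atom_filter == "sidechain_heavy":
            keep = np.array(
                [n not in NON_SIDECHAIN and e != "H" for n, e in zip(names, elem)]
            )
        elif atom_filter == "heavy":
            keep = elem != "H"
        else:
            raise InvalidParameterError(f"unknown atom filter {atom_filter!r}")
        if not np.any(keep):
            raise MissingRegionError(
                f"residue {res} chain {chain} has no atoms for filter {atom_filter!r}"
            )
        order = sorted(range(int(keep.sum())), key=lambda i: _atom_order_key(names[keep][i]))
        coords.append(xyz[keep][order])
    return np.concatenate(coords, axis=0)


def sidechain_center(model: StructureModel, chain: str, res: int) -> np.ndarray:
    """Unweighted geometric centre of a residue's side-chain heavy atoms.

    All heavy atoms excluding the backbone (N, CA, C, O, OXT) count as
    side chain -- for phosphoserine this includes the phosphate atoms.
    Glycine (no side-chain heavy atoms) falls back to its CA position.
    """
    mask = (model.chain_id == chain) & (model.res_id == res)
    if not np.any(mask):
        raise MissingRegionError(f"residue {res} chain {chain} not found")
    names = model.atom_name[mask]
    elem = model.element[mask]
    xyz = model.coord[mask]
    sc = np.array([n not in NON_SIDECHAIN and e != "H" for n, e in zip(names, elem)])
    if not np.any(sc):
        ca = names == "CA"
        if not np.any(ca):
            raise MissingRegionError(
                f"residue {res} chain {chain} has neither side-chain atoms nor CA"
            )
        return xyz[ca][0].copy()
    return xyz[sc].mean(axis=0)
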