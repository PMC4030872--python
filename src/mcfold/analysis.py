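"""Structural observables for coupled-folding-and-binding ensembles.

Implements the full analysis suite applied to conformational ensembles of
a flexible ligand chain on a (restrained) receptor framework:

* RMSD with optimal superposition (Kabsch) and without it -- the raw
  variant is meaningful because the receptor frame is held fixed, so
  absolute positions are comparable between conformations;
* minimum RMSD against a multi-model reference set;
* reaction coordinates R_aA, R_aB (region-centroid displacements from the
  reference) and the 2D potential of mean force over them;
* orientation inner products of helix-axis surrogate vectors;
* side-chain-centre residue contacts, native-contact sets from a
  multi-model reference (formed in at least a threshold number of
  models), and native/non-native contact counts per conformation;
* alpha-helix assignment by backbone hydrogen bonds (Kabsch-Sander
  electrostatic criterion, H state only) and per-residue helix content;
* solvent-accessible surface area (Shrake-Rupley) of residue regions in
  the context of the whole model;
* radial and spatial (voxel) densities of a marker atom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .constants import R_GAS
from .errors import InvalidParameterError, MissingRegionError
from .structure_io import ModelSet, StructureModel, select_region, sidechain_center

__all__ = [
    "LandscapeGrid",
    "NativeContactSet",
    "rmsd_superposed",
    "rmsd_raw",
    "min_rmsd_to_models",
    "centroid_displacement",
    "pmf_landscape",
    "orientation_inner_product",
    "contact_map",
    "native_contact_set",
    "classify_contacts",
    "helix_assign",
    "helix_content",
    "asa",
    "radial_distribution",
    "spatial_density",
    "filter_bound",
]

CONTACT_CUTOFF_DEFAULT = 6.5  # A, strict upper bound on side-chain-centre distance
NATIVE_SUPPORT_DEFAULT = 8    # of 17 reference models

#: Van der Waals radii (A) used for accessible-surface-area calculations.
VDW_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "P": 1.8, "H": 1.2}


# ---------------------------------------------------------------------------
# RMSD family


def _as_coords(x) -> np.ndarray:
    c = np.asarray(x, dtype=float)
    if c.ndim != 2 or c.shape[1] != 3:
        raise InvalidParameterError(f"expected (n, 3) coordinates, got shape {c.shape}")
    return c


def rmsd_superposed(coords_a, coords_b) -> float:
    """RMSD after optimal rigid superposition (Kabsch, proper rotation).

    Both sets are centred, the rotation minimising the residual is found
    with determinant +1 enforced, and the root-mean-square of the residual
    displacements is returned.
    """
    a, b = _as_coords(coords_a), _as_coords(coords_b)
    if a.shape != b.shape:
        raise InvalidParameterError(f"length mismatch: {a.shape} vs {b.shape}")
    if len(a) < 3:
        raise InvalidParameterError("need at least 3 atoms for superposition")
    a_c = a - a.mean(axis=0)
    b_c = b - b.mean(axis=0)
    _, rssd = Rotation.align_vectors(a_c, b_c)
    return float(rssd / np.sqrt(len(a)))


def rmsd_raw(coords_a, coords_b) -> float:
    """RMSD of raw coordinates, no fitting (shared-frame displacement)."""
    a, b = _as_coords(coords_a), _as_coords(coords_b)
    if a.shape != b.shape:
        raise InvalidParameterError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def min_rmsd_to_models(
    conf: StructureModel,
    models: ModelSet,
    chain: str,
    res_range: tuple[int, int],
    mode: str = "superposed",
    atom_filter: str = "CA",
) -> float:
    """Smallest RMSD of a region against each model of a reference set."""
    if len(models) == 0:
        raise InvalidParameterError("empty reference model set")
    if mode not in ("superposed", "raw"):
        raise InvalidParameterError(f"unknown RMSD mode {mode!r}")
    c = select_region(conf, chain, res_range, atom_filter)
    fn = rmsd_superposed if mode == "superposed" else rmsd_raw
    return min(fn(c, select_region(m, chain, res_range, atom_filter)) for m in models)


def centroid_displacement(
    conf: StructureModel,
    reference: StructureModel,
    chain: str,
    res_range: tuple[int, int],
    atom_filter: str = "CA",
) -> float:
    """Distance between region centroids in the shared frame (no fitting)."""
    c = select_region(conf, chain, res_range, atom_filter).mean(axis=0)
    r = select_region(reference, chain, res_range, atom_filter).mean(axis=0)
    return float(np.linalg.norm(c - r))


# ---------------------------------------------------------------------------
# Free-energy landscape


@dataclass
class LandscapeGrid:
    """Binned 2D potential of mean force over two reaction coordinates.

    ``pmf`` is NaN on unoccupied bins (undefined, not zero); the minimum
    over occupied bins is exactly zero.  Bin centres are integers times
    the bin width by default, i.e. bin (i, j) covers [i +- w/2, j +- w/2].
    """

    centers_i: np.ndarray
    centers_j: np.ndarray
    counts: np.ndarray
    pmf: np.ndarray
    T: float
    binwidth: float

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def occupied_probabilities(self) -> np.ndarray:
        """Renormalised exp(-PMF/RT); equals counts/total on occupied bins."""
        rt = R_GAS * self.T
        with np.errstate(invalid="ignore"):
            p = np.exp(-self.pmf / rt)
        p[~np.isfinite(p)] = 0.0
        return p / p.sum()

    def minima_locations(self, depth: float = 0.5) -> list[tuple[float, float]]:
        """Bin centres whose PMF lies within ``depth`` of the global minimum."""
        out = []
        with np.errstate(invalid="ignore"):
            mask = self.pmf <= depth
        for ii, jj in zip(*np.nonzero(mask)):
            out.append((float(self.centers_i[ii]), float(self.centers_j[jj])))
        return out

    def to_csv(self, path) -> None:
        rows = []
        for ii, ci in enumerate(self.centers_i):
            for jj, cj in enumerate(self.centers_j):
                v = self.pmf[ii, jj]
                rows.append(
                    (ci, cj, int(self.counts[ii, jj]), "" if np.isnan(v) else v)
                )
        pd.DataFrame(rows, columns=["R_aA", "R_aB", "count", "pmf"]).to_csv(
            path, index=False
        )


def pmf_landscape(
    values: Sequence[tuple[float, float]],
    T: float,
    binwidth: float = 1.0,
) -> LandscapeGrid:
    """PMF(i, j) = -RT ln(count_ij / total), minimum shifted to zero.

    Bins are ``binwidth``-wide squares centred on integer multiples of the
    bin width; bins with zero count are undefined (NaN).
    """
    vals = np.asarray(values, dtype=float)
    if vals.ndim != 2 or vals.shape[1] != 2 or len(vals) == 0:
        raise InvalidParameterError("values must be a non-empty (n, 2) array")
    if T <= 0:
        raise InvalidParameterError("T must be > 0")
    idx = np.rint(vals / binwidth).astype(int)
    i_max = int(idx[:, 0].max())
    j_max = int(idx[:, 1].max())
    counts = np.zeros((i_max + 1, j_max + 1), dtype=int)
    for i, j in idx:
        if i >= 0 and j >= 0:
            counts[i, j] += 1
    total = counts.sum()
    rt = R_GAS * T
    with np.errstate(divide="ignore"):
        pmf = -rt * np.log(counts / total)
    pmf[counts == 0] = np.nan
    pmf -= np.nanmin(pmf)
    return LandscapeGrid(
        centers_i=np.arange(i_max + 1) * binwidth,
        centers_j=np.arange(j_max + 1) * binwidth,
        counts=counts,
        pmf=pmf,
        T=float(T),
        binwidth=float(binwidth),
    )


# ---------------------------------------------------------------------------
# Orientation


def orientation_inner_product(
    conf: StructureModel,
    reference: StructureModel,
    chain: str,
    vector: tuple[int, int],
) -> float:
    """Inner product of unit CA->CA vectors in the shared frame.

    The vector points from the CA of the start residue to the CA of the
    end residue; +1 means the region is oriented as in the reference.
    """
    start, end = vector
    v_c = conf.atom_coord(chain, end, "CA") - conf.atom_coord(chain, start, "CA")
    v_r = reference.atom_coord(chain, end, "CA") - reference.atom_coord(chain, start, "CA")
    n_c, n_r = np.linalg.norm(v_c), np.linalg.norm(v_r)
    if n_c == 0 or n_r == 0:
        raise InvalidParameterError("zero-length orientation vector")
    return float(np.dot(v_c / n_c, v_r / n_r))


# ---------------------------------------------------------------------------
# Contacts


@dataclass
class NativeContactSet:
    """Inter-chain residue pairs contacting in enough reference models."""

    pairs: frozenset
    support: dict
    model_count: int
    threshold: int

    def __len__(self) -> int:
        return len(self.pairs)


def _chain_centers(model: StructureModel, chain: str):
    res = model.residues(chain)
    centers = np.array([sidechain_center(model, chain, int(r)) for r in res])
    return res, centers


def contact_map(
    model: StructureModel,
    chain_a: str,
    chain_b: str,
    cutoff: float = CONTACT_CUTOFF_DEFAULT,
) -> set[tuple[int, int]]:
    """Residue pairs whose side-chain centres are strictly within cutoff.

    Returns pairs as ``(residue of chain_a, residue of chain_b)``; a
    distance exactly equal to the cutoff is not a contact.
    """
    res_a, cen_a = _chain_centers(model, chain_a)
    res_b, cen_b = _chain_centers(model, chain_b)
    d = cdist(cen_a, cen_b)
    ia, ib = np.nonzero(d < cutoff)
    return {(int(res_a[i]), int(res_b[j])) for i, j in zip(ia, ib)}


def native_contact_set(
    models: ModelSet,
    chain_a: str,
    chain_b: str,
    cutoff: float = CONTACT_CUTOFF_DEFAULT,
    support_threshold: int = NATIVE_SUPPORT_DEFAULT,
) -> NativeContactSet:
    """Pairs contacting in at least ``support_threshold`` reference models."""
    support: dict[tuple[int, int], int] = {}
    for m in models:
        for pair in contact_map(m, chain_a, chain_b, cutoff):
            support[pair] = support.get(pair, 0) + 1
    pairs = frozenset(p for p, s in support.items() if s >= support_threshold)
    return NativeContactSet(
        pairs=pairs,
        support={p: support[p] for p in pairs},
        model_count=len(models),
        threshold=support_threshold,
    )


def classify_contacts(
    conf: StructureModel,
    native: NativeContactSet,
    chain_a: str,
    chain_b: str,
    cutoff: float = CONTACT_CUTOFF_DEFAULT,
) -> tuple[int, int]:
    """(N_nc, N_nnc): native and non-native contact counts of a conformation."""
    contacts = contact_map(conf, chain_a, chain_b, cutoff)
    n_nc = len(contacts & native.pairs)
    return n_nc, len(contacts) - n_nc


# ---------------------------------------------------------------------------
# Helix assignment (Kabsch-Sander H state)

_KS_COUPLING = 27.888  # kcal/mol * A, = 332 * 0.42 * 0.20
_KS_CUTOFF = -0.5      # kcal/mol
_NH_LENGTH = 1.0       # A, reconstructed amide H


def _backbone_table(model: StructureModel, chain: str):
    res = [int(r) for r in model.residues(chain)]
    table = {}
    missing = []
    for r in res:
        try:
            table[r] = {a: model.atom_coord(chain, r, a) for a in ("N", "CA", "C", "O")}
        except MissingRegionError:
            missing.append(r)
    if missing:
        raise MissingRegionError(
            f"chain {chain}: backbone atoms missing for residues {missing}"
        )
    return res, table


def _amide_h(n, ca, c_prev):
    """Reconstructed amide hydrogen: 1 A from N, opposing the bond bisector."""
    d1 = n - c_prev
    d2 = n - ca
    d1 /= np.linalg.norm(d1)
    d2 /= np.linalg.norm(d2)
    d = d1 + d2
    d /= np.linalg.norm(d)
    return n + _NH_LENGTH * d


def _hbond_energy(c, o, n, h):
    """Kabsch-Sander electrostatic hydrogen-bond energy (kcal/mol)."""
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 1e-6:
        return 0.0
    return _KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def helix_assign(model: StructureModel, chain: str) -> dict[int, bool]:
    """Per-residue alpha-helix flags from backbone hydrogen bonds.

    A backbone H-bond CO(i) -> NH(j) exists when the Kabsch-Sander
    electrostatic energy is below -0.5 kcal/mol, with the amide hydrogen
    reconstructed geometrically at 1 A from N opposite the bisector of
    its two covalent bonds.  An i -> i+4 H-bond defines a helical turn at
    i; a residue is alpha-helix (H state only -- 3-10 and pi helices do
    not count) when it lies in the span of two consecutive turns, the
    minimal-helix rule.  Proline and chain-numbering gaps break the
    pattern naturally because no donor/acceptor geometry is available.
    """
    res, bb = _backbone_table(model, chain)
    res_set = set(res)
    hpos = {}
    for r in res:
        if r - 1 in res_set:
            hpos[r] = _amide_h(bb[r]["N"], bb[r]["CA"], bb[r - 1]["C"])
    turn = {}
    for r in res:
        j = r + 4
        if j in res_set and j in hpos:
            e = _hbond_energy(bb[r]["C"], bb[r]["O"], bb[j]["N"], hpos[j])
            turn[r] = e < _KS_CUTOFF
    helix = {r: False for r in res}
    for r in res:
        if turn.get(r - 1) and turn.get(r):
            for j in range(r, r + 4):
                if j in helix:
                    helix[j] = True
    return helix


def helix_content(
    ensemble: Iterable[StructureModel],
    chain: str,
    res_range: tuple[int, int],
    weights: np.ndarray | None = None,
) -> pd.Series:
    """Per-residue mean helix flag over an ensemble (optionally weighted)."""
    lo, hi = res_range
    residues = list(range(int(lo), int(hi) + 1))
    ensemble = list(ensemble)
    if len(ensemble) == 0:
        raise InvalidParameterError("empty ensemble")
    if weights is None:
        w = np.full(len(ensemble), 1.0 / len(ensemble))
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    acc = np.zeros(len(residues))
    for wi, conf in zip(w, ensemble):
        flags = helix_assign(conf, chain)
        acc += wi * np.array([float(flags.get(r, False)) for r in residues])
    return pd.Series(acc, index=residues, name="helix_content")


# ---------------------------------------------------------------------------
# Accessible surface area


def asa(
    model: StructureModel,
    chain: str | None = None,
    res_range: tuple[int, int] | None = None,
    probe_radius: float = 1.4,
    point_number: int = 960,
) -> float:
    """Solvent-accessible surface area (A^2) of a region within the model.

    Shrake-Rupley with the stated probe and per-element radii (C 1.7,
    N 1.55, O 1.52, S 1.8, P 1.8 A).  Hydrogens are excluded from both the
    surface and the occlusion.  The whole model occludes the region, so
    binding partners bury interface area.  With ``chain``/``res_range``
    omitted the total ASA of the model is returned.
    """
    heavy = model.element != "H"
    arr = StructureModel(
        chain_id=model.chain_id[heavy],
        res_id=model.res_id[heavy],
        res_name=model.res_name[heavy],
        atom_name=model.atom_name[heavy],
        element=model.element[heavy],
        coord=model.coord[heavy],
        model_id=model.model_id,
    ).to_atom_array()
    radii = np.empty(arr.array_length())
    for i, el in enumerate(arr.element):
        if el not in VDW_RADII:
            raise InvalidParameterError(
                f"unknown element {el!r} for atom {arr.atom_name[i]} "
                f"residue {int(arr.res_id[i])}"
            )
        radii[i] = VDW_RADII[el]
    # degenerate input: exactly coincident atoms are collapsed to the one
    # with the largest radius (a point exactly on a sphere's surface does
    # not count as buried, so duplicates would otherwise double the area)
    order = np.lexsort((-radii, arr.coord[:, 2], arr.coord[:, 1], arr.coord[:, 0]))
    keep = np.ones(arr.array_length(), dtype=bool)
    for i, j in zip(order[:-1], order[1:]):
        if np.array_equal(arr.coord[i], arr.coord[j]):
            keep[j] = False
    if not np.all(keep):
        arr = arr[keep]
        radii = radii[keep]

    # explicit all-atom filter: modified residues (e.g. phosphoserine) and
    # lone atoms must not fall through biotite's default solvent filtering
    per_atom = struc.sasa(
        arr,
        probe_radius=probe_radius,
        point_number=point_number,
        vdw_radii=radii,
        atom_filter=np.ones(arr.array_length(), dtype=bool),
        ignore_ions=False,
    )
    per_atom = np.nan_to_num(per_atom)
    if chain is None:
        return float(per_atom.sum())
    mask = arr.chain_id == chain
    if res_range is not None:
        lo, hi = res_range
        mask &= (arr.res_id >= lo) & (arr.res_id <= hi)
    if not np.any(mask):
        raise MissingRegionError(f"no atoms for chain {chain} range {res_range}")
    return float(per_atom[mask].sum())


# ---------------------------------------------------------------------------
# Marker densities


def radial_distribution(
    points: np.ndarray,
    reference: np.ndarray,
    binwidth: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Probability density of the distance to a reference point.

    Returns (bin centres, density per A); the density integrates to one
    over r.
    """
    pts = _as_coords(points)
    r = np.linalg.norm(pts - np.asarray(reference, dtype=float), axis=1)
    n_bins = max(1, int(np.ceil((r.max() + binwidth) / binwidth)))
    counts, edges = np.histogram(r, bins=n_bins, range=(0.0, n_bins * binwidth))
    density = counts / (len(r) * binwidth)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, density


@dataclass
class VoxelDensity:
    """Probability density (A^-3) on a regular 3D grid."""

    origin: np.ndarray
    spacing: float
    density: np.ndarray

    def threshold_volume(self, iso: float) -> float:
        """Total volume (A^3) of voxels with density above ``iso``."""
        return float(np.sum(self.density > iso) * self.spacing**3)

    def peak_position(self) -> np.ndarray:
        idx = np.unravel_index(np.argmax(self.density), self.density.shape)
        return self.origin + (np.asarray(idx) + 0.5) * self.spacing

    def to_csv(self, path) -> None:
        rows = []
        for idx in zip(*np.nonzero(self.density > 0)):
            c = self.origin + (np.asarray(idx) + 0.5) * self.spacing
            rows.append((c[0], c[1], c[2], self.density[idx]))
        pd.DataFrame(rows, columns=["x", "y", "z", "density"]).to_csv(path, index=False)


def spatial_density(points: np.ndarray, spacing: float = 1.0) -> VoxelDensity:
    """Voxelised probability density of 3D positions.

    Voxel value = count / (N * voxel volume), so the densities integrate
    to one and iso-levels are in A^-3.
    """
    pts = _as_coords(points)
    origin = np.floor(pts.min(axis=0) / spacing) * spacing
    idx = np.floor((pts - origin) / spacing).astype(int)
    shape = idx.max(axis=0) + 1
    counts = np.zeros(shape, dtype=int)
    for i in idx:
        counts[tuple(i)] += 1
    density = counts / (len(pts) * spacing**3)
    return VoxelDensity(origin=origin, spacing=float(spacing), density=density)


# ---------------------------------------------------------------------------
# Bound-state filter


def filter_bound(
    values: Sequence[tuple[float, float]],
    thresholds: tuple[float, float] = (13.0, 7.0),
) -> np.ndarray:
    """Indices of conformations with R_aA <= t_A and R_aB <= t_B (inclusive)."""
    vals = np.atleast_2d(np.asarray(values, dtype=float))
    t_a, t_b = thresholds
    return np.flatnonzero((vals[:, 0] <= t_a) & (vals[:, 1] <= t_b))
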