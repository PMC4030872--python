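"""Synthetic structural ensembles with planted ground truth.

Every analysis operation in :mod:`mcfold.analysis` is testable without
external downloads against ensembles whose statistical structure is known
exactly by construction.  The generator emulates the features the real
coupled-folding-and-binding analyses rely on:

* a rigid receptor chain (the restrained binding framework) plus a
  28-residue flexible ligand chain numbered 119-146, with the two helical
  regions, orientation vectors and phosphoserine-like marker residue 133
  of the standard region conventions;
* a pseudo-NMR reference set of jittered copies of the native complex, in
  which planted inter-chain contacts are formed in an exactly controlled
  number of models (so the at-least-k-of-n native-contact rule has an
  exact answer);
* a conformational ensemble drawn from a three-component binding-pose
  mixture -- native-like (regions anchored at their reference positions,
  planted native contacts formed), misoriented (the alphaB helix bound
  with its axis reversed, planted non-native contacts), and unbound (the
  ligand displaced far from the receptor);
* per-residue helix propensities realised as region-cooperative draws:
  one uniform variate per region per conformation decides which residues
  adopt helical dihedrals, so the expected helix content of a
  region-interior residue equals its propensity exactly.  In bound poses
  the alphaB region is always helical (it folds upon binding); the
  propensities govern the unbound state.

Backbones are built residue-by-residue from ideal geometry; side chains
are a single pseudo-atom at the CB position (plus a phosphate-like P atom
on residue 133), which is what the side-chain-centre contact rules see.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import InvalidParameterError
from .structure_io import ModelSet, RegionSpec, StructureModel

__all__ = ["SyntheticConfig", "make_reference_models", "sample_ensemble", "planted_truth"]

# Ideal backbone geometry (bond lengths A, angles deg)
B_N_CA, B_CA_C, B_C_N, B_C_O, B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.53
A_N_CA_C, A_CA_C_N, A_C_N_CA, A_CA_C_O = 111.2, 116.2, 121.7, 120.5
PHI_HELIX, PSI_HELIX = -57.0, -47.0
COIL_PHI = (-150.0, -60.0)
COIL_PSI = (90.0, 180.0)

LIG_CHAIN, REC_CHAIN = "B", "A"
LIG_FIRST, LIG_LAST = 119, 146
MARKER_RES = 133

# Default planted contacts, (ligand residue, receptor residue).  Receptor
# binding-site residues are spaced >= 6 residues (9 A along the helix
# axis) and each ligand residue is paired with the site nearest its own
# axial position, so a planted side chain cannot stray within the contact
# cutoff of a neighbouring site.
NATIVE_PAIRS_DEFAULT = (
    (121, 14), (124, 14), (125, 14),          # alphaA block
    (132, 24),                                # loop
    (135, 30), (138, 30), (139, 30),          # alphaB block
    (141, 36), (142, 36),
)
NONNATIVE_PAIRS_DEFAULT = ((136, 42), (139, 42), (140, 6), (143, 6))


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic generator.

    ``helix_propensity`` maps region names (``alphaA``, ``alphaB``,
    ``other``) or individual residue numbers to propensities in [0, 1];
    defaults reflect a nascent-helix unbound state in which the
    N-terminal region is roughly twice as helical as the C-terminal one.
    ``pose_weights`` are the (native-like, misoriented, unbound) mixture
    fractions.  ``support`` optionally overrides, per planted pair, the
    number of reference models in which the contact is formed.
    """

    n_models: int = 17
    model_jitter_sigma: float = 0.3
    n_conformations: int = 2000
    helix_propensity: dict = field(
        default_factory=lambda: {"alphaA": 0.4, "alphaB": 0.2, "other": 0.05}
    )
    pose_weights: tuple[float, float, float] = (0.5, 0.3, 0.2)
    native_pairs: tuple = NATIVE_PAIRS_DEFAULT
    nonnative_pairs: tuple = NONNATIVE_PAIRS_DEFAULT
    support: dict = field(default_factory=dict)
    marker_anchor_sigma: float = 1.0
    pose_noise_sigma: float = 0.5
    contact_distance: float = 5.0
    broken_distance: float = 9.0
    misoriented_offset: float = 8.0
    #: centroid displacement of the unbound pose.  A fully extended
    #: 28-residue chain reaches ~49 A from its centroid, so the distance
    #: must exceed that reach plus the receptor clearance for the unbound
    #: pose to be contact-free by construction.
    unbound_distance: float = 60.0
    receptor_n_res: int = 48
    seed: int = 0
    regions: RegionSpec = field(default_factory=lambda: RegionSpec(chain_id=LIG_CHAIN))

    def __post_init__(self):
        w = np.asarray(self.pose_weights, dtype=float)
        if w.shape != (3,) or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise InvalidParameterError(
                f"pose weights must be 3 non-negative numbers summing to 1, got {self.pose_weights}"
            )
        for r, h in self.residue_propensities().items():
            if not (0.0 <= h <= 1.0):
                raise InvalidParameterError(f"propensity {h} of residue {r} outside [0, 1]")
        if self.n_models < 1:
            raise InvalidParameterError("n_models must be >= 1")

    def residue_propensities(self) -> dict[int, float]:
        reg = self.regions
        out = {}
        for r in range(LIG_FIRST, LIG_LAST + 1):
            if reg.alphaA[0] <= r <= reg.alphaA[1]:
                key = "alphaA"
            elif reg.alphaB[0] <= r <= reg.alphaB[1]:
                key = "alphaB"
            else:
                key = "other"
            out[r] = float(self.helix_propensity.get(r, self.helix_propensity.get(key, 0.0)))
        return out

    def region_of(self, r: int) -> str:
        reg = self.regions
        if reg.alphaA[0] <= r <= reg.alphaA[1]:
            return "alphaA"
        if reg.alphaB[0] <= r <= reg.alphaB[1]:
            return "alphaB"
        return "other"


# ---------------------------------------------------------------------------
# Ideal-geometry backbone construction


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position of atom D from internal coordinates w.r.t. chain A-B-C."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def _cb_position(n, ca, c) -> np.ndarray:
    """Pseudo side-chain carbon at the tetrahedral CB site."""
    n1 = (n - ca) / np.linalg.norm(n - ca)
    n2 = (c - ca) / np.linalg.norm(c - ca)
    d = np.cross(n1, n2)
    d /= np.linalg.norm(d)
    e = (n1 + n2) / np.linalg.norm(n1 + n2)
    return ca + B_CA_CB * (-0.620 * e + 0.785 * d)


def build_chain(
    phi: np.ndarray,
    psi: np.ndarray,
    chain_id: str,
    first_res: int,
    marker_res: int | None = None,
) -> StructureModel:
    """Build an n-residue backbone (N, CA, C, O, CB) from dihedral angles.

    ``phi[0]`` is unused (no preceding carbonyl); omega is fixed at 180.
    The marker residue, when present, is named SEP and carries an extra
    phosphorus pseudo-atom extending the CB direction.
    """
    n_res = len(phi)
    N = np.empty((n_res, 3))
    CA = np.empty((n_res, 3))
    C = np.empty((n_res, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (B_N_CA, 0.0, 0.0)
    ang = np.deg2rad(A_N_CA_C)
    C[0] = CA[0] + B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n_res):
        N[i] = _place_atom(N[i - 1], CA[i - 1], C[i - 1], B_C_N, A_CA_C_N, psi[i - 1])
        CA[i] = _place_atom(CA[i - 1], C[i - 1], N[i], B_N_CA, A_C_N_CA, 180.0)
        C[i] = _place_atom(C[i - 1], N[i], CA[i], B_CA_C, A_N_CA_C, phi[i])
    rows = []
    for i in range(n_res):
        res = first_res + i
        o = _place_atom(N[i], CA[i], C[i], B_C_O, A_CA_C_O, psi[i] + 180.0)
        cb = _cb_position(N[i], CA[i], C[i])
        name = "SEP" if res == marker_res else "ALA"
        rows.append((res, name, "N", "N", N[i]))
        rows.append((res, name, "CA", "C", CA[i]))
        rows.append((res, name, "C", "C", C[i]))
        rows.append((res, name, "O", "O", o))
        rows.append((res, name, "CB", "C", cb))
        if res == marker_res:
            p = cb + 1.5 * (cb - CA[i]) / np.linalg.norm(cb - CA[i])
            rows.append((res, name, "P", "P", p))
    return StructureModel(
        chain_id=np.array([chain_id] * len(rows)),
        res_id=np.array([r[0] for r in rows]),
        res_name=np.array([r[1] for r in rows]),
        atom_name=np.array([r[2] for r in rows]),
        element=np.array([r[3] for r in rows]),
        coord=np.array([r[4] for r in rows]),
    )


def _helical_angles(n_res: int) -> tuple[np.ndarray, np.ndarray]:
    return np.full(n_res, PHI_HELIX), np.full(n_res, PSI_HELIX)


def _axis_align_transform(model: StructureModel, chain: str, centroid_to: np.ndarray):
    """Rotation + translation mapping the CA axis to +x, centroid to a point."""
    ca = model.coord[model.atom_name == "CA"]
    axis = ca[-1] - ca[0]
    axis /= np.linalg.norm(axis)
    rot, _ = Rotation.align_vectors(np.array([[1.0, 0.0, 0.0]]), axis[None, :])
    center = ca.mean(axis=0)
    return rot, center, np.asarray(centroid_to, dtype=float)


def _apply_transform(coords, rot: Rotation, center, target):
    return rot.apply(coords - center) + target


def _transform_model(model: StructureModel, rot, center, target) -> StructureModel:
    out = _copy_model(model)
    out.coord = _apply_transform(model.coord, rot, center, target)
    return out


def _copy_model(model: StructureModel) -> StructureModel:
    return StructureModel(
        chain_id=model.chain_id.copy(),
        res_id=model.res_id.copy(),
        res_name=model.res_name.copy(),
        atom_name=model.atom_name.copy(),
        element=model.element.copy(),
        coord=model.coord.copy(),
        model_id=model.model_id,
    )


def _merge(parts: list[StructureModel], model_id: int = 0) -> StructureModel:
    return StructureModel(
        chain_id=np.concatenate([p.chain_id for p in parts]),
        res_id=np.concatenate([p.res_id for p in parts]),
        res_name=np.concatenate([p.res_name for p in parts]),
        atom_name=np.concatenate([p.atom_name for p in parts]),
        element=np.concatenate([p.element for p in parts]),
        coord=np.concatenate([p.coord for p in parts]),
        model_id=model_id,
    )


def _set_atom(model: StructureModel, chain: str, res: int, atom: str, pos) -> None:
    mask = (model.chain_id == chain) & (model.res_id == res) & (model.atom_name == atom)
    model.coord[mask] = np.asarray(pos, dtype=float)


def _receptor_scaffold(config: SyntheticConfig) -> StructureModel:
    """Rigid receptor: an ideal helix along x with side chains re-pointed.

    Binding-site residues (the planted contact partners) extend their CB
    pseudo-atom toward the ligand side (+y); all other side chains point
    away, keeping the groove clean so contacts are controlled solely by
    ligand side-chain placement.
    """
    phi, psi = _helical_angles(config.receptor_n_res)
    rec = build_chain(phi, psi, REC_CHAIN, 1)
    rot, center, target = _axis_align_transform(rec, REC_CHAIN, (0.0, -21.0, 0.0))
    rec = _transform_model(rec, rot, center, target)
    site_res = {r for _, r in config.native_pairs} | {r for _, r in config.nonnative_pairs}
    for r in range(1, config.receptor_n_res + 1):
        ca = rec.atom_coord(REC_CHAIN, r, "CA")
        if r in site_res:
            _set_atom(rec, REC_CHAIN, r, "CB", ca + np.array([0.0, 5.5, 0.0]))
        else:
            _set_atom(rec, REC_CHAIN, r, "CB", ca + np.array([0.0, -2.0, 0.0]))
    return rec


def _reference_ligand() -> StructureModel:
    n_res = LIG_LAST - LIG_FIRST + 1
    phi, psi = _helical_angles(n_res)
    lig = build_chain(phi, psi, LIG_CHAIN, LIG_FIRST, marker_res=MARKER_RES)
    rot, center, target = _axis_align_transform(lig, LIG_CHAIN, (0.0, 0.0, 0.0))
    return _transform_model(lig, rot, center, target)


def _receptor_center(rec: StructureModel, res: int) -> np.ndarray:
    return rec.atom_coord(REC_CHAIN, res, "CB")


def _plant_contact(lig, rec, lig_res: int, rec_res: int, distance: float) -> None:
    """Place a ligand CB at an exact distance from a receptor centre."""
    c = _receptor_center(rec, rec_res)
    ca = lig.atom_coord(LIG_CHAIN, lig_res, "CA")
    u = ca - c
    u /= np.linalg.norm(u)
    _set_atom(lig, LIG_CHAIN, lig_res, "CB", c + distance * u)


def reference_complex(config: SyntheticConfig) -> StructureModel:
    """The jitter-free native complex all reference models derive from."""
    rec = _receptor_scaffold(config)
    lig = _reference_ligand()
    for lig_res, rec_res in config.native_pairs:
        _plant_contact(lig, rec, lig_res, rec_res, config.contact_distance)
    return _merge([rec, lig])


def make_reference_models(config: SyntheticConfig) -> ModelSet:
    """Pseudo-NMR reference set: jittered copies with exact contact support.

    Each planted pair is formed (distance = ``contact_distance``) in
    exactly ``support[pair]`` models (default: all) and broken (distance =
    ``broken_distance``) in the rest, placed after jitter so the support
    counts are exact by construction.  Deterministic given the config seed.
    """
    rng = np.random.default_rng(config.seed)
    base = reference_complex(config)
    models = []
    for m in range(config.n_models):
        mod = _copy_model(base)
        mod.model_id = m
        if config.model_jitter_sigma > 0:
            mod.coord = mod.coord + rng.normal(
                0.0, config.model_jitter_sigma, size=mod.coord.shape
            )
        rec_view = mod  # single merged model; receptor atoms addressed by chain
        for lig_res, rec_res in config.native_pairs:
            s = int(config.support.get((lig_res, rec_res), config.n_models))
            d = config.contact_distance if m < s else config.broken_distance
            c = rec_view.atom_coord(REC_CHAIN, rec_res, "CB")
            ca = mod.atom_coord(LIG_CHAIN, lig_res, "CA")
            u = ca - c
            u /= np.linalg.norm(u)
            _set_atom(mod, LIG_CHAIN, lig_res, "CB", c + d * u)
        models.append(mod)
    return ModelSet(models)


# ---------------------------------------------------------------------------
# Ensemble generation


def _region_mask(config: SyntheticConfig, rng) -> dict[int, bool]:
    """Region-cooperative helicity draws: one uniform variate per region."""
    u = {"alphaA": rng.uniform(), "alphaB": rng.uniform(), "other": rng.uniform()}
    prop = config.residue_propensities()
    return {r: u[config.region_of(r)] < prop[r] for r in prop}


def _chain_angles(mask: dict[int, bool], rng) -> tuple[np.ndarray, np.ndarray]:
    n = LIG_LAST - LIG_FIRST + 1
    phi = np.empty(n)
    psi = np.empty(n)
    for i, r in enumerate(range(LIG_FIRST, LIG_LAST + 1)):
        if mask[r]:
            phi[i], psi[i] = PHI_HELIX, PSI_HELIX
        else:
            phi[i] = rng.uniform(*COIL_PHI)
            psi[i] = rng.uniform(*COIL_PSI)
    return phi, psi


def _fit_segment(coords_mobile_ca, coords_target_ca, segment_coords):
    """Kabsch-superpose a segment by its region CA atoms onto target CAs.

    The optimal translation matches the CA centroids exactly, so the
    region's centroid displacement from the target is exactly zero.
    """
    mc = coords_mobile_ca.mean(axis=0)
    tc = coords_target_ca.mean(axis=0)
    rot, _ = Rotation.align_vectors(coords_target_ca - tc, coords_mobile_ca - mc)
    return rot.apply(segment_coords - mc) + tc


def _segment_atoms(model: StructureModel, lo: int, hi: int) -> np.ndarray:
    return np.flatnonzero(
        (model.chain_id == LIG_CHAIN) & (model.res_id >= lo) & (model.res_id <= hi)
    )


def _region_ca(model: StructureModel, lo: int, hi: int) -> np.ndarray:
    mask = (
        (model.chain_id == LIG_CHAIN)
        & (model.res_id >= lo)
        & (model.res_id <= hi)
        & (model.atom_name == "CA")
    )
    return model.coord[mask]


def _enumerate_contacts(conf: StructureModel, cutoff: float = 6.5) -> set:
    """Direct double-loop contact enumeration used as generator ground truth."""
    out = set()
    lig_res = conf.residues(LIG_CHAIN)
    rec_res = conf.residues(REC_CHAIN)
    lig_centers = {}
    for r in lig_res:
        mask = (
            (conf.chain_id == LIG_CHAIN)
            & (conf.res_id == r)
            & np.isin(conf.atom_name, ("CB", "P"))
        )
        lig_centers[int(r)] = conf.coord[mask].mean(axis=0)
    for r in rec_res:
        c = conf.atom_coord(REC_CHAIN, int(r), "CB")
        for lr, lc in lig_centers.items():
            if np.linalg.norm(lc - c) < cutoff:
                out.add((lr, int(r)))
    return out


def sample_ensemble(
    config: SyntheticConfig,
) -> tuple[list[StructureModel], dict]:
    """Draw a conformational ensemble from the pose mixture.

    Returns the conformations (receptor + posed ligand, one model each)
    and a truth record with per-conformation pose labels, realised
    helicity masks, exact contact lists (by direct enumeration), and the
    marker-atom positions.  Deterministic given the config seed.
    """
    rng = np.random.default_rng(config.seed + 1)
    reg = config.regions
    ref = reference_complex(config)
    ref_aA_ca = _region_ca(ref, *reg.alphaA)
    ref_aB_ca = _region_ca(ref, *reg.alphaB)
    aB_centroid = ref_aB_ca.mean(axis=0)
    flip = Rotation.from_rotvec([0.0, 0.0, np.pi])
    ref_aB_ca_flipped = flip.apply(ref_aB_ca - aB_centroid) + aB_centroid
    loop_idx_ref = _segment_atoms(ref, reg.alphaA[1] + 1, reg.alphaB[0] - 1)
    lig_centroid_ref = ref.coord[
        (ref.chain_id == LIG_CHAIN) & (ref.atom_name == "CA")
    ].mean(axis=0)
    rec_only = _copy_model(ref)
    rec_mask = rec_only.chain_id == REC_CHAIN
    rec_only = StructureModel(
        chain_id=ref.chain_id[rec_mask],
        res_id=ref.res_id[rec_mask],
        res_name=ref.res_name[rec_mask],
        atom_name=ref.atom_name[rec_mask],
        element=ref.element[rec_mask],
        coord=ref.coord[rec_mask],
    )
    pose_names = ("native", "misoriented", "unbound")
    conformations = []
    truth = {
        "pose": [],
        "helical_mask": [],
        "contacts": [],
        "marker_position": [],
    }
    for k in range(config.n_conformations):
        pose = pose_names[rng.choice(3, p=config.pose_weights)]
        mask = _region_mask(config, rng)
        if pose != "unbound":
            for r in range(reg.alphaB[0], reg.alphaB[1] + 1):
                mask[r] = True  # alphaB folds upon binding
        phi, psi = _chain_angles(mask, rng)
        lig = build_chain(phi, psi, LIG_CHAIN, LIG_FIRST, marker_res=MARKER_RES)
        if pose == "unbound":
            rot = Rotation.random(rng=rng)
            # displacement into the +y half-space, away from the receptor
            # (which sits at negative y), so no chain conformation reaches it
            direction = rng.normal(size=3)
            direction = np.array(
                [0.4 * direction[0], abs(direction[1]) + 2.5, 0.4 * direction[2]]
            )
            direction /= np.linalg.norm(direction)
            ca = lig.coord[lig.atom_name == "CA"]
            target = lig_centroid_ref + config.unbound_distance * direction
            lig.coord = rot.apply(lig.coord - ca.mean(axis=0)) + target
        else:
            noise_a = rng.normal(0.0, config.pose_noise_sigma, size=3)
            noise_b = rng.normal(0.0, config.pose_noise_sigma, size=3)
            if pose == "native":
                target_a = ref_aA_ca + noise_a
                target_b = ref_aB_ca + noise_b
            else:
                angle = rng.uniform(0.0, 2 * np.pi)
                offset = config.misoriented_offset * np.array(
                    [np.cos(angle), 0.0, np.sin(angle)]
                )
                target_a = ref_aA_ca + offset + noise_a
                target_b = ref_aB_ca_flipped + noise_b
            coords = lig.coord.copy()
            seg_a = _segment_atoms(lig, LIG_FIRST, reg.alphaA[1])
            seg_b = _segment_atoms(lig, reg.alphaB[0], LIG_LAST)
            coords[seg_a] = _fit_segment(
                _region_ca(lig, *reg.alphaA), target_a, lig.coord[seg_a]
            )
            coords[seg_b] = _fit_segment(
                _region_ca(lig, *reg.alphaB), target_b, lig.coord[seg_b]
            )
            # loop (marker) residues: reference geometry, anchored with jitter
            delta = rng.normal(0.0, config.marker_anchor_sigma, size=3)
            loop_idx = _segment_atoms(lig, reg.alphaA[1] + 1, reg.alphaB[0] - 1)
            coords[loop_idx] = ref.coord[loop_idx_ref] + delta
            lig.coord = coords
        conf = _merge([rec_only, lig], model_id=k)
        if pose == "native":
            for lig_res, rec_res in config.native_pairs:
                _plant_contact(conf, conf, lig_res, rec_res, config.contact_distance)
        elif pose == "misoriented":
            for lig_res, rec_res in config.nonnative_pairs:
                _plant_contact(conf, conf, lig_res, rec_res, config.contact_distance)
            # the loop is copied from the reference, where its side chain
            # is planted on a native site; break that contact here so the
            # misoriented pose forms exactly the non-native set
            loop_lo, loop_hi = reg.alphaA[1] + 1, reg.alphaB[0] - 1
            for lig_res, rec_res in config.native_pairs:
                if loop_lo <= lig_res <= loop_hi:
                    _plant_contact(conf, conf, lig_res, rec_res, config.broken_distance)
        conformations.append(conf)
        truth["pose"].append(pose)
        truth["helical_mask"].append({r: bool(v) for r, v in mask.items()})
        truth["contacts"].append(sorted(_enumerate_contacts(conf)))
        truth["marker_position"].append(
            conf.atom_coord(LIG_CHAIN, MARKER_RES, "CA").tolist()
        )
    return conformations, truth


def planted_truth(config: SyntheticConfig) -> dict:
    """Exact expected values implied by the generator's construction.

    Pose fractions echo the mixture weights; the bound fraction under the
    standard (13 A, 7 A) filter is computed by enumerating the
    deterministic pose geometry (native and misoriented poses anchor both
    region centroids within the thresholds, the unbound pose is displaced
    far beyond them); expected interior helix contents follow from the
    region-cooperative draws and the bound-state folding of alphaB.
    """
    reg = config.regions
    w_native, w_mis, w_unbound = config.pose_weights
    prop = config.residue_propensities()
    pose_R = {
        "native": (0.0, 0.0),
        "misoriented": (config.misoriented_offset, 0.0),
        "unbound": (config.unbound_distance, config.unbound_distance),
    }
    t_a, t_b = 13.0, 7.0
    bound = {
        p: (r[0] <= t_a and r[1] <= t_b) for p, r in pose_R.items()
    }
    expected_bound = sum(
        w * bound[p]
        for w, p in zip(config.pose_weights, ("native", "misoriented", "unbound"))
    )
    # "interior" residues are those whose helix flag responds only to
    # their own region's draw: >= 2 residues from a region end and >= 4
    # residues from the loop-segment break, where the rigidly anchored
    # loop can donate or accept chance hydrogen bonds
    interior = list(range(reg.alphaA[0] + 2, reg.alphaA[1] - 3)) + list(
        range(reg.alphaB[0] + 4, reg.alphaB[1] - 1)
    )
    expected_content = {}
    for r in interior:
        if config.region_of(r) == "alphaB":
            expected_content[r] = w_native + w_mis + w_unbound * prop[r]
        else:
            expected_content[r] = prop[r]
    return {
        "pose_fractions": {
            "native": w_native, "misoriented": w_mis, "unbound": w_unbound
        },
        "expected_bound_fraction": float(expected_bound),
        "expected_native_oriented_fraction": float(w_native),
        "pose_R": pose_R,
        "pmf_modes": [pose_R["native"], pose_R["misoriented"]],
        # a basin's occupied bin centre can sit one bin off the nominal
        # mode: |N(0, sigma^2 I_3)| peaks near sigma*sqrt(2), plus binning
        "pmf_mode_tolerance": 2.0 * config.pose_noise_sigma + 1.0,
        "interior_residues": interior,
        "expected_helix_content": expected_content,
        "n_native_pairs": len(config.native_pairs),
        "n_nonnative_pairs": len(config.nonnative_pairs),
    }
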