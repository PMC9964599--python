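"""3D shape and pharmacophore ("color") similarity.

Open re-implementation of the 3D stage of the cascade: seeded conformer
ensembles, rigid-body first-order Gaussian shape overlay in the style of
Grant & Pickup, same-type pharmacophore-feature overlap, and the combined
TanimotoCombo score in [0, 2].

Each heavy atom is modeled as an isotropic Gaussian of amplitude ``p = 2.7``
whose integral equals the atom's hard-sphere volume, i.e. width

    alpha_i = pi * (3 p / (4 pi R_i^3))**(2/3)

so that ``p (pi/alpha)^{3/2} = 4/3 pi R^3``. The shape overlap between two
molecules is the first-order pairwise sum of Gaussian-product integrals

    V_AB = sum_ij p^2 (pi/(a_i+a_j))^{3/2} exp(-a_i a_j / (a_i+a_j) d_ij^2)

and ShapeTanimoto = V_AB / (V_AA + V_BB - V_AB), maximized over rigid
transforms. Color features (donor, acceptor, cation, anion, hydrophobe,
aromatic ring centroid) are scored with the same kernel at radius 1 Å,
restricted to same-type pairs, at the shape-optimal pose. Hydrogens are
excluded throughout for robustness to protonation conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolAlign
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .curation import CompoundRecord
from .descriptors import vdw_radius
from .errors import EmbedError

GAUSSIAN_AMPLITUDE = 2.7
COLOR_RADIUS = 1.0  # Å
RMSD_PRUNE = 0.5  # Å, heavy-atom

#: Minimal pharmacophore dictionary (SMARTS → feature type). Hydrophobes are
#: placed per aliphatic carbon with no heteroatom neighbor; aromatic features
#: are ring centroids handled separately.
FEATURE_SMARTS = {
    "donor": "[#7,#8;!H0]",
    "acceptor": "[$([#8;+0]),$([#7;+0;!X4])]",
    "cation": "[+1,+2,+3]",
    "anion": "[-1,-2,-3]",
    "hydrophobe": "[C;!$(C~[#7,#8,#9,#15,#16,#17,#35,#53])]",
}


@dataclass(frozen=True)
class Transform:
    """Rigid transform x -> x @ R.T + t."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def compose(self, inner: "Transform") -> "Transform":
        """Return the transform equivalent to self∘inner (inner applied first)."""
        return Transform(
            rotation=self.rotation @ inner.rotation,
            translation=self.rotation @ inner.translation + self.translation,
        )

    @staticmethod
    def identity() -> "Transform":
        return Transform(np.eye(3), np.zeros(3))

    def inverse(self) -> "Transform":
        rt = self.rotation.T
        return Transform(rt, -rt @ self.translation)


@dataclass(frozen=True)
class Conformer:
    """Heavy-atom geometry plus typed pharmacophore features of one conformer."""

    coords: np.ndarray  # (n_heavy, 3) Å
    radii: np.ndarray  # (n_heavy,) Å
    elements: tuple[str, ...]
    feature_types: tuple[str, ...]
    feature_coords: np.ndarray  # (n_features, 3) Å


@dataclass(frozen=True)
class ConformerSet:
    """A seeded, RMSD-pruned conformer ensemble for one compound."""

    compound_id: str
    conformers: tuple[Conformer, ...]
    max_conformers: int
    seed: int
    mol: Chem.Mol = field(compare=False, repr=False, default=None)


@dataclass(frozen=True)
class OverlayScore:
    """Best shape+color overlay between two conformer ensembles."""

    drug_id: str
    active_id: str
    shape_tanimoto: float
    color_tanimoto: float
    tanimoto_combo: float
    best_transform: Transform
    best_conformer_pair: tuple[int, int]


def _alpha(radii: np.ndarray, p: float = GAUSSIAN_AMPLITUDE) -> np.ndarray:
    return np.pi * (3.0 * p / (4.0 * np.pi * radii**3)) ** (2.0 / 3.0)


def _heavy_atom_arrays(mol: Chem.Mol, conf_id: int) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    conf = mol.GetConformer(conf_id)
    pos = conf.GetPositions()
    idx = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    coords = pos[idx]
    radii = np.array([vdw_radius(mol.GetAtomWithIdx(i).GetAtomicNum()) for i in idx])
    elements = tuple(mol.GetAtomWithIdx(i).GetSymbol() for i in idx)
    return coords, radii, elements


def extract_features(mol: Chem.Mol, conf_id: int) -> tuple[tuple[str, ...], np.ndarray]:
    """Type and locate pharmacophore features on one conformer."""
    pos = mol.GetConformer(conf_id).GetPositions()
    types: list[str] = []
    coords: list[np.ndarray] = []
    for ftype, smarts in FEATURE_SMARTS.items():
        patt = Chem.MolFromSmarts(smarts)
        for match in mol.GetSubstructMatches(patt):
            types.append(ftype)
            coords.append(pos[match[0]])
    for ring in Chem.GetSymmSSSR(mol):
        atoms = list(ring)
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in atoms):
            types.append("ring")
            coords.append(pos[atoms].mean(axis=0))
    if not coords:
        return (), np.zeros((0, 3))
    return tuple(types), np.array(coords)


def generate_conformers(
    compound: CompoundRecord,
    n: int = 10,
    seed: int = 2023,
) -> ConformerSet:
    """Embed up to ``n`` conformers, greedily pruned to pairwise RMSD >= 0.5 Å.

    Embedding is seeded (deterministic for a fixed seed), MMFF-minimized,
    sorted by energy, and pruned by best-fit heavy-atom RMSD so that every
    retained pair differs by at least 0.5 Å.

    Raises
    ------
    EmbedError
        If no conformer can be embedded.
    """
    mol = Chem.AddHs(compound.structure)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    params.pruneRmsThresh = RMSD_PRUNE
    n_try = max(2 * n, n + 2)
    ids = AllChem.EmbedMultipleConfs(mol, numConfs=n_try, params=params)
    if len(ids) == 0:
        params.useRandomCoords = True
        ids = AllChem.EmbedMultipleConfs(mol, numConfs=n_try, params=params)
        if len(ids) == 0:
            raise EmbedError(f"embedding failed for {compound.compound_id}")
    energies: dict[int, float] = {}
    try:
        results = AllChem.MMFFOptimizeMoleculeConfs(mol, maxIters=200)
        for cid, (converged, energy) in zip(ids, results):
            energies[cid] = energy if np.isfinite(energy) else np.inf
    except Exception:
        energies = {cid: 0.0 for cid in ids}
    ordered = sorted(ids, key=lambda cid: (energies.get(cid, np.inf), cid))
    noh = Chem.RemoveHs(mol)
    kept: list[int] = []
    for cid in ordered:
        if len(kept) >= n:
            break
        ok = True
        for kid in kept:
            if rdMolAlign.GetBestRMS(noh, noh, prbId=cid, refId=kid) < RMSD_PRUNE:
                ok = False
                break
        if ok:
            kept.append(cid)
    confs = []
    for cid in kept:
        coords, radii, elements = _heavy_atom_arrays(mol, cid)
        ftypes, fcoords = extract_features(mol, cid)
        confs.append(
            Conformer(
                coords=coords,
                radii=radii,
                elements=elements,
                feature_types=ftypes,
                feature_coords=fcoords,
            )
        )
    keep_mol = Chem.Mol(mol)
    for cid in list(c.GetId() for c in keep_mol.GetConformers()):
        if cid not in kept:
            keep_mol.RemoveConformer(cid)
    return ConformerSet(
        compound_id=compound.compound_id,
        conformers=tuple(confs),
        max_conformers=n,
        seed=int(seed),
        mol=keep_mol,
    )


class _OverlapKernel:
    """Precomputed cross terms for the pairwise Gaussian overlap of two atom sets."""

    def __init__(self, radii_a: np.ndarray, radii_b: np.ndarray, p: float = GAUSSIAN_AMPLITUDE):
        aa = _alpha(radii_a, p)[:, None]
        ab = _alpha(radii_b, p)[None, :]
        s = aa + ab
        self.decay = aa * ab / s  # (na, nb)
        self.prefactor = p * p * (np.pi / s) ** 1.5

    def overlap(self, coords_a: np.ndarray, coords_b: np.ndarray) -> float:
        d2 = ((coords_a[:, None, :] - coords_b[None, :, :]) ** 2).sum(axis=2)
        return float((self.prefactor * np.exp(-self.decay * d2)).sum())


def gaussian_overlap_volume(
    conf_a: Conformer,
    conf_b: Conformer,
    transform: Transform | None = None,
) -> float:
    """First-order Gaussian shape-overlap volume V_AB in Å³.

    ``transform`` is applied to ``conf_b`` before scoring. Symmetric:
    V(A, T·B) equals V(B, T⁻¹·A).
    """
    if transform is None:
        transform = Transform.identity()
    kernel = _OverlapKernel(conf_a.radii, conf_b.radii)
    return kernel.overlap(conf_a.coords, transform.apply(conf_b.coords))


def self_overlap(conf: Conformer) -> float:
    """V_AA: the molecule's Gaussian overlap with itself (identity pose)."""
    return gaussian_overlap_volume(conf, conf, Transform.identity())


def _principal_frame(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and right-handed principal-axes rotation with fixed sign convention."""
    center = coords.mean(axis=0)
    x = coords - center
    cov = x.T @ x / max(len(x), 1)
    _, vecs = np.linalg.eigh(cov)
    axes = vecs[:, ::-1].T  # rows: major, mid, minor axis
    # sign each axis by the skewness of the projections — intrinsic to the
    # molecule, hence stable under any rigid transform of the input
    for i in range(2):
        skew = float(((x @ axes[i]) ** 3).sum())
        if skew < 0:
            axes[i] = -axes[i]
    axes[2] = np.cross(axes[0], axes[1])  # right-handed by construction
    return center, axes


_FLIPS = (
    np.diag([1.0, 1.0, 1.0]),
    np.diag([1.0, -1.0, -1.0]),
    np.diag([-1.0, 1.0, -1.0]),
    np.diag([-1.0, -1.0, 1.0]),
)


def optimize_overlay(
    conf_a: Conformer,
    conf_b: Conformer,
    maxiter: int = 200,
    tol: float = 1e-4,
) -> tuple[Transform, float]:
    """Maximize ShapeTanimoto over rigid transforms of ``conf_b``.

    Both molecules are internally canonicalized (centroid + principal axes)
    and the four 180° axis-flip starts are refined by Nelder–Mead over the
    6 rigid-body parameters — in both orderings, so the search (and hence
    the score) is symmetric in the two inputs. The returned transform maps
    ``conf_b``'s original coordinates into ``conf_a``'s original frame.
    """
    v_ab_f, t_f = _directed_overlay(conf_a, conf_b, maxiter, tol)
    v_ab_b, t_b = _directed_overlay(conf_b, conf_a, maxiter, tol)
    if v_ab_b > v_ab_f:
        v_ab, transform = v_ab_b, t_b.inverse()
        # re-evaluate in the forward frame for a frame-consistent value
        v_ab = gaussian_overlap_volume(conf_a, conf_b, transform)
    else:
        v_ab, transform = v_ab_f, t_f
    v_aa = self_overlap(conf_a)
    v_bb = self_overlap(conf_b)
    shape_t = v_ab / (v_aa + v_bb - v_ab)
    return transform, float(np.clip(shape_t, 0.0, 1.0))


def _directed_overlay(
    conf_a: Conformer,
    conf_b: Conformer,
    maxiter: int,
    tol: float,
) -> tuple[float, Transform]:
    """One-directional pose search: best V_AB and the b->a-frame transform."""
    ca, ra = _principal_frame(conf_a.coords)
    cb, rb = _principal_frame(conf_b.coords)
    a_canon = (conf_a.coords - ca) @ ra.T
    b_canon = (conf_b.coords - cb) @ rb.T
    kernel = _OverlapKernel(conf_a.radii, conf_b.radii)

    best_vab = -np.inf
    best_rot = np.eye(3)
    best_tr = np.zeros(3)
    for flip in _FLIPS:
        b0 = b_canon @ flip.T

        def neg_overlap(params, b0=b0):
            rot = Rotation.from_rotvec(params[:3]).as_matrix()
            return -kernel.overlap(a_canon, b0 @ rot.T + params[3:])

        res = minimize(
            neg_overlap,
            np.zeros(6),
            method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": tol, "fatol": tol, "adaptive": False},
        )
        if -res.fun > best_vab:
            best_vab = -res.fun
            rot = Rotation.from_rotvec(res.x[:3]).as_matrix()
            best_rot = rot @ flip
            best_tr = res.x[3:]
        if b_canon.shape[0] == 1:
            break  # single atom: pose space is translation only
    # Compose: x -> ra.T @ (best_rot @ (rb @ (x - cb)) + best_tr) + ca
    canon_b = Transform(rb, -rb @ cb)
    refine = Transform(best_rot, best_tr)
    uncanon_a = Transform(ra.T, ca)
    full = uncanon_a.compose(refine.compose(canon_b))
    return float(best_vab), full


def color_tanimoto(
    conf_a: Conformer,
    conf_b: Conformer,
    transform: Transform | None = None,
) -> float:
    """Pharmacophore overlap C_AB / (C_AA + C_BB - C_AB) at a fixed pose.

    Features are isotropic Gaussians of radius 1 Å and amplitude 2.7;
    only same-type feature pairs contribute. Returns 0 when either molecule
    has no features.
    """
    if transform is None:
        transform = Transform.identity()
    if len(conf_a.feature_types) == 0 or len(conf_b.feature_types) == 0:
        return 0.0
    fb = transform.apply(conf_b.feature_coords)

    def typed_overlap(types1, coords1, types2, coords2) -> float:
        total = 0.0
        for t in set(types1) & set(types2):
            i = [k for k, tt in enumerate(types1) if tt == t]
            j = [k for k, tt in enumerate(types2) if tt == t]
            kern = _OverlapKernel(
                np.full(len(i), COLOR_RADIUS), np.full(len(j), COLOR_RADIUS)
            )
            total += kern.overlap(coords1[i], coords2[j])
        return total

    c_ab = typed_overlap(conf_a.feature_types, conf_a.feature_coords, conf_b.feature_types, fb)
    c_aa = typed_overlap(
        conf_a.feature_types, conf_a.feature_coords, conf_a.feature_types, conf_a.feature_coords
    )
    c_bb = typed_overlap(
        conf_b.feature_types, conf_b.feature_coords, conf_b.feature_types, conf_b.feature_coords
    )
    denom = c_aa + c_bb - c_ab
    if denom <= 0:
        return 0.0
    return float(np.clip(c_ab / denom, 0.0, 1.0))


def tanimoto_combo(drug: ConformerSet, active: ConformerSet) -> OverlayScore:
    """Best shape+color score over all conformer pairs of two ensembles.

    For every (drug, active) conformer pair the shape overlay is optimized
    and the color score evaluated at the shape-optimal pose; the reported
    score is the maximum shape+color sum, with the achieving transform and
    conformer indices.
    """
    best = None
    for i, cd in enumerate(drug.conformers):
        for j, ca in enumerate(active.conformers):
            transform, shape_t = optimize_overlay(ca, cd)
            color_t = color_tanimoto(ca, cd, transform)
            combo = shape_t + color_t
            if best is None or combo > best[0]:
                best = (combo, shape_t, color_t, transform, (i, j))
    combo, shape_t, color_t, transform, pair = best
    return OverlayScore(
        drug_id=drug.compound_id,
        active_id=active.compound_id,
        shape_tanimoto=shape_t,
        color_tanimoto=color_t,
        tanimoto_combo=combo,
        best_transform=transform,
        best_conformer_pair=pair,
    )


def cascade_filter_3d(
    scores: Sequence[OverlayScore],
    t_combo: float = 1.5,
) -> list[OverlayScore]:
    """Retain overlays with TanimotoCombo >= ``t_combo`` (inclusive)."""
    return [s for s in scores if s.tanimoto_combo >= t_combo]
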