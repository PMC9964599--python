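"""Molecular descriptor panel used for dataset comparison.

LogP, topological polar surface area, H-bond donor/acceptor counts and
molecular weight come from RDKit's standard definitions. Molecular volume is
a grid estimate over van-der-Waals spheres (Bondi radii) and ovality is the
molecular (solvent-excluded probe-0) surface area divided by the surface
area of the sphere of equal volume — exactly 1 for a single spherical atom,
larger for elongated shapes. A reciprocal convention (values < 1) seen in
some toolkits is available via ``ovality_convention="reciprocal"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, rdMolDescriptors

from .curation import CompoundRecord
from .errors import EmbedError

#: Bondi (1964) van-der-Waals radii, Å.
BONDI_RADII = {
    1: 1.20, 2: 1.40, 6: 1.70, 7: 1.55, 8: 1.52, 9: 1.47, 10: 1.54,
    14: 2.10, 15: 1.80, 16: 1.80, 17: 1.75, 18: 1.88, 35: 1.85, 53: 1.98,
}
DEFAULT_RADIUS = 1.70


@dataclass(frozen=True)
class DescriptorSet:
    """The seven-descriptor panel. Units: psa Å², mw Da, volume Å³."""

    logp: float
    psa: float
    hbd: int
    hba: int
    mw: float
    volume: float
    ovality: float


def vdw_radius(atomic_num: int) -> float:
    return BONDI_RADII.get(atomic_num, DEFAULT_RADIUS)


def embed_3d(mol: Chem.Mol, seed: int = 2023) -> Chem.Mol:
    """Return a hydrogen-complete copy of ``mol`` with one 3D conformer."""
    m = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(m, params) != 0:
        # fallback: random coordinates for pathological inputs
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(m, params) != 0:
            raise EmbedError(f"conformer embedding failed for {Chem.MolToSmiles(mol)}")
    try:
        AllChem.MMFFOptimizeMolecule(m)
    except Exception:
        pass  # descriptor estimates tolerate unminimized geometry
    return m


def _conformer_arrays(mol: Chem.Mol) -> tuple[np.ndarray, np.ndarray]:
    conf = mol.GetConformer()
    coords = conf.GetPositions()
    radii = np.array([vdw_radius(a.GetAtomicNum()) for a in mol.GetAtoms()])
    return coords, radii

def grid_volume(coords: np.ndarray, radii: np.ndarray, spacing: float = 0.2) -> float:
    """Van-der-Waals volume (Å³): fraction of a regular grid inside any sphere."""
    center = coords.mean(axis=0)
    lo = (coords - radii[:, None]).min(axis=0) - spacing
    hi = (coords + radii[:, None]).max(axis=0) + spacing
    # anchor the lattice on the centroid: keeps quantization error well
    # below the 2% envelope regardless of absolute coordinates
    lo = center + np.floor((lo - center) / spacing) * spacing
    axes = [np.arange(lo[d], hi[d] + spacing, spacing) for d in range(3)]
    inside_total = 0
    # slab over x to bound memory on large grids
    gy, gz = np.meshgrid(axes[1], axes[2], indexing="ij")
    yz = np.stack([gy.ravel(), gz.ravel()], axis=1)
    r2 = radii**2
    for x in axes[0]:
        dx2 = (coords[:, 0] - x) ** 2  # (natoms,)
        dy2 = (yz[:, 0][:, None] - coords[:, 1]) ** 2
        dz2 = (yz[:, 1][:, None] - coords[:, 2]) ** 2
        inside = (dy2 + dz2 + dx2 <= r2).any(axis=1)
        inside_total += int(inside.sum())
    return inside_total * spacing**3


def _sphere_points(n: int = 256) -> np.ndarray:
    """Quasi-uniform unit-sphere points (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def surface_area(coords: np.ndarray, radii: np.ndarray, n_points: int = 512) -> float:
    """Exposed van-der-Waals surface area (Å²), Shrake–Rupley with probe 0."""
    pts = _sphere_points(n_points)
    total = 0.0
    for i in range(len(coords)):
        sphere = coords[i] + radii[i] * pts
        exposed = np.ones(n_points, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            d2 = ((sphere - coords[j]) ** 2).sum(axis=1)
            exposed &= d2 > radii[j] ** 2
        total += 4.0 * np.pi * radii[i] ** 2 * exposed.mean()
    return total


def compute_descriptors(
    compound: CompoundRecord,
    seed: int = 2023,
    ovality_convention: str = "ratio",
) -> DescriptorSet:
    """Compute the seven-descriptor panel for a standardized compound.

    A 3D conformer is embedded for the volume/ovality terms; 2D descriptors
    use the connection table only. ``ovality_convention`` selects the
    surface-area ratio (default, >= 1) or its reciprocal.
    """
    mol = compound.structure
    m3d = embed_3d(mol, seed=seed)
    coords, radii = _conformer_arrays(m3d)
    vol = grid_volume(coords, radii)
    area = surface_area(coords, radii)
    sphere_area = np.pi ** (1.0 / 3.0) * (6.0 * vol) ** (2.0 / 3.0)
    ovality = area / sphere_area
    if ovality_convention == "reciprocal":
        ovality = 1.0 / ovality
    elif ovality_convention != "ratio":
        raise ValueError(f"unknown ovality convention: {ovality_convention!r}")
    return DescriptorSet(
        logp=Crippen.MolLogP(mol),
        psa=rdMolDescriptors.CalcTPSA(mol),
        hbd=rdMolDescriptors.CalcNumHBD(mol),
        hba=rdMolDescriptors.CalcNumHBA(mol),
        mw=Descriptors.MolWt(mol),
        volume=vol,
        ovality=ovality,
    )
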