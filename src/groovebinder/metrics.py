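"""Geometric and probabilistic interface metrics.

Covers the quantities used as optimization losses (radius of gyration and
its normalized/gradient forms, distogram contact probability, inter-chain
predicted aligned error) and as structure-analysis filters (Lawrence–Colman
shape complementarity, contact molecular surface, Shrake–Rupley SASA).

Surfaces are dot surfaces: points sampled on van der Waals spheres at a
fixed density, pruned to the solvent-exposed part, with radial normals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class SizeError(ValueError):
    """Empty or too-small input."""


class BinningError(ValueError):
    """Distance bins incompatible with the requested contact threshold."""


class UndefinedInterfaceError(ValueError):
    """The two bodies share no buried interface."""


class DomainError(ValueError):
    """Argument outside its mathematical domain."""


# ---------------------------------------------------------------------------
# Radius of gyration family
# ---------------------------------------------------------------------------

def radius_of_gyration(coords: np.ndarray) -> float:
    """Root-mean-square distance of atoms from their unweighted centroid."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.size == 0:
        raise SizeError("radius of gyration of an empty coordinate set")
    rel = coords - coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(rel ** 2, axis=1))))


RESIDUE_VOLUME = 110.0  # Å³, typical residue volume for the length normalizer


def rg_loss_normalized(coords: np.ndarray, n_residues: int,
                       residue_volume: float = RESIDUE_VOLUME) -> float:
    """Radius of gyration divided by the radius of the equivalent sphere.

    The normalizer is the radius of a sphere whose volume is
    ``n_residues * residue_volume``, which makes the loss roughly
    length-independent: a compact globule scores ≈ sqrt(3/5) ≈ 0.775
    (the rg of a uniform ball of radius r is r·sqrt(3/5)).
    """
    if n_residues < 1:
        raise SizeError("n_residues must be >= 1")
    r_sphere = (3.0 * n_residues * residue_volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    return radius_of_gyration(coords) / r_sphere


def rg_guiding_potential(coords: np.ndarray) -> tuple[float, np.ndarray]:
    """Radius of gyration and its analytic per-atom gradient.

    d rg / d x_i = (x_i − centroid) / (N · rg); the gradient sums to the
    zero vector (translation invariance) and is defined as zero for a
    fully collapsed point set.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if len(coords) < 2:
        raise SizeError("gradient needs at least 2 atoms")
    rel = coords - coords.mean(axis=0)
    rg = float(np.sqrt(np.mean(np.sum(rel ** 2, axis=1))))
    if rg < 1e-12:
        return 0.0, np.zeros_like(coords)
    return rg, rel / (len(coords) * rg)


def cubic_decay_scale(t: float, T: float, w0: float) -> float:
    """Guiding-potential weight w0·(t/T)³ with t counting down from T.

    Full weight at the start of a denoising trajectory (t = T), zero at
    the end (t = 0): the quaternary arrangement is set early, so the
    potential matters most in the first steps.
    """
    if not 0 <= t <= T:
        raise DomainError(f"t={t} outside [0, {T}]")
    return w0 * (t / T) ** 3


# ---------------------------------------------------------------------------
# Oracle-tensor metrics
# ---------------------------------------------------------------------------

@dataclass
class Distogram:
    """Per-residue-pair probability over distance bins.

    ``probs`` has shape (L, L, K) with ``edges`` of length K+1 (Å,
    strictly ascending; probs[..., k] is the mass between edges[k] and
    edges[k+1]).  ``binder_span``/``target_span`` partition 0..L as
    (start, stop) half-open index ranges.
    """
    probs: np.ndarray
    edges: np.ndarray
    binder_span: tuple[int, int]
    target_span: tuple[int, int]

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.edges = np.asarray(self.edges, dtype=float)
        if self.probs.ndim != 3 or self.probs.shape[0] != self.probs.shape[1]:
            raise ValueError("probs must be (L, L, K)")
        if len(self.edges) != self.probs.shape[2] + 1:
            raise ValueError("need K+1 edges for K bins")
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin edges must be strictly ascending")
        sums = self.probs.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("per-pair probabilities must sum to 1 ± 1e-6")


@dataclass
class PaeMatrix:
    """Pairwise aligned-error estimates (Å) with a binder/target partition."""
    values: np.ndarray
    binder_span: tuple[int, int]
    target_span: tuple[int, int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("pae matrix must be square")
        if np.any(self.values < 0):
            raise ValueError("pae values must be non-negative")


def _sub_threshold_mass(probs: np.ndarray, edges: np.ndarray,
                        threshold: float) -> np.ndarray:
    """Probability mass below a distance threshold, with the straddling
    bin counted fractionally by linear interpolation."""
    if edges[0] >= threshold:
        raise BinningError(
            f"no bin boundary below {threshold} Å (first edge {edges[0]})")
    frac = np.clip((threshold - edges[:-1]) / np.diff(edges), 0.0, 1.0)
    return probs @ frac


def contact_probability_loss(d: Distogram, threshold: float = 8.0) -> float:
    """Mean over target residues of their best single-partner contact
    probability against the binder.

    For each (target, binder) residue pair the sub-8-Å distogram mass is
    summed (fractional for the straddling bin); per target residue the
    maximum over binder residues is taken, and the result is averaged
    across target residues.  Lies in [0, 1].
    """
    b0, b1 = d.binder_span
    t0, t1 = d.target_span
    if b1 <= b0 or t1 <= t0:
        raise SizeError("empty binder or target span")
    mass = _sub_threshold_mass(d.probs[t0:t1, b0:b1], d.edges, threshold)
    return float(np.mean(mass.max(axis=1)))


def interface_pae(p: PaeMatrix) -> float:
    """Mean predicted aligned error over both inter-chain blocks."""
    b0, b1 = p.binder_span
    t0, t1 = p.target_span
    if b1 <= b0 or t1 <= t0:
        raise SizeError("empty binder or target span")
    block_bt = p.values[b0:b1, t0:t1]
    block_tb = p.values[t0:t1, b0:b1]
    return float(np.concatenate([block_bt.ravel(), block_tb.ravel()]).mean())


# ---------------------------------------------------------------------------
# Dot surfaces, shape complementarity, contact molecular surface
# ---------------------------------------------------------------------------

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}
DEFAULT_VDW = 1.70
SC_WEIGHT = 0.5          # Å⁻², Gaussian distance weight in the Sc score
SC_PATCH_DIST = 1.5      # Å, surface-to-surface cutoff defining the patch
SURFACE_DENSITY = 5.0    # points per Å²


@dataclass
class DotSurface:
    """Sampled molecular surface: points, outward unit normals, and the
    area each point represents."""
    points: np.ndarray
    normals: np.ndarray
    areas: np.ndarray

    def __len__(self) -> int:
        return len(self.points)


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def dot_surface(coords: np.ndarray, radii: np.ndarray | float | None = None,
                density: float = SURFACE_DENSITY) -> DotSurface:
    """Solvent-exposed dot surface of a set of atomic spheres.

    Points are sampled on each atom's van der Waals sphere at ``density``
    points/Å² and pruned if buried inside any other atom of the same set.
    Normals are radial; each surviving point carries its share of the
    sphere area.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.size == 0:
        raise SizeError("empty atom set")
    n_atoms = len(coords)
    if radii is None:
        radii = np.full(n_atoms, DEFAULT_VDW)
    elif np.isscalar(radii):
        radii = np.full(n_atoms, float(radii))
    else:
        radii = np.asarray(radii, dtype=float)
    pts, nrm, areas = [], [], []
    for i in range(n_atoms):
        r = radii[i]
        n_pts = max(int(np.ceil(density * 4.0 * np.pi * r * r)), 12)
        unit = _fibonacci_sphere(n_pts)
        p = coords[i] + r * unit
        # prune points buried in any other sphere
        keep = np.ones(n_pts, dtype=bool)
        d2 = np.sum((p[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
        d2[:, i] = np.inf
        keep = np.all(d2 >= (radii[None, :] - 1e-9) ** 2, axis=1)
        if not keep.any():
            continue
        pts.append(p[keep])
        nrm.append(unit[keep])
        areas.append(np.full(keep.sum(), 4.0 * np.pi * r * r / n_pts))
    if not pts:
        raise SizeError("all surface points buried")
    return DotSurface(points=np.vstack(pts), normals=np.vstack(nrm),
                      areas=np.concatenate(areas))


def _nearest(points_a: np.ndarray, points_b: np.ndarray
             ) -> tuple[np.ndarray, np.ndarray]:
    """Index into b and distance of the nearest b-point for each a-point."""
    from scipy.spatial import cKDTree
    tree = cKDTree(points_b)
    dist, idx = tree.query(points_a)
    return idx, dist


def sc_from_surfaces(surf_a: DotSurface, surf_b: DotSurface,
                     weight: float = SC_WEIGHT,
                     patch_dist: float = SC_PATCH_DIST) -> float:
    """Lawrence–Colman shape complementarity of two pre-sampled surfaces.

    Interface patches are the surface points within ``patch_dist`` of the
    opposing surface.  Each patch point is scored against its nearest
    opposing patch point as exp(−w·d²)·(n̂_a·(−n̂_b)); the statistic is the
    mean of the two per-side medians, in [−1, 1].
    """
    idx_ab, d_ab = _nearest(surf_a.points, surf_b.points)
    idx_ba, d_ba = _nearest(surf_b.points, surf_a.points)
    patch_a = d_ab <= patch_dist
    patch_b = d_ba <= patch_dist
    if not patch_a.any() or not patch_b.any():
        raise UndefinedInterfaceError(
            f"no surface points within {patch_dist} Å of the partner")

    def _side(points, normals, patch, opp_points, opp_normals, opp_patch):
        opp_pts = opp_points[opp_patch]
        opp_nrm = opp_normals[opp_patch]
        idx, d = _nearest(points[patch], opp_pts)
        s = np.exp(-weight * d ** 2) * np.sum(
            normals[patch] * (-opp_nrm[idx]), axis=1)
        return float(np.median(s))

    s_a = _side(surf_a.points, surf_a.normals, patch_a,
                surf_b.points, surf_b.normals, patch_b)
    s_b = _side(surf_b.points, surf_b.normals, patch_b,
                surf_a.points, surf_a.normals, patch_a)
    return 0.5 * (s_a + s_b)


def shape_complementarity(coords_a: np.ndarray, coords_b: np.ndarray,
                          radii_a: np.ndarray | None = None,
                          radii_b: np.ndarray | None = None,
                          density: float = SURFACE_DENSITY) -> float:
    """Sc statistic between two atom sets (see :func:`sc_from_surfaces`)."""
    return sc_from_surfaces(dot_surface(coords_a, radii_a, density),
                            dot_surface(coords_b, radii_b, density))


CMS_CUTOFF = 5.0     # Å, beyond this a surface point contributes nothing
CMS_SIGMA2 = 4.0     # Å², Gaussian falloff of the distance weight


def cms_from_surfaces(surf_a: DotSurface, surf_b: DotSurface,
                      cutoff: float = CMS_CUTOFF,
                      sigma2: float = CMS_SIGMA2) -> float:
    """Distance-weighted area (Å²) of surface A in contact with surface B.

    Each A-surface point contributes its represented area weighted by
    exp(−d²/sigma2) where d is the distance to the nearest B-surface
    point, truncated at ``cutoff``.  One-sided: pass the binder surface
    first.
    """
    _, d = _nearest(surf_a.points, surf_b.points)
    w = np.where(d <= cutoff, np.exp(-d ** 2 / sigma2), 0.0)
    return float(np.sum(surf_a.areas * w))


def contact_molecular_surface(coords_a: np.ndarray, coords_b: np.ndarray,
                              radii_a: np.ndarray | None = None,
                              radii_b: np.ndarray | None = None,
                              density: float = SURFACE_DENSITY) -> float:
    """Contact molecular surface of atom set A against atom set B (Å²)."""
    return cms_from_surfaces(dot_surface(coords_a, radii_a, density),
                             dot_surface(coords_b, radii_b, density))


def sasa(coords: np.ndarray, radii: np.ndarray | float | None = None,
         probe_radius: float = 1.4, n_points: int = 960) -> np.ndarray:
    """Shrake–Rupley solvent-accessible surface area per atom (Å²).

    Thin array-level wrapper around biotite's Shrake–Rupley with explicit
    per-atom van der Waals radii (default 1.7 Å carbon-like spheres).
    """
    import biotite.structure as struc
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.size == 0:
        raise SizeError("empty atom set")
    n_atoms = len(coords)
    if radii is None:
        radii = np.full(n_atoms, DEFAULT_VDW)
    elif np.isscalar(radii):
        radii = np.full(n_atoms, float(radii))
    else:
        radii = np.asarray(radii, dtype=float)
    arr = struc.AtomArray(n_atoms)
    arr.coord = coords
    arr.chain_id = np.full(n_atoms, "A")
    arr.res_id = np.arange(1, n_atoms + 1)
    arr.res_name = np.full(n_atoms, "ALA")
    arr.atom_name = np.full(n_atoms, "CA")
    arr.element = np.full(n_atoms, "C")
    return np.asarray(struc.sasa(arr, probe_radius=probe_radius,
                                 vdw_radii=radii, point_number=n_points),
                      dtype=float)
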