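"""Crick coiled-coil parameterization and backbone geometry.

Generates ideal and supercoiled poly-alanine α-helix backbones from the
classic Crick generating equations: a minor helix of radius ``R1`` winding
at ``omega1`` degrees per residue around a superhelical circle of radius
``R0`` traversed at ``omega0`` degrees per residue.  The axial rise per
residue *along the minor-helix axis* is fixed (canonically 1.51 Å), which
ties the superhelical pitch angle alpha to ``R0`` and ``omega0`` through

    sin(alpha) = R0 * omega0_rad / rise

so that the net rise along the global axis is ``rise * cos(alpha)`` per
residue.  Only Cα positions come from the generating equations; N, C and O
are completed by superimposing a three-residue ideal-helix template onto
each local Cα triplet.

Angles are degrees in every public interface and converted to radians
exactly once, on entry.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np

# Canonical coiled-coil constants (config defaults, overridable per call /
# per CrickParams instance).
RISE_PER_RESIDUE = 1.51          # Å along the minor-helix axis
MINOR_RADIUS = 2.26              # Å, Cα radius of an α-helix
OMEGA1_SUPERCOILED = 102.85      # deg/res (heptad repeat, 720/7)
OMEGA1_STRAIGHT = 100.0          # deg/res (3.6 res/turn)

# Ideal backbone internal coordinates (Engh–Huber-like values).
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7
_ANGLE_CA_C_O = 120.8
_PHI_IDEAL = -57.8
_PSI_IDEAL = -47.0


class ParameterDomainError(ValueError):
    """A Crick parameter violates its mathematical domain."""


class GeometryError(ValueError):
    """Degenerate geometry (collinear trace, undefined axis, ...)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrickParams:
    """Parametric description of one helix in a bundle.

    Attributes
    ----------
    R0, omega0, phi0:
        Superhelical radius (Å), frequency (deg/res, signed: negative is
        the left-handed supercoil of canonical coiled coils) and phase
        (deg; azimuth of the helix around the bundle axis).
    R1, omega1, phi1:
        Minor-helix radius (Å), frequency (deg/res) and phase (deg).
    z_offset:
        Axial displacement (Å) added to all coordinates.
    length:
        Number of residues.
    sense:
        +1 runs N→C along +z, −1 is flipped end-over-end about its own
        radial axis (a proper rotation: chirality is preserved, azimuth
        phi0 is kept).
    rise:
        Rise per residue along the minor-helix axis (Å).
    """

    R0: float
    omega0: float
    phi0: float
    R1: float = MINOR_RADIUS
    omega1: float = OMEGA1_SUPERCOILED
    phi1: float = 0.0
    z_offset: float = 0.0
    length: int = 17
    sense: int = 1
    rise: float = RISE_PER_RESIDUE

    def __post_init__(self) -> None:
        if self.R0 < 0:
            raise ParameterDomainError(f"R0 must be >= 0, got {self.R0}")
        if self.R1 <= 0:
            raise ParameterDomainError(f"R1 must be > 0, got {self.R1}")
        if self.length < 1:
            raise ParameterDomainError(f"length must be >= 1, got {self.length}")
        if self.sense not in (+1, -1):
            raise ParameterDomainError(f"sense must be +1 or -1, got {self.sense}")
        if self.rise <= 0:
            raise ParameterDomainError(f"rise must be > 0, got {self.rise}")
        if abs(self.R0 * np.deg2rad(self.omega0)) >= self.rise:
            raise ParameterDomainError(
                "no real pitch angle: |R0 * omega0| = "
                f"{abs(self.R0 * np.deg2rad(self.omega0)):.3f} Å/res must be "
                f"< rise ({self.rise} Å/res)"
            )

    def with_(self, **kwargs) -> "CrickParams":
        return replace(self, **kwargs)


@dataclass
class BackboneChain:
    """Heavy-backbone (N, Cα, C, O) coordinate container for one chain.

    Coordinates are (L, 3) float arrays in Å; residues are numbered
    1..L contiguously.  ``sequence`` defaults to poly-alanine.
    """

    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    o: np.ndarray
    chain_id: str = "A"
    sequence: str | None = None

    def __post_init__(self) -> None:
        for name in ("n", "ca", "c", "o"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"{name} coordinates must be (L, 3)")
            setattr(self, name, arr)
        L = len(self.ca)
        if not (len(self.n) == len(self.c) == len(self.o) == L):
            raise ValueError("backbone atom arrays must share one length")
        if self.sequence is None:
            self.sequence = "A" * L
        elif len(self.sequence) != L:
            raise ValueError("sequence length must match coordinates")

    def __len__(self) -> int:
        return len(self.ca)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "BackboneChain":
        """Return a rigidly moved copy (rotation applied first)."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        return BackboneChain(
            n=self.n @ R.T + t, ca=self.ca @ R.T + t,
            c=self.c @ R.T + t, o=self.o @ R.T + t,
            chain_id=self.chain_id, sequence=self.sequence,
        )

    def reversed(self) -> "BackboneChain":
        """Chain running through the same Cα positions in opposite spatial
        order, with N/C/O rebuilt so the result is a valid N→C chain."""
        return backbone_from_ca(self.ca[::-1].copy(), chain_id=self.chain_id,
                                sequence=(self.sequence or "")[::-1] or None)

    def validate(self) -> None:
        """Assert chemical-sanity invariants; raises GeometryError."""
        if len(self) >= 2:
            dca = np.linalg.norm(np.diff(self.ca, axis=0), axis=1)
            if not np.all((dca >= 3.6) & (dca <= 4.0)):
                bad = int(np.argmax(~((dca >= 3.6) & (dca <= 4.0))))
                raise GeometryError(
                    f"CA–CA step {dca[bad]:.3f} Å at residue {bad + 1} "
                    "outside [3.6, 4.0]")
            dcn = np.linalg.norm(self.n[1:] - self.c[:-1], axis=1)
            if not np.all((dcn >= 1.2) & (dcn <= 1.5)):
                bad = int(np.argmax(~((dcn >= 1.2) & (dcn <= 1.5))))
                raise GeometryError(
                    f"C–N bond {dcn[bad]:.3f} Å at residue {bad + 1} "
                    "outside [1.2, 1.5]")


# ---------------------------------------------------------------------------
# Ideal-helix template (NeRF construction from internal coordinates)
# ---------------------------------------------------------------------------

def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of atom D after a-b-c."""
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(ang),
                  bond * np.sin(ang) * np.cos(tor),
                  bond * np.sin(ang) * np.sin(tor)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _ideal_helix_template(n_res: int = 3,
                          phi: float = _PHI_IDEAL,
                          psi: float = _PSI_IDEAL) -> dict[str, np.ndarray]:
    """Backbone of an ideal α-helix built from internal coordinates."""
    N = [np.zeros(3)]
    CA = [np.array([_BOND_N_CA, 0.0, 0.0])]
    ang = np.deg2rad(_ANGLE_N_CA_C)
    C = [CA[0] + np.array([-_BOND_CA_C * np.cos(ang), _BOND_CA_C * np.sin(ang), 0.0])]
    O = []
    for i in range(n_res - 1):
        N.append(_place_atom(N[i], CA[i], C[i], _BOND_C_N, _ANGLE_CA_C_N, psi))
        CA.append(_place_atom(CA[i], C[i], N[i + 1], _BOND_N_CA, _ANGLE_C_N_CA, 180.0))
        C.append(_place_atom(C[i], N[i + 1], CA[i + 1], _BOND_CA_C, _ANGLE_N_CA_C, phi))
        O.append(_place_atom(N[i], CA[i], C[i], _BOND_C_O, _ANGLE_CA_C_O, psi + 180.0))
    # last O: reuse the preceding psi (no i+1 residue to define the plane)
    O.append(_place_atom(N[-1], CA[-1], C[-1], _BOND_C_O, _ANGLE_CA_C_O, psi + 180.0))
    return {"N": np.array(N), "CA": np.array(CA), "C": np.array(C), "O": np.array(O)}


_TEMPLATE = _ideal_helix_template(3)


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation R and translation t minimizing |R@mobile + t − target|."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    H = (mobile - mc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, tc - R @ mc


def backbone_from_ca(ca: np.ndarray, chain_id: str = "A",
                     sequence: str | None = None) -> BackboneChain:
    """Complete N, C, O around a Cα trace by local ideal-template fitting.

    For each residue the three-residue ideal-helix template is superimposed
    (Kabsch) onto the Cα triplet centred there and the central residue's
    N, C, O are copied; terminal residues borrow the first/last triplet.
    The Cα positions themselves are kept exactly.
    """
    ca = np.asarray(ca, dtype=float)
    L = len(ca)
    if L < 3:
        # Degenerate short chains: place template directly on available CAs.
        tmpl_ca = _TEMPLATE["CA"][:max(L, 1)]
        if L == 1:
            t = ca[0] - _TEMPLATE["CA"][0]
            R = np.eye(3)
        else:
            R, t = _kabsch(tmpl_ca, ca)
        out = {k: _TEMPLATE[k][:L] @ R.T + t for k in ("N", "C", "O")}
        return BackboneChain(n=out["N"], ca=ca, c=out["C"], o=out["O"],
                             chain_id=chain_id, sequence=sequence)
    n = np.empty_like(ca)
    c = np.empty_like(ca)
    o = np.empty_like(ca)
    tmpl_ca = _TEMPLATE["CA"]
    for i in range(L):
        j = min(max(i, 1), L - 2)          # centre of the fitting triplet
        k = i - j + 1                      # template residue to copy (0..2)
        R, t = _kabsch(tmpl_ca, ca[j - 1:j + 2])
        n[i] = R @ _TEMPLATE["N"][k] + t
        c[i] = R @ _TEMPLATE["C"][k] + t
        o[i] = R @ _TEMPLATE["O"][k] + t
    return BackboneChain(n=n, ca=ca, c=c, o=o, chain_id=chain_id, sequence=sequence)


# ---------------------------------------------------------------------------
# Generating equations
# ---------------------------------------------------------------------------

def crick_ca_trace(params: CrickParams) -> np.ndarray:
    """Cα coordinates (L, 3) from the Crick generating equations."""
    p = params
    t = np.arange(p.length, dtype=float)
    w0 = np.deg2rad(p.omega0)
    w1 = np.deg2rad(p.omega1)
    f0 = np.deg2rad(p.phi0)
    f1 = np.deg2rad(p.phi1)
    alpha = np.arcsin(p.R0 * w0 / p.rise) if p.R0 * w0 != 0 else 0.0
    a0 = w0 * t + f0
    a1 = w1 * t + f1
    x = (p.R0 * np.cos(a0)
         + p.R1 * np.cos(a0) * np.cos(a1)
         - p.R1 * np.cos(alpha) * np.sin(a0) * np.sin(a1))
    y = (p.R0 * np.sin(a0)
         + p.R1 * np.sin(a0) * np.cos(a1)
         + p.R1 * np.cos(alpha) * np.cos(a0) * np.sin(a1))
    z = p.rise * np.cos(alpha) * t - p.R1 * np.sin(alpha) * np.sin(a1)
    xyz = np.stack([x, y, z], axis=1)
    if p.sense == -1:
        centre = xyz.mean(axis=0)
        u = np.array([centre[0], centre[1], 0.0])
        if np.linalg.norm(u) > 1e-6:
            u /= np.linalg.norm(u)       # radial axis through the centroid
        else:
            u = np.array([np.cos(f0), np.sin(f0), 0.0])
        R = 2.0 * np.outer(u, u) - np.eye(3)   # 180° rotation about that axis
        xyz = (xyz - centre) @ R.T + centre
    xyz[:, 2] += p.z_offset
    return xyz


def generate_helix(params: CrickParams, chain_id: str = "A",
                   sequence: str | None = None) -> BackboneChain:
    """Build a full heavy-backbone helix from Crick parameters.

    Cα positions follow :func:`crick_ca_trace`; N, C, O are completed by
    ideal-template fitting.  Raises :class:`ParameterDomainError` for
    invalid parameters (checked at ``CrickParams`` construction).
    """
    ca = crick_ca_trace(params)
    return backbone_from_ca(ca, chain_id=chain_id, sequence=sequence)


def ideal_straight_helix(length: int, chain_id: str = "A",
                         sequence: str | None = None,
                         rise: float = 1.5, omega1: float = OMEGA1_STRAIGHT,
                         phi1: float = 0.0, z_offset: float = 0.0) -> BackboneChain:
    """Ideal straight α-helix on the +z axis (no supercoil)."""
    params = CrickParams(R0=0.0, omega0=0.0, phi0=0.0, R1=MINOR_RADIUS,
                         omega1=omega1, phi1=phi1, z_offset=z_offset,
                         length=length, rise=rise)
    return generate_helix(params, chain_id=chain_id, sequence=sequence)


# ---------------------------------------------------------------------------
# Axis fitting and inter-helix distance
# ---------------------------------------------------------------------------

def helix_axis(chain: BackboneChain | np.ndarray) -> np.ndarray:
    """Local helical-axis polyline estimated from sliding Cα windows.

    Each window of four consecutive Cα atoms yields one axis point: the
    local axis direction comes from successive second-difference (inward
    normal) vectors, and the axis point is the least-squares circle centre
    of the window projected perpendicular to that direction.  Returns an
    (L−3, 3) array.

    Raises
    ------
    GeometryError
        For fewer than 4 residues or a degenerate (near-collinear) trace.
    """
    ca = chain.ca if isinstance(chain, BackboneChain) else np.asarray(chain, float)
    L = len(ca)
    if L < 4:
        raise GeometryError("axis fitting needs at least 4 residues")
    pts = []
    for j in range(L - 3):
        w = ca[j:j + 4]
        n1 = w[0] - 2.0 * w[1] + w[2]
        n2 = w[1] - 2.0 * w[2] + w[3]
        a = np.cross(n1, n2)
        na = np.linalg.norm(a)
        if na < 1e-8:
            raise GeometryError(f"degenerate axis (collinear trace) at window {j}")
        a /= na
        if np.dot(a, w[3] - w[0]) < 0:
            a = -a
        # orthonormal in-plane basis
        u = n1 - np.dot(n1, a) * a
        u /= np.linalg.norm(u)
        v = np.cross(a, u)
        m = w.mean(axis=0)
        rel = w - m
        q = np.stack([rel @ u, rel @ v], axis=1)
        # Kåsa circle fit: minimize sum((|q-c|^2 - r^2)^2), linear in (cx, cy)
        A = np.column_stack([2.0 * q, np.ones(len(q))])
        b = (q ** 2).sum(axis=1)
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        pts.append(m + sol[0] * u + sol[1] * v)
    return np.array(pts)


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray
                            ) -> tuple[float, float]:
    """Distance from p to segment ab and the clamped parameter in [0, 1]."""
    ab = b - a
    denom = float(ab @ ab)
    s = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    return float(np.linalg.norm(p - (a + s * ab))), s


def _directed_axis_distances(pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    """For each point of polyline A, closest distance to polyline B, keeping
    only points whose nearest approach projects to B's interior (the
    overlapping span).  Falls back to all points if no interior projection."""
    if len(pb) == 1:
        return np.linalg.norm(pa - pb[0], axis=1)
    dists, interior = [], []
    nseg = len(pb) - 1
    for p in pa:
        best, best_interior = np.inf, False
        for k in range(nseg):
            d, s = _point_segment_distance(p, pb[k], pb[k + 1])
            if d < best:
                best = d
                best_interior = not ((k == 0 and s <= 0.0) or
                                     (k == nseg - 1 and s >= 1.0))
        dists.append(best)
        interior.append(best_interior)
    dists = np.asarray(dists)
    interior = np.asarray(interior)
    return dists[interior] if interior.any() else dists


def neighbor_distance(a: BackboneChain, b: BackboneChain) -> float:
    """Mean closest-approach distance between two fitted helix axes.

    Symmetric in its arguments; measured over the overlapping span of the
    two axis polylines.  Used for helix–helix spacing in bundle sampling.
    """
    pa = helix_axis(a)
    pb = helix_axis(b)
    d_ab = _directed_axis_distances(pa, pb)
    d_ba = _directed_axis_distances(pb, pa)
    return 0.5 * (float(d_ab.mean()) + float(d_ba.mean()))
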