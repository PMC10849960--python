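"""Random sampling of five-helix groove arrangements.

A candidate scaffold is a three-helix "groove" cradling an imaginary
central target helix (the slot), flanked by two buttressing helices moved
radially outwards.  The groove helices share one sampled supercoil value
and sit at azimuths 90°/180°/270° around the slot axis, leaving the 0°
face open for the target; buttresses sit in the 135°/225° gaps.  Helix
spacings are drawn per-helix from a tight Gaussian around a per-candidate
average, itself drawn from a wider Gaussian informed by native helical
bundle packing.  Supercoil magnitude is drawn from a biased (truncated
exponential) law favouring strongly supercoiled bundles.

Candidates that clash, occlude the slot, or leave the supercoil pitch
domain are *rejected* (a value, not an error) and resampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .crick import (
    BackboneChain, CrickParams, GeometryError, ParameterDomainError,
    OMEGA1_SUPERCOILED, generate_helix, ideal_straight_helix,
)

#: azimuth (deg) and chain id of each scaffold helix, in azimuthal order
_HELIX_AZIMUTH = {"g1": 90.0, "b1": 135.0, "g2": 180.0, "b2": 225.0, "g3": 270.0}
_CHAIN_IDS = {"g1": "A", "b1": "B", "g2": "C", "b2": "D", "g3": "E"}
_SENSE = {"g1": +1, "b1": -1, "g2": +1, "b2": -1, "g3": +1}
#: groove neighbours of each buttress (for spacing geometry)
_BUTTRESS_NEIGHBORS = {"b1": ("g1", "g2"), "b2": ("g2", "g3")}

SLOT_RADIUS = 2.3  # Å, clearance cylinder around the slot axis


class ConfigurationError(ValueError):
    """Sampling configuration cannot produce candidates."""


class DockingError(ValueError):
    """Target cannot be placed in the scaffold slot."""


@dataclass(frozen=True)
class SamplingConfig:
    """Distributions and cutoffs for groove-scaffold sampling.

    Lengths are residues, distances Å, angles degrees.  ``supercoil_rate``
    is the rate of the truncated-exponential bias on |omega0| over
    ``supercoil_range``: density ∝ exp(rate·|omega0|), so positive rates
    favour more supercoiled bundles.
    """

    helix_length_range: tuple[int, int] = (15, 19)
    # |omega0| in deg/res; capped so the superhelical pitch angle stays in
    # the native coiled-coil regime (alpha <= ~35°) at the sampled radii,
    # keeping CA-CA steps protein-like across the whole library
    supercoil_range: tuple[float, float] = (0.0, 4.0)
    supercoil_rate: float = 0.5                          # per deg/res
    avg_neighbor_dist: tuple[float, float] = (9.5, 0.7)  # mean, sd (Å)
    per_helix_dist_sd: float = 0.25                      # the tight Gaussian
    phase_range: tuple[float, float] = (0.0, 360.0)      # phi1 per helix
    z_offset_range: tuple[float, float] = (-3.0, 3.0)
    buttress_radial_extra: float = 0.0
    buttress_tilt_range: tuple[float, float] = (-15.0, 15.0)
    clash_cutoff: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.helix_length_range
        if lo > hi or lo < 4:
            raise ConfigurationError("helix_length_range must be non-empty, >= 4")
        if self.per_helix_dist_sd < 0 or self.avg_neighbor_dist[1] < 0:
            raise ConfigurationError("standard deviations must be >= 0")
        if self.clash_cutoff <= 0:
            raise ConfigurationError("clash_cutoff must be > 0")
        if self.supercoil_range[0] < 0 or self.supercoil_range[1] < self.supercoil_range[0]:
            raise ConfigurationError("supercoil_range must be ascending, >= 0")


@dataclass
class Rejection:
    """Reason a sampled arrangement was discarded (not an error).

    Carries the draw record of the discarded attempt so library-level
    statistics can be audited against the sampler's raw draws.
    """
    reason: str
    detail: str = ""
    provenance: dict = field(default_factory=dict)


@dataclass
class ScaffoldCandidate:
    """Accepted five-helix arrangement with full sampling provenance."""
    params: dict[str, CrickParams]          # g1, g2, g3, b1, b2
    chains: dict[str, BackboneChain]
    slot_params: CrickParams                # imaginary central helix
    provenance: dict = field(default_factory=dict)

    @property
    def helices(self) -> list[BackboneChain]:
        canonical = [k for k in ("g1", "b1", "g2", "b2", "g3") if k in self.chains]
        keys = canonical if len(canonical) == len(self.chains) else list(self.chains)
        return [self.chains[k] for k in keys]

    def all_ca(self) -> np.ndarray:
        return np.concatenate([h.ca for h in self.helices])


def _sample_supercoil(cfg: SamplingConfig, rng: np.random.Generator) -> float:
    """|omega0| from the truncated exponential favouring larger values."""
    lo, hi = cfg.supercoil_range
    lam = cfg.supercoil_rate
    u = rng.random()
    if abs(lam) < 1e-12:
        return lo + u * (hi - lo)
    span = hi - lo
    return lo + math.log1p(u * math.expm1(lam * span)) / lam


def _tilt_matrix(azimuth_deg: float, tilt_deg: float) -> np.ndarray:
    """Rotation by tilt about the azimuthal tangent direction."""
    phi = np.deg2rad(azimuth_deg)
    u = np.array([-np.sin(phi), np.cos(phi), 0.0])
    th = np.deg2rad(tilt_deg)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


def sample_candidate(config: SamplingConfig, rng: np.random.Generator
                     ) -> ScaffoldCandidate | Rejection:
    """Draw one five-helix arrangement; returns a candidate or a Rejection.

    The draw order is fixed (lengths, supercoil, average distance,
    per-helix distances, phases, z-offsets, tilts) so that provenance
    records are replayable and runs are bitwise deterministic per seed.
    """
    lo, hi = config.helix_length_range
    lengths = {k: int(rng.integers(lo, hi + 1)) for k in _HELIX_AZIMUTH}
    omega0_mag = _sample_supercoil(config, rng)
    omega0 = -omega0_mag  # canonical left-handed supercoil
    avg_d = rng.normal(*config.avg_neighbor_dist)
    dists = {k: rng.normal(avg_d, config.per_helix_dist_sd)
             for k in _HELIX_AZIMUTH}
    phases = {k: rng.uniform(*config.phase_range) for k in _HELIX_AZIMUTH}
    zoffs = {k: rng.uniform(*config.z_offset_range) for k in _HELIX_AZIMUTH}
    tilts = {k: rng.uniform(*config.buttress_tilt_range)
             for k in ("b1", "b2")}
    prov = {
        "lengths": lengths, "omega0": omega0, "avg_neighbor_dist": avg_d,
        "neighbor_dists": dists, "phi1": phases, "z_offsets": zoffs,
        "buttress_tilts": tilts,
    }

    if avg_d <= SLOT_RADIUS + config.clash_cutoff:
        return Rejection("slot_occlusion",
                         f"avg neighbour distance {avg_d:.2f} Å too small",
                         provenance=prov)

    params: dict[str, CrickParams] = {}
    chains: dict[str, BackboneChain] = {}
    radii: dict[str, float] = {}
    # --- groove helices: radius = sampled distance to the central slot.
    #     phi0 is shifted by -omega0*(L-1)/2 so the supercoil twist is
    #     centred: at mid-height each helix sits at its nominal azimuth ---
    for k in ("g1", "g2", "g3"):
        r = dists[k]
        radii[k] = r
        try:
            params[k] = CrickParams(
                R0=r, omega0=omega0,
                phi0=_HELIX_AZIMUTH[k] - omega0 * (lengths[k] - 1) / 2.0,
                omega1=OMEGA1_SUPERCOILED, phi1=phases[k],
                z_offset=zoffs[k], length=lengths[k], sense=_SENSE[k])
        except ParameterDomainError as e:
            return Rejection("pitch_domain", str(e), provenance=prov)
        chains[k] = generate_helix(params[k], chain_id=_CHAIN_IDS[k])
    # --- buttresses: same parameterization, moved radially outwards so the
    #     sampled distance is realized against the adjacent groove pair,
    #     preserving the tangential supercoil rate R0*omega0 (same pitch
    #     angle), then tilted about the azimuthal tangent ---
    for k in ("b1", "b2"):
        nb = _BUTTRESS_NEIGHBORS[k]
        r_g = 0.5 * (radii[nb[0]] + radii[nb[1]])
        d_b = dists[k]
        gap = np.deg2rad(45.0)
        disc = d_b ** 2 - (r_g * np.sin(gap)) ** 2
        if disc <= 0:
            return Rejection("buttress_geometry",
                             f"spacing {d_b:.2f} Å unreachable at radius {r_g:.2f} Å",
                             provenance=prov)
        r_b = r_g * np.cos(gap) + math.sqrt(disc) + config.buttress_radial_extra
        if r_b <= max(radii[nb[0]], radii[nb[1]]):
            return Rejection("buttress_geometry", "buttress not outside groove",
                             provenance=prov)
        radii[k] = r_b
        # pitch-match the buttress: all helices of the bundle share the
        # superhelical pitch (azimuth advance per Å of axial rise), which
        # fixes omega0 at the larger radius and never leaves the domain
        w0g = np.deg2rad(omega0)
        if abs(w0g) > 1e-12:
            alpha_g = math.asin(r_g * w0g / 1.51)
            rho = w0g / (1.51 * math.cos(alpha_g))       # rad/Å of rise
            alpha_b = math.atan(r_b * rho)
            omega0_b = float(np.rad2deg(rho * 1.51 * math.cos(alpha_b)))
        else:
            omega0_b = 0.0
        try:
            params[k] = CrickParams(
                R0=r_b, omega0=omega0_b,
                phi0=_HELIX_AZIMUTH[k] - omega0_b * (lengths[k] - 1) / 2.0,
                omega1=OMEGA1_SUPERCOILED, phi1=phases[k],
                z_offset=zoffs[k], length=lengths[k], sense=_SENSE[k])
        except ParameterDomainError as e:
            return Rejection("pitch_domain", str(e), provenance=prov)
        chain = generate_helix(params[k], chain_id=_CHAIN_IDS[k])
        centre = chain.ca.mean(axis=0)
        R = _tilt_matrix(_HELIX_AZIMUTH[k], tilts[k])
        chains[k] = chain.transformed(rotation=R, translation=centre - R @ centre)

    # --- acceptance checks: the clash gate applies between non-adjacent
    #     helices only; azimuthally adjacent pairs have their spacing set
    #     by construction (the sampled neighbour distances) ---
    names = list(_HELIX_AZIMUTH)
    adjacent = {("g1", "b1"), ("b1", "g2"), ("g2", "b2"), ("b2", "g3")}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if (a, b) in adjacent or (b, a) in adjacent:
                continue
            d2 = np.min(np.sum(
                (chains[a].ca[:, None, :] - chains[b].ca[None, :, :]) ** 2, axis=-1))
            if d2 < config.clash_cutoff ** 2:
                return Rejection("clash", f"{a}-{b} CA pair at {math.sqrt(d2):.2f} Å",
                                 provenance=prov)
    all_ca = np.concatenate([chains[k].ca for k in names])
    radial = np.linalg.norm(all_ca[:, :2], axis=1)
    if np.any(radial < SLOT_RADIUS + config.clash_cutoff):
        return Rejection("slot_occlusion",
                         f"scaffold CA at {radial.min():.2f} Å from slot axis",
                         provenance=prov)

    slot_len = max(lengths[k] for k in ("g1", "g2", "g3"))
    groove_z = np.concatenate([chains[k].ca[:, 2] for k in ("g1", "g2", "g3")])
    slot_z0 = float(groove_z.mean()) - 1.5 * (slot_len - 1) / 2.0
    slot = CrickParams(R0=0.0, omega0=0.0, phi0=0.0, omega1=100.0,
                       phi1=0.0, z_offset=slot_z0, length=slot_len, rise=1.5)
    return ScaffoldCandidate(params=params, chains=chains, slot_params=slot,
                             provenance=prov)


def sample_library(n: int, config: SamplingConfig
                   ) -> tuple[list[ScaffoldCandidate], dict[str, int]]:
    """Rejection-sample exactly ``n`` accepted candidates.

    Returns the candidates plus statistics: rejection counts by reason and
    ``avg_dist_draws``, the average-neighbour-distance draw of every
    attempt (accepted or not), for law-of-large-numbers auditing of the
    sampler against its own raw draws.  Raises
    :class:`ConfigurationError` if acceptance stays below 0.1% after 10^6
    attempts.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(config.seed)
    out: list[ScaffoldCandidate] = []
    stats: dict = {"accepted": 0, "avg_dist_draws": []}
    attempts = 0
    while len(out) < n:
        attempts += 1
        cand = sample_candidate(config, rng)
        stats["avg_dist_draws"].append(cand.provenance["avg_neighbor_dist"])
        if isinstance(cand, Rejection):
            stats[cand.reason] = stats.get(cand.reason, 0) + 1
        else:
            cand.provenance.update(seed=config.seed, index=len(out),
                                   attempt=attempts)
            out.append(cand)
            stats["accepted"] += 1
        if attempts >= 1_000_000 and stats["accepted"] < 0.001 * attempts:
            raise ConfigurationError(
                f"acceptance rate {stats['accepted'] / attempts:.2e} below "
                "0.1% after 10^6 attempts")
    return out, stats


@dataclass
class DockedComplex:
    """Scaffold helices plus the target helix placed in the groove slot."""
    scaffold: ScaffoldCandidate
    target: BackboneChain                   # chain id "T"

    @property
    def scaffold_ca(self) -> np.ndarray:
        return self.scaffold.all_ca()


def dock_target(candidate: ScaffoldCandidate,
                target: BackboneChain | str,
                clash_cutoff: float = 4.0) -> DockedComplex:
    """Place a target helix on the central-slot axis of a scaffold.

    ``target`` may be a peptide sequence (an ideal helix is built for it)
    or an existing helical chain, which is moved onto the slot axis.
    Raises :class:`DockingError` on length overflow or steric clash (the
    clash message lists the offending residue pairs).
    """
    slot = candidate.slot_params
    if isinstance(target, str):
        seq = target
        if len(seq) > slot.length + 4:
            raise DockingError(
                f"target length {len(seq)} exceeds slot length {slot.length} + 4")
        chain = ideal_straight_helix(len(seq), chain_id="T", sequence=seq,
                                     z_offset=slot.z_offset
                                     + 1.5 * (slot.length - len(seq)) / 2.0)
    else:
        if len(target) > slot.length + 4:
            raise DockingError(
                f"target length {len(target)} exceeds slot length {slot.length} + 4")
        from .crick import helix_axis  # local import to avoid cycle noise
        axis = helix_axis(target)
        centre = axis.mean(axis=0)
        direction = axis[-1] - axis[0]
        direction /= np.linalg.norm(direction)
        # rotate fitted axis onto +z
        v = np.cross(direction, [0.0, 0.0, 1.0])
        s = np.linalg.norm(v)
        cth = float(direction @ [0.0, 0.0, 1.0])
        if s < 1e-12:
            R = np.eye(3) if cth > 0 else np.diag([1.0, -1.0, -1.0])
        else:
            K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
            R = np.eye(3) + K + K @ K * ((1 - cth) / s ** 2)
        slot_centre = np.array([0.0, 0.0,
                                slot.z_offset + 1.5 * (slot.length - 1) / 2.0])
        chain = target.transformed(rotation=R,
                                   translation=slot_centre - R @ centre)
        chain.chain_id = "T"
    d = np.linalg.norm(candidate.all_ca()[:, None, :] - chain.ca[None, :, :],
                       axis=-1)
    if np.min(d) < clash_cutoff:
        bad = np.argwhere(d < clash_cutoff)
        pairs = ", ".join(f"scaffold#{i}-target#{j}" for i, j in bad[:10])
        raise DockingError(f"steric clash in slot: {pairs}")
    return DockedComplex(scaffold=candidate, target=chain)


def groove_is_open(candidate: ScaffoldCandidate,
                   half_width_deg: float = 45.0,
                   radial_limit: float = 10.0) -> bool:
    """True if the groove face between g1 and g3 is solvent-open: rays
    from the slot axis through the gap hit no scaffold CA within
    ``radial_limit``.  The gap twists with the supercoil, so azimuths are
    evaluated in the detwisted frame (rotated back by omega0 per axial
    rise)."""
    ca = candidate.all_ca()
    omega0 = float(candidate.provenance.get("omega0", 0.0))
    z_mid = float(ca[:, 2].mean())
    radial = np.linalg.norm(ca[:, :2], axis=1)
    azim = np.degrees(np.arctan2(ca[:, 1], ca[:, 0]))
    azim = (azim - omega0 * (ca[:, 2] - z_mid) / 1.5 + 180.0) % 360.0 - 180.0
    inside = (radial < radial_limit) & (np.abs(azim) < half_width_deg)
    return not bool(inside.any())
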