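"""Loop closure: connect five scaffold helices into a single chain.

The closure is purely geometric: helices are visited in some order, each
traversed forward or reversed, and consecutive termini are bridged by
short loops whose Cα atoms lie on a circular arc bulged away from the
scaffold body, with Cα–Cα steps in the protein-like [3.6, 4.0] Å window.
Full backbone atoms for loop residues are completed by local
ideal-template fitting; helix coordinates are preserved exactly.

Strongly supercoiled bundles spread their termini further apart, so they
fail closure more often — closure failure is a value, not an exception.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .crick import BackboneChain, backbone_from_ca
from .sampling import ScaffoldCandidate

_CA_STEP = 3.8          # target Cα–Cα step along a loop (Å)
_GAP_SLACK = 2.0        # admissibility slack on junction gaps (Å)
_MIN_NONLOCAL = 3.5     # post-closure non-local Cα clash floor (Å)


@dataclass(frozen=True)
class ConnectionPlan:
    """Helix visit order with per-helix direction and per-junction loops.

    ``order`` is a permutation of helix names; ``reverse[i]`` marks whether
    helix ``order[i]`` is traversed C→N (rebuilt reversed); ``loop_lengths``
    holds the residue count of each of the four junction loops.
    """
    order: tuple[str, ...]
    reverse: tuple[bool, ...]
    loop_lengths: tuple[int, ...]
    total_gap: float

    def __post_init__(self) -> None:
        if sorted(self.order) != sorted(set(self.order)):
            raise ValueError("order must be a permutation without repeats")
        if len(self.reverse) != len(self.order):
            raise ValueError("one direction flag per helix required")
        if len(self.loop_lengths) != len(self.order) - 1:
            raise ValueError("one loop length per junction required")


@dataclass
class ClosureFailure:
    """Geometric failure closing one junction (a value, not an error)."""
    junction: int
    reason: str


@dataclass
class ClosedChain:
    """Single-chain result of loop closure."""
    chain: BackboneChain
    plan: ConnectionPlan
    #: per-residue origin: helix name or "loop<i>", with source index
    residue_map: list[tuple[str, int]] = field(default_factory=list)


def _oriented(chains: dict[str, BackboneChain], name: str,
              rev: bool) -> BackboneChain:
    ch = chains[name]
    return ch.reversed() if rev else ch


def enumerate_plans(candidate: ScaffoldCandidate,
                    loop_len_range: tuple[int, int] = (2, 5),
                    max_plans: int | None = None) -> list[ConnectionPlan]:
    """All admissible visit order / direction combinations, best first.

    Plans are ranked by total end-to-start Euclidean gap over the four
    junctions; a plan is admissible only if every junction gap is at most
    ``loop_len_max * 3.8 + 2`` Å.  Each junction is assigned the smallest
    loop length in range that can span its gap.  May return an empty list.
    """
    lo, hi = loop_len_range
    if lo < 1 or hi < lo:
        raise ValueError("loop length range must be ascending and >= 1")
    names = list(candidate.chains)
    # cache termini for both directions of every helix
    term = {}
    for k in names:
        ca = candidate.chains[k].ca
        term[(k, False)] = (ca[0], ca[-1])
        term[(k, True)] = (ca[-1], ca[0])
    gap_limit = hi * _CA_STEP + _GAP_SLACK
    plans: list[ConnectionPlan] = []
    for order in itertools.permutations(names):
        for rev in itertools.product((False, True), repeat=len(names)):
            gaps = []
            ok = True
            for i in range(len(order) - 1):
                g = float(np.linalg.norm(
                    term[(order[i + 1], rev[i + 1])][0]
                    - term[(order[i], rev[i])][1]))
                if g > gap_limit:
                    ok = False
                    break
                gaps.append(g)
            if not ok:
                continue
            loop_lens = []
            for g in gaps:
                # smallest loop whose (L+1) steps of <= 4.0 Å can span the gap
                L = lo
                while L < hi and 4.0 * (L + 1) < g:
                    L += 1
                loop_lens.append(L)
            plans.append(ConnectionPlan(order=order, reverse=rev,
                                        loop_lengths=tuple(loop_lens),
                                        total_gap=float(sum(gaps))))
    plans.sort(key=lambda p: (p.total_gap, p.order, p.reverse))
    return plans[:max_plans] if max_plans is not None else plans


def _arc_points(p0: np.ndarray, p1: np.ndarray, n_interior: int,
                bulge_dir: np.ndarray) -> np.ndarray | None:
    """Interior points of a circular arc from p0 to p1 with ~3.8 Å steps.

    The arc lies in the plane spanned by the chord and ``bulge_dir`` and
    has arc length (n_interior + 1) * 3.8 Å; if the chord is already that
    long or longer, points are placed on the straight segment instead.
    Returns None if no protein-like spacing is achievable.
    """
    chord = p1 - p0
    c = float(np.linalg.norm(chord))
    n_steps = n_interior + 1
    s = _CA_STEP * n_steps
    if c < 1e-9:
        return None
    ts = np.arange(1, n_steps) / n_steps
    if c >= s:  # stretch straight; admissibility bounds the step at 4.0-ish
        return p0 + np.outer(ts, chord)
    # solve chord/arc ratio: sin(x)/x = c/s with x = theta/2
    f = lambda x: math.sin(x) / x - c / s
    try:
        x = brentq(f, 1e-9, math.pi - 1e-9)
    except ValueError:
        return None
    theta = 2.0 * x
    R = s / theta
    u = chord / c
    w = bulge_dir - np.dot(bulge_dir, u) * u
    nw = np.linalg.norm(w)
    if nw < 1e-9:
        w = np.array([0.0, 0.0, 1.0]) - u * u[2]
        nw = np.linalg.norm(w)
        if nw < 1e-9:
            w = np.array([1.0, 0.0, 0.0]) - u * u[0]
            nw = np.linalg.norm(w)
    w /= nw
    mid = 0.5 * (p0 + p1)
    centre = mid - w * R * math.cos(x)
    # parametrize from p0 to p1 through the bulged side
    v0 = p0 - centre
    ang = theta * ts
    # rotate v0 about the plane normal toward p1
    normal = np.cross(u, w)
    normal /= np.linalg.norm(normal)
    def _rot(vec: np.ndarray, b: float) -> np.ndarray:
        return (vec * math.cos(b)
                + np.cross(normal, vec) * math.sin(b)
                + normal * np.dot(normal, vec) * (1 - math.cos(b)))

    # the arc may be reflex (> 180°), so pick the rotation sense that
    # actually lands on p1 after the full sweep
    v1 = p1 - centre
    err_pos = np.linalg.norm(_rot(v0, theta) - v1)
    err_neg = np.linalg.norm(_rot(v0, -theta) - v1)
    sense = 1.0 if err_pos <= err_neg else -1.0
    if min(err_pos, err_neg) > 1e-6 * max(R, 1.0):
        return None
    pts = []
    for a in ang:
        b = sense * a
        rot = (v0 * math.cos(b)
               + np.cross(normal, v0) * math.sin(b)
               + normal * np.dot(normal, v0) * (1 - math.cos(b)))
        pts.append(centre + rot)
    return np.array(pts)


def close_loops(candidate: ScaffoldCandidate, plan: ConnectionPlan,
                ) -> ClosedChain | ClosureFailure:
    """Build the single-chain backbone realizing a connection plan.

    Returns a :class:`ClosureFailure` naming the junction if loop Cα
    placement cannot keep steps within [3.6, 4.0] Å or introduces a
    non-local Cα contact below 3.5 Å.  Helix Cα/N/C/O coordinates are
    preserved exactly; only loop residues are newly built.
    """
    oriented = [_oriented(candidate.chains, k, r)
                for k, r in zip(plan.order, plan.reverse)]
    body = candidate.all_ca()
    centre = body.mean(axis=0)
    ca_segments: list[np.ndarray] = []
    residue_map: list[tuple[str, int]] = []
    placed_loops: list[np.ndarray] = []
    for i, (name, ch) in enumerate(zip(plan.order, oriented)):
        ca_segments.append(ch.ca)
        residue_map.extend((name, j) for j in range(len(ch)))
        if i == len(oriented) - 1:
            break
        p0 = ch.ca[-1]
        p1 = oriented[i + 1].ca[0]
        L = plan.loop_lengths[i]
        mid = 0.5 * (p0 + p1)
        # candidate bulge directions, most outward-pointing first
        r_hat = mid - centre
        nr = np.linalg.norm(r_hat)
        r_hat = r_hat / nr if nr > 1e-9 else np.array([1.0, 0.0, 0.0])
        z_hat = np.array([0.0, 0.0, 1.0])
        t_hat = np.cross(z_hat, r_hat)
        nt = np.linalg.norm(t_hat)
        t_hat = t_hat / nt if nt > 1e-9 else np.array([0.0, 1.0, 0.0])
        bulges = [r_hat, r_hat + 0.7 * z_hat, r_hat - 0.7 * z_hat,
                  r_hat + t_hat, r_hat - t_hat, z_hat, -z_hat]
        # context for the clash pre-check: every helix CA except the two
        # attachment residues, plus already-placed loops
        ctx = [body[~np.all(np.isclose(body, p0), axis=1)
                    & ~np.all(np.isclose(body, p1), axis=1)]]
        ctx.extend(placed_loops)
        context = np.vstack(ctx)
        loop_ca = None
        why = "degenerate junction"
        for bulge in bulges:
            trial = _arc_points(p0, p1, L, bulge)
            if trial is None:
                continue
            steps = np.linalg.norm(
                np.diff(np.vstack([p0[None], trial, p1[None]]), axis=0), axis=1)
            if not np.all((steps >= 3.6) & (steps <= 4.0)):
                why = (f"loop step {steps.min():.2f}-{steps.max():.2f} Å "
                       "outside [3.6, 4.0]")
                continue
            dmin = np.min(np.linalg.norm(
                trial[:, None, :] - context[None, :, :], axis=-1))
            if dmin < _MIN_NONLOCAL:
                why = f"loop sweeps within {dmin:.2f} Å of the scaffold"
                continue
            loop_ca = trial
            break
        if loop_ca is None:
            return ClosureFailure(junction=i, reason=why)
        placed_loops.append(loop_ca)
        ca_segments.append(loop_ca)
        residue_map.extend((f"loop{i}", j) for j in range(L))
    ca = np.vstack(ca_segments)
    # Non-local clash check (|i-j| > 2) restricted to pairs involving a
    # loop residue: closure must not *add* contacts; helix–helix packing
    # was already gated at the sampling stage.
    d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
    idx = np.arange(len(ca))
    is_loop = np.array([src.startswith("loop") for src, _ in residue_map])
    nonlocal_mask = (np.abs(idx[:, None] - idx[None, :]) > 2) \
        & (is_loop[:, None] | is_loop[None, :])
    if np.any(d[nonlocal_mask] < _MIN_NONLOCAL):
        bad = np.argwhere((d < _MIN_NONLOCAL) & nonlocal_mask)
        # attribute the failure to the junction of the first loop residue hit
        junction = 0
        for i_res in bad[:, 0]:
            src = residue_map[int(i_res)][0]
            if src.startswith("loop"):
                junction = int(src[4:])
                break
        return ClosureFailure(junction=junction,
                              reason=f"non-local CA contact {d[nonlocal_mask].min():.2f} Å")
    chain = backbone_from_ca(ca, chain_id="A")
    # Restore exact helix backbone atoms (Cα positions are preserved by
    # construction).  The atoms that bond across a junction — C/O of the
    # residue entering a loop and N of the residue leaving it — keep the
    # chain-wide build so the peptide bond stays continuous.
    pos = 0
    n_exact = np.zeros(len(ca), dtype=bool)
    c_exact = np.zeros(len(ca), dtype=bool)
    for i, ch in enumerate(oriented):
        Lh = len(ch)
        lo_n = pos + 1 if i > 0 else pos
        chain.n[lo_n:pos + Lh] = ch.n[lo_n - pos:]
        n_exact[lo_n:pos + Lh] = True
        hi_c = pos + Lh - 1 if i < len(oriented) - 1 else pos + Lh
        chain.c[pos:hi_c] = ch.c[:hi_c - pos]
        chain.o[pos:hi_c] = ch.o[:hi_c - pos]
        c_exact[pos:hi_c] = True
        pos += Lh
        if i < len(oriented) - 1:
            pos += plan.loop_lengths[i]
    # Enforce peptide-bond continuity where the local trace is far from
    # helical (template fits of neighbouring kinked triplets disagree):
    # snap the rebuilt atom onto the bond vector at ideal C–N length.
    for i in range(len(ca) - 1):
        v = chain.n[i + 1] - chain.c[i]
        d = float(np.linalg.norm(v))
        if 1.2 <= d <= 1.5 or d < 1e-9:
            continue
        if not n_exact[i + 1]:
            chain.n[i + 1] = chain.c[i] + 1.329 * v / d
        elif not c_exact[i]:
            chain.c[i] = chain.n[i + 1] - 1.329 * v / d
    return ClosedChain(chain=chain, plan=plan, residue_map=residue_map)


def close_candidate(candidate: ScaffoldCandidate,
                    loop_len_range: tuple[int, int] = (2, 5),
                    max_plans: int = 40) -> ClosedChain | ClosureFailure:
    """Try ranked plans in order; return the first closure that succeeds."""
    plans = enumerate_plans(candidate, loop_len_range, max_plans=max_plans)
    last: ClosedChain | ClosureFailure = ClosureFailure(0, "no admissible plan")
    for plan in plans:
        result = close_loops(candidate, plan)
        if isinstance(result, ClosedChain):
            return result
        last = result
    return last
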