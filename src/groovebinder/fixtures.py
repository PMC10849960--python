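"""Deterministic fixture generators exercising every module.

All fixtures are synthetic and generated at run time: ideal poly-alanine
helices, small docked groove complexes, hash-seeded oracle tensors, and
analytically complementary surface patches for shape-complementarity
checks.  Nothing here requires a download.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .crick import BackboneChain, ideal_straight_helix
from .hallucination import HashOracle, OraclePrediction, init_sequence
from .metrics import DotSurface
from .sampling import (DockedComplex, SamplingConfig, dock_target,
                       sample_library)

FIXTURE_KINDS = ("ideal_helix_peptide", "toy_complex", "oracle_tensors",
                 "sc_toy_surfaces")


class FixtureError(ValueError):
    """Unknown fixture kind or bad parameters."""


def ideal_helix_peptide(length: int = 34, sequence: str | None = None
                        ) -> BackboneChain:
    """Ideal α-helical peptide (poly-Ala unless a sequence is given)."""
    if sequence is not None and len(sequence) != length:
        raise FixtureError("sequence length must match requested length")
    return ideal_straight_helix(length, chain_id="T", sequence=sequence)


def toy_complex(seed: int = 0, target_length: int = 15) -> DockedComplex:
    """One sampled groove scaffold with a poly-Ala target docked.

    For targets longer than the default 15–19-residue helices, the
    scaffold helices are stretched to match so the slot can hold them.
    """
    length_range = (max(15, target_length), max(19, target_length))
    lib, _ = sample_library(1, SamplingConfig(seed=seed,
                                              helix_length_range=length_range))
    return dock_target(lib[0], "A" * target_length)


def oracle_tensors(binder_length: int = 80, target_length: int = 34,
                   seed: int = 0) -> OraclePrediction:
    """Hash-seeded oracle output of the full contract shape."""
    rng = np.random.default_rng(seed)
    binder = init_sequence(binder_length, rng)
    target = init_sequence(target_length, rng)
    return HashOracle().predict(binder, target)


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def sc_toy_surfaces(radius: float = 10.0, gap: float = 0.25,
                    cap_fraction: float = 0.35, n_points: int = 4000
                    ) -> tuple[DotSurface, DotSurface]:
    """Convex spherical cap seated in an exactly complementary pocket.

    The pocket surface is the cap pushed outward by ``gap`` with inward
    normals, so every point has a near-ideal opposing partner; the pair
    scores a shape complementarity close to 1.
    """
    unit = _fibonacci_sphere(n_points)
    cap = unit[unit[:, 2] > 1.0 - 2.0 * cap_fraction]
    area = 4.0 * np.pi * radius * radius / n_points
    convex = DotSurface(points=radius * cap, normals=cap.copy(),
                        areas=np.full(len(cap), area))
    pocket = DotSurface(points=(radius + gap) * cap, normals=-cap.copy(),
                        areas=np.full(len(cap), area))
    return convex, pocket


def make_fixture(kind: str, out_dir: str | Path, seed: int = 0,
                 **params) -> list[Path]:
    """Write a named fixture to disk; returns the created files.

    Structures go out as PDB, oracle tensors and surfaces as ``.npz``
    archives.  Deterministic in (kind, seed, params).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    from .io import write_structure
    if kind == "ideal_helix_peptide":
        chain = ideal_helix_peptide(int(params.get("length", 34)),
                                    params.get("sequence"))
        path = out_dir / "ideal_helix_peptide.pdb"
        write_structure(path, [chain])
        return [path]
    if kind == "toy_complex":
        dc = toy_complex(seed=seed,
                         target_length=int(params.get("target_length", 15)))
        path = out_dir / "toy_complex.pdb"
        write_structure(path, dc.scaffold.helices + [dc.target])
        return [path]
    if kind == "oracle_tensors":
        pred = oracle_tensors(int(params.get("binder_length", 80)),
                              int(params.get("target_length", 34)), seed=seed)
        path = out_dir / "oracle_tensors.npz"
        np.savez(path, plddt=pred.plddt, ptm=pred.ptm,
                 pae=pred.pae.values, distogram=pred.distogram.probs,
                 edges=pred.distogram.edges, coords=pred.coords)
        return [path]
    if kind == "sc_toy_surfaces":
        a, b = sc_toy_surfaces(
            radius=float(params.get("radius", 10.0)),
            gap=float(params.get("gap", 0.25)))
        path = out_dir / "sc_toy_surfaces.npz"
        np.savez(path, points_a=a.points, normals_a=a.normals, areas_a=a.areas,
                 points_b=b.points, normals_b=b.normals, areas_b=b.areas)
        return [path]
    raise FixtureError(f"unknown fixture kind {kind!r}; "
                       f"choose from {FIXTURE_KINDS}")
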