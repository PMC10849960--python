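"""Thread target peptide sequences onto the groove-bound slot helix.

Given a scaffold–helix complex, a peptide of interest is placed onto the
bound helix at every register and orientation, and each threading is
scored by how many peptide positions make hydrophobic contact with the
scaffold.  Side chains are not modelled: contacts are measured between
Cβ proxy points built from the backbone at ideal tetrahedral geometry
(glycine falls back to Cα).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .crick import BackboneChain
from .sampling import DockedComplex

HYDROPHOBIC = frozenset("AVLIMFWY")
CB_CUTOFF = 8.0  # Å between Cβ proxies


class ThreadingSizeError(ValueError):
    """Peptide does not fit the slot helix."""


def cb_proxy(chain: BackboneChain, sequence: str | None = None) -> np.ndarray:
    """Idealized Cβ positions from backbone N/Cα/C geometry.

    Uses the standard tetrahedral construction
    Cβ = Cα − 0.5827·(b×c) + 0.5680·b − 0.5407·c with b = Cα−N, c = C−Cα;
    glycine positions return Cα itself.
    """
    b = chain.ca - chain.n
    c = chain.c - chain.ca
    a = np.cross(b, c)
    cb = chain.ca - 0.58273431 * a + 0.56802827 * b - 0.54067466 * c
    seq = sequence if sequence is not None else chain.sequence
    if seq:
        gly = np.array([aa == "G" for aa in seq])
        cb[gly] = chain.ca[gly]
    return cb


@dataclass
class ThreadedComplex:
    """A peptide sequence placed on the slot helix at one register.

    ``offset`` is 0-based into the slot numbering; ``orientation`` is
    "parallel" (peptide N→C along slot numbering) or "antiparallel".
    ``annotations`` per peptide position: (is_hydrophobic, in_contact);
    ``count`` caches the hydrophobic-contact score once computed.
    """
    scaffold_ca_cb: np.ndarray               # scaffold Cβ proxies
    slot: BackboneChain
    peptide: str
    offset: int
    orientation: str
    annotations: list[tuple[bool, bool]] = field(default_factory=list)
    count: int | None = None

    def __post_init__(self) -> None:
        if self.orientation not in ("parallel", "antiparallel"):
            raise ValueError("orientation must be parallel or antiparallel")
        if not 0 <= self.offset <= len(self.slot) - len(self.peptide):
            raise ValueError("register offset out of range")

    def slot_indices(self) -> np.ndarray:
        """Slot residue index carrying each peptide position."""
        idx = self.offset + np.arange(len(self.peptide))
        return idx if self.orientation == "parallel" else idx[::-1]


def _scaffold_cb(complex_model: DockedComplex | Iterable[BackboneChain]
                 ) -> np.ndarray:
    if isinstance(complex_model, DockedComplex):
        chains = complex_model.scaffold.helices
    elif isinstance(complex_model, BackboneChain):
        chains = [complex_model]
    else:
        chains = list(complex_model)
    return np.vstack([cb_proxy(ch) for ch in chains])


def enumerate_threadings(complex_model, peptide: str,
                         orientations: Sequence[str] = ("parallel",
                                                        "antiparallel"),
                         ) -> list[ThreadedComplex]:
    """All (register, orientation) placements of a peptide on the slot.

    ``complex_model`` is a :class:`~groovebinder.sampling.DockedComplex`
    (its target chain is the slot helix) or any scaffold chain collection
    paired with a slot via ``(chains, slot)`` tuple.  Ordering is
    deterministic: offset ascending, parallel before antiparallel.
    """
    if isinstance(complex_model, tuple):
        chains, slot = complex_model
        scaffold_cb = _scaffold_cb(chains)
    elif isinstance(complex_model, DockedComplex):
        slot = complex_model.target
        scaffold_cb = _scaffold_cb(complex_model)
    else:
        raise TypeError("need a DockedComplex or a (chains, slot) tuple")
    if len(peptide) > len(slot):
        raise ThreadingSizeError(
            f"peptide length {len(peptide)} exceeds slot length {len(slot)}")
    out = []
    for offset in range(len(slot) - len(peptide) + 1):
        for orientation in orientations:
            out.append(ThreadedComplex(
                scaffold_ca_cb=scaffold_cb, slot=slot, peptide=peptide,
                offset=offset, orientation=orientation))
    return out


def hydrophobic_contact_count(threaded: ThreadedComplex,
                              cutoff: float = CB_CUTOFF) -> int:
    """Number of peptide positions forming hydrophobic interface contacts.

    A position counts if its residue is in the hydrophobic set
    {A,V,L,I,M,F,W,Y} and its Cβ proxy (built on the slot backbone at its
    register position) lies within ``cutoff`` of any scaffold Cβ proxy.
    Annotations are stored on the threading as a side effect.
    """
    slot_cb = cb_proxy(threaded.slot, sequence=None)
    idx = threaded.slot_indices()
    pep_cb = slot_cb[idx]
    # glycine in the peptide: fall back to the slot CA at that register
    gly = np.array([aa == "G" for aa in threaded.peptide])
    if gly.any():
        pep_cb = pep_cb.copy()
        pep_cb[gly] = threaded.slot.ca[idx[gly]]
    d2 = np.min(np.sum(
        (pep_cb[:, None, :] - threaded.scaffold_ca_cb[None, :, :]) ** 2,
        axis=-1), axis=1)
    in_contact = d2 <= cutoff ** 2
    hydrophobic = np.array([aa in HYDROPHOBIC for aa in threaded.peptide])
    threaded.annotations = list(zip(hydrophobic.tolist(), in_contact.tolist()))
    threaded.count = int(np.sum(hydrophobic & in_contact))
    return threaded.count


def filter_threadings(threadings: list[ThreadedComplex],
                      min_hydrophobic: int = 0,
                      cutoff: float = CB_CUTOFF) -> list[ThreadedComplex]:
    """Rank threadings by hydrophobic contact count, best first.

    Unscored entries are scored in place.  Ties break by offset then
    orientation (parallel first); entries below ``min_hydrophobic`` are
    dropped.
    """
    for t in threadings:
        if t.count is None:
            hydrophobic_contact_count(t, cutoff)
    kept = [t for t in threadings if t.count >= min_hydrophobic]
    return sorted(kept, key=lambda t: (-t.count, t.offset,
                                       0 if t.orientation == "parallel" else 1))
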