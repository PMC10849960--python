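"""Structure and sequence I/O, run configuration, and stage logging.

PDB reading and writing go through biotite; chains are exchanged with the
rest of the package as :class:`~groovebinder.crick.BackboneChain` objects.
Reading keeps the first altLoc conformer and skips waters and other
heteroatoms unless asked otherwise; author residue numbering is preserved
in a side table.  Writing emits ATOM records with TER separators between
chains.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from biotite.sequence import ProteinSequence

from .crick import BackboneChain

logger = logging.getLogger("groovebinder")

_BACKBONE_ATOMS = ("N", "CA", "C", "O")


class StructureParseError(ValueError):
    """Malformed or unusable structure file."""


def _three_to_one(res_name: str) -> str:
    try:
        return ProteinSequence.convert_letter_3to1(res_name)
    except Exception:
        return "X"


def chains_to_atom_array(chains: list[BackboneChain]) -> struc.AtomArray:
    """Backbone chains → biotite AtomArray (N, CA, C, O per residue)."""
    n_atoms = sum(4 * len(ch) for ch in chains)
    arr = struc.AtomArray(n_atoms)
    coords = np.empty((n_atoms, 3))
    pos = 0
    chain_ids, res_ids, res_names, atom_names, elements = [], [], [], [], []
    for ch in chains:
        seq = ch.sequence or "A" * len(ch)
        for i in range(len(ch)):
            res3 = ProteinSequence.convert_letter_1to3(seq[i]).upper()
            for name in _BACKBONE_ATOMS:
                coords[pos] = getattr(ch, name.lower() if name != "CA" else "ca")[i]
                chain_ids.append(ch.chain_id)
                res_ids.append(i + 1)
                res_names.append(res3)
                atom_names.append(name)
                elements.append(name[0])
                pos += 1
    arr.coord = coords
    arr.chain_id = np.array(chain_ids)
    arr.res_id = np.array(res_ids)
    arr.res_name = np.array(res_names)
    arr.atom_name = np.array(atom_names)
    arr.element = np.array(elements)
    return arr


def write_structure(path: str | Path, chains: list[BackboneChain]) -> None:
    """Write chains as a PDB model: ATOM records, TER between chains."""
    pdb = PDBFile()
    pdb.set_structure(chains_to_atom_array(chains))
    path = Path(path)
    pdb.write(path)
    # biotite emits plain ATOM records; insert TER separators by chain
    lines = path.read_text().splitlines()
    out, prev_chain = [], None
    for line in lines:
        if line.startswith("ATOM"):
            chain = line[21]
            if prev_chain is not None and chain != prev_chain:
                out.append("TER")
            prev_chain = chain
        out.append(line)
    out.append("TER")
    path.write_text("\n".join(out) + "\n")


def read_structure(path: str | Path, keep_hetero: bool = False
                   ) -> tuple[dict[str, BackboneChain], dict[str, list[int]]]:
    """Read a PDB file into per-chain backbone containers.

    Keeps the first altLoc conformer; skips waters and (by default) all
    heteroatoms.  Residues missing any backbone atom are dropped.  Returns
    ``(chains, numbering)`` where ``numbering[chain_id]`` lists the author
    residue ids in order (the containers themselves renumber 1..L).
    """
    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=1, altloc="first")
    except Exception as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    arr = arr[arr.res_name != "HOH"]
    if not keep_hetero:
        arr = arr[~arr.hetero]
    chains: dict[str, BackboneChain] = {}
    numbering: dict[str, list[int]] = {}
    for chain_id in np.unique(arr.chain_id):
        sub = arr[arr.chain_id == chain_id]
        res_atoms: dict[int, dict[str, np.ndarray]] = {}
        res_names: dict[int, str] = {}
        for atom in sub:
            if atom.atom_name in _BACKBONE_ATOMS:
                res_atoms.setdefault(int(atom.res_id), {})[atom.atom_name] = \
                    np.array(atom.coord)
                res_names[int(atom.res_id)] = atom.res_name
        ids = [rid for rid in sorted(res_atoms)
               if all(a in res_atoms[rid] for a in _BACKBONE_ATOMS)]
        if not ids:
            continue
        coords = {a: np.array([res_atoms[rid][a] for rid in ids])
                  for a in _BACKBONE_ATOMS}
        seq = "".join(_three_to_one(res_names[rid]) for rid in ids)
        chains[str(chain_id)] = BackboneChain(
            n=coords["N"], ca=coords["CA"], c=coords["C"], o=coords["O"],
            chain_id=str(chain_id), sequence=seq)
        numbering[str(chain_id)] = ids
    if not chains:
        raise StructureParseError(f"no usable protein chains in {path}")
    return chains, numbering


def read_fasta(path: str | Path) -> dict[str, str]:
    """Sequences from a FASTA file (id → sequence)."""
    from biotite.sequence.io.fasta import FastaFile
    ff = FastaFile.read(str(path))
    return dict(ff.items())


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    from biotite.sequence.io.fasta import FastaFile
    ff = FastaFile()
    for k, v in sequences.items():
        ff[k] = v
    ff.write(str(path))


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Top-level run configuration with lossless YAML round-trip.

    ``modules`` holds per-module sub-configurations as plain mappings;
    the global seed is stamped into every output header the CLI writes.
    """
    seed: int = 0
    out_dir: str = "out"
    verbosity: str = "INFO"
    modules: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def stage_counters(**counts: int) -> str:
    """Uniform one-line counter report for pipeline stages."""
    return " ".join(f"{k}={v}" for k, v in counts.items())
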