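"""Reading and writing backbone-level chain models from PDB files.

Predicted complex models (e.g. AlphaFold multimer output) are plain PDB
files whose B-factor column carries the per-residue pLDDT confidence
score.  This module reduces each chain to the five backbone atoms the
downstream geometry needs (N, CA, C, O, CB), validates the invariants the
pipeline relies on, and assigns receptor/substrate roles by sequence
identity against a reference receptor sequence.
"""

from __future__ import annotations

import glob as _glob
import logging
import os
import re
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "CA", "C", "O", "CB")

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}


class StructureError(ValueError):
    """Raised for PDB content that violates the pipeline's contracts."""


@dataclass
class ResidueRecord:
    """One residue: author number, one-letter code, backbone atoms, pLDDT.

    ``atoms`` maps atom names (N, CA, C, O, CB) to 3-vectors in Angstrom.
    CA is always present; CB is absent only for glycine.  ``plddt`` is the
    B-factor of the CA atom, expected in [0, 100].
    """

    author_number: int
    aa: str
    atoms: dict[str, np.ndarray]
    plddt: float

    @property
    def ca(self) -> np.ndarray:
        return self.atoms["CA"]

    @property
    def cb(self) -> np.ndarray | None:
        return self.atoms.get("CB")

    def has_full_backbone(self) -> bool:
        return all(name in self.atoms for name in ("N", "CA", "C", "O"))


@dataclass
class ChainModel:
    """One polypeptide chain as an ordered residue list."""

    chain_id: str
    residues: list[ResidueRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        nums = [r.author_number for r in self.residues]
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise StructureError(
                f"chain {self.chain_id}: residue author numbers not "
                f"strictly increasing"
            )
        for r in self.residues:
            if "CA" not in r.atoms:
                raise StructureError(
                    f"chain {self.chain_id}: residue {r.author_number} "
                    f"({r.aa}) lacks a CA atom"
                )

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def residue_by_number(self, number: int) -> ResidueRecord:
        for r in self.residues:
            if r.author_number == number:
                return r
        raise KeyError(f"residue {number} not in chain {self.chain_id}")

    def numbers(self) -> list[int]:
        return [r.author_number for r in self.residues]

    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues])


@dataclass
class ComplexModel:
    """A ranked receptor-substrate complex model."""

    receptor: ChainModel
    substrate: ChainModel
    rank: int = 0
    source_path: str = ""


def _prescan_atom_lines(path: str) -> None:
    # gemmi is lenient; this pre-scan supplies line-numbered errors for
    # records that would silently corrupt coordinates.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise StructureError(
                    f"{path}:{lineno}: truncated ATOM record"
                )
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise StructureError(
                        f"{path}:{lineno}: unparseable coordinate field "
                        f"{line[lo:hi]!r}"
                    ) from None


def read_pdb_model(path: str, model_index: int = 0) -> list[ChainModel]:
    """Read one MODEL block of a PDB file into ChainModels.

    One ChainModel per chain identifier; backbone atoms mapped by name;
    the CA B-factor is stored as pLDDT.  Only the requested MODEL block
    (default: the first) is read, and only the first-listed altloc of
    each atom is kept.
    """
    _prescan_atom_lines(path)
    st = gemmi.read_structure(path, format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise StructureError(f"{path}: no coordinate models")
    model = st[model_index]
    chains: list[ChainModel] = []
    for chain in model:
        residues: list[ResidueRecord] = []
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            if info is None or not info.is_amino_acid():
                continue
            atoms: dict[str, np.ndarray] = {}
            b_ca = None
            for atom in res:
                if atom.name in BACKBONE_ATOMS and atom.name not in atoms:
                    atoms[atom.name] = np.array(
                        [atom.pos.x, atom.pos.y, atom.pos.z]
                    )
                    if atom.name == "CA":
                        b_ca = atom.b_iso
            if "CA" not in atoms:
                raise StructureError(
                    f"{path}: chain {chain.name} residue "
                    f"{res.seqid.num} ({res.name}) has no CA atom"
                )
            plddt = float(b_ca)
            if not (0.0 <= plddt <= 100.0):
                warnings.warn(
                    f"{path}: chain {chain.name} residue {res.seqid.num}: "
                    f"B-factor {plddt} outside the pLDDT range [0, 100]",
                    stacklevel=2,
                )
            residues.append(
                ResidueRecord(
                    author_number=res.seqid.num,
                    aa=AA_3TO1.get(res.name, "X"),
                    atoms=atoms,
                    plddt=plddt,
                )
            )
        if residues:
            chains.append(ChainModel(chain_id=chain.name, residues=residues))
    if not chains:
        raise StructureError(f"{path}: no amino-acid chains found")
    return chains


def write_pdb(chains: list[ChainModel], path: str) -> None:
    """Write ChainModels as a single-model PDB file (pLDDT -> B-factor)."""
    st = gemmi.Structure()
    st.name = "catchscan"
    model = gemmi.Model("1")
    for cm in chains:
        chain = gemmi.Chain(cm.chain_id)
        for res in cm.residues:
            gres = gemmi.Residue()
            gres.name = AA_1TO3.get(res.aa, "UNK")
            gres.seqid = gemmi.SeqId(res.author_number, " ")
            for name in BACKBONE_ATOMS:
                if name not in res.atoms:
                    continue
                atom = gemmi.Atom()
                atom.name = name
                x, y, z = (float(v) for v in res.atoms[name])
                atom.pos = gemmi.Position(x, y, z)
                atom.element = gemmi.Element(name[0])
                atom.b_iso = float(res.plddt)
                atom.occ = 1.0
                gres.add_atom(atom)
            chain.add_residue(gres)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(path)


def _ungapped_identity(seq: str, ref: str) -> float:
    """Best ungapped-alignment identity of ``seq`` against ``ref``.

    Fraction of ``seq`` positions matching ``ref`` under the best sliding
    offset (no gaps).
    """
    if not seq or not ref:
        return 0.0
    best = 0
    for offset in range(-len(seq) + 1, len(ref)):
        matches = sum(
            1
            for i, aa in enumerate(seq)
            if 0 <= offset + i < len(ref) and ref[offset + i] == aa
        )
        best = max(best, matches)
    return best / len(seq)


def assign_roles(
    chains: list[ChainModel],
    receptor_sequence: str,
    rank: int = 0,
    source_path: str = "",
) -> ComplexModel:
    """Label the chain more identical to ``receptor_sequence`` as receptor.

    Requires exactly two chains; an identity tie is an error instructing
    an explicit chain-id override.
    """
    if len(chains) != 2:
        raise StructureError(
            f"expected exactly 2 chains, got {len(chains)}"
        )
    if not receptor_sequence:
        raise StructureError("receptor reference sequence is empty")
    ident = [_ungapped_identity(c.sequence, receptor_sequence) for c in chains]
    if ident[0] == ident[1]:
        raise StructureError(
            "chains tie on receptor sequence identity "
            f"({ident[0]:.3f}); pass an explicit receptor chain id"
        )
    i_rec = 0 if ident[0] > ident[1] else 1
    return ComplexModel(
        receptor=chains[i_rec],
        substrate=chains[1 - i_rec],
        rank=rank,
        source_path=source_path,
    )


def load_model_set(
    directory: str,
    receptor_sequence: str,
    n_models: int = 25,
    model_glob: str = "ranked_*.pdb",
) -> list[ComplexModel]:
    """Load a directory of ranked complex models, ordered by rank.

    Ranks are parsed from the first integer in each filename (AlphaFold's
    ``ranked_0.pdb`` .. ``ranked_24.pdb`` convention).  A partial set is
    accepted with a logged warning; an empty set is an error.
    """
    paths = sorted(_glob.glob(os.path.join(directory, model_glob)))
    ranked: list[tuple[int, str]] = []
    for p in paths:
        m = re.search(r"(\d+)", os.path.basename(p))
        rank = int(m.group(1)) if m else len(ranked)
        ranked.append((rank, p))
    ranked.sort()
    models: list[ComplexModel] = []
    for rank, p in ranked[:n_models]:
        chains = read_pdb_model(p)
        models.append(
            assign_roles(chains, receptor_sequence, rank=rank, source_path=p)
        )
    if not models:
        raise StructureError(
            f"no models matching {model_glob!r} in {directory}"
        )
    if len(models) < n_models:
        logger.warning(
            "%s: found %d models, expected %d", directory, len(models), n_models
        )
    return models
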