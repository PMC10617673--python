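"""Minimal Kabsch-Sander secondary-structure assignment.

Implements the electrostatic hydrogen-bond model and the bridge/ladder
logic needed to assign extended beta-strand state ("E") plus a simple
alpha-helix detector ("H"), self-contained and deterministic.  The amide
hydrogen is reconstructed geometrically (predicted models carry no
hydrogens), a bond is declared below -0.5 kcal/mol, and ladder membership
of at least two consecutive bridges is required for "E" (an isolated
bridge is coded '-').

Chain termini cannot be assigned (the first residue of a segment has no
reconstructable amide H) and are coded '?'; ``propagate_terminal_E``
applies the terminal-propagation rule that restores 'E' at a terminus
whose neighbour is 'E'.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import ChainModel, ResidueRecord

# Kabsch-Sander coupling constant q1*q2*f in kcal/mol * Angstrom
KS_COUPLING = 0.084 * 332.0
HBOND_CUTOFF = -0.5  # kcal/mol
CLASH_DISTANCE = 0.5  # Angstrom
PEPTIDE_BOND_MAX = 2.5  # C(i)-N(i+1) distance defining a chain break
CA_PREFILTER = 9.0  # Angstrom; pairs farther apart cannot H-bond
N_H_LENGTH = 1.0  # Angstrom


@dataclass
class SecondaryStructureString:
    """Per-residue codes over {E, H, '-', '?'} aligned to a ChainModel.

    ``segments`` lists the inclusive index ranges of continuous backbone
    (a physically broken chain yields several segments); '?' appears only
    at segment termini before propagation.
    """

    codes: str
    segments: list[tuple[int, int]]

    def __str__(self) -> str:  # serialized form: '?' collapses to '-'
        return self.codes.replace("?", "-")

    def __len__(self) -> int:
        return len(self.codes)


def amide_hydrogen(prev: ResidueRecord | None, res: ResidueRecord) -> np.ndarray | None:
    """Reconstruct the backbone amide H of ``res``.

    H sits 1.0 A from N along the direction of the previous residue's
    C=O bond (standard Kabsch-Sander placement).  Returns None when the
    residue is proline (no amide H) or the previous residue is absent.
    """
    if res.aa == "P" or prev is None:
        return None
    if "N" not in res.atoms or "C" not in prev.atoms or "O" not in prev.atoms:
        return None
    co = prev.atoms["C"] - prev.atoms["O"]
    norm = np.linalg.norm(co)
    if norm == 0:
        return None
    return res.atoms["N"] + N_H_LENGTH * co / norm


def hbond_energy(
    donor: ResidueRecord,
    donor_h: np.ndarray,
    acceptor: ResidueRecord,
) -> float:
    """Kabsch-Sander electrostatic H-bond energy in kcal/mol.

    ``donor`` provides N (with reconstructed H at ``donor_h``); the
    acceptor provides the carbonyl C=O.  E = q1*q2*f * (1/r_ON + 1/r_CH
    - 1/r_OH - 1/r_CN); a bond is declared when E < -0.5.
    """
    n = donor.atoms["N"]
    c = acceptor.atoms["C"]
    o = acceptor.atoms["O"]
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - donor_h)
    r_oh = np.linalg.norm(o - donor_h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) <= CLASH_DISTANCE:
        raise ValueError(
            f"atoms of residues {acceptor.author_number} (acceptor) and "
            f"{donor.author_number} (donor) clash (< {CLASH_DISTANCE} A)"
        )
    return KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _segments_of(residues: list[ResidueRecord]) -> list[tuple[int, int]]:
    """Split a residue list into continuous-backbone segments."""
    segments = []
    start = 0
    for k in range(len(residues) - 1):
        a, b = residues[k], residues[k + 1]
        broken = (
            "C" not in a.atoms
            or "N" not in b.atoms
            or np.linalg.norm(b.atoms["N"] - a.atoms["C"]) > PEPTIDE_BOND_MAX
            or b.author_number != a.author_number + 1
        )
        if broken:
            segments.append((start, k))
            start = k + 1
    segments.append((start, len(residues) - 1))
    return segments


class _Pool:
    """All residues of a model pooled for inter-chain bond detection."""

    def __init__(self, chains: list[ChainModel]):
        self.residues: list[ResidueRecord] = []
        self.chain_slices: list[tuple[str, int, int]] = []
        self.segments: list[tuple[int, int]] = []
        for cm in chains:
            base = len(self.residues)
            segs = [(a + base, b + base) for a, b in _segments_of(cm.residues)]
            self.residues.extend(cm.residues)
            self.segments.extend(segs)
            self.chain_slices.append((cm.chain_id, base, len(self.residues) - 1))
        self.seg_id = np.empty(len(self.residues), dtype=int)
        for s, (a, b) in enumerate(self.segments):
            self.seg_id[a : b + 1] = s
        self.hpos: list[np.ndarray | None] = []
        for idx, res in enumerate(self.residues):
            prev = (
                self.residues[idx - 1]
                if idx > 0 and self.seg_id[idx - 1] == self.seg_id[idx]
                else None
            )
            self.hpos.append(amide_hydrogen(prev, res))

    def hbond_matrix(self) -> np.ndarray:
        """hb[a, d] True iff C=O of residue a accepts the N-H of residue d."""
        n = len(self.residues)
        hb = np.zeros((n, n), dtype=bool)
        ca = np.array(
            [r.ca for r in self.residues]
        )
        near = cdist(ca, ca) < CA_PREFILTER
        for a in range(n):
            res_a = self.residues[a]
            if "C" not in res_a.atoms or "O" not in res_a.atoms:
                continue
            for d in range(n):
                if not near[a, d]:
                    continue
                same_seg = self.seg_id[a] == self.seg_id[d]
                if same_seg and abs(a - d) < 2:
                    continue
                if a == d:
                    continue
                res_d = self.residues[d]
                h = self.hpos[d]
                if h is None or "N" not in res_d.atoms:
                    continue
                try:
                    e = hbond_energy(res_d, h, res_a)
                except ValueError:
                    continue
                if e < HBOND_CUTOFF:
                    hb[a, d] = True
        return hb


def _bridges(hb: np.ndarray, seg_id: np.ndarray) -> dict[tuple[int, int], str]:
    """Kabsch-Sander bridge detection.

    Returns {(i, j): 'P'|'A'} for i < j.  hb[a, d] means CO(a)...HN(d).
    Bridges within one segment require |i - j| >= 3.
    """

    def valid(k: int, ref: int) -> bool:
        return 0 <= k < len(seg_id) and seg_id[k] == seg_id[ref]

    n = hb.shape[0]
    bridges: dict[tuple[int, int], str] = {}
    for i in range(n):
        for j in range(i + 1, n):
            if seg_id[i] == seg_id[j] and j - i < 3:
                continue
            antiparallel = (hb[i, j] and hb[j, i]) or (
                valid(i - 1, i)
                and valid(i + 1, i)
                and valid(j - 1, j)
                and valid(j + 1, j)
                and hb[i - 1, j + 1]
                and hb[j - 1, i + 1]
            )
            parallel = (
                valid(i - 1, i)
                and valid(i + 1, i)
                and hb[i - 1, j]
                and hb[j, i + 1]
            ) or (
                valid(j - 1, j)
                and valid(j + 1, j)
                and hb[j - 1, i]
                and hb[i, j + 1]
            )
            if antiparallel:
                bridges[(i, j)] = "A"
            elif parallel:
                bridges[(i, j)] = "P"
    return bridges


def _ladder_members(bridges: dict[tuple[int, int], str]) -> set[int]:
    """Residues in ladders of >= 2 consecutive same-type bridges."""
    members: set[int] = set()
    for (i, j), kind in bridges.items():
        if kind == "A":
            partners = [(i + 1, j - 1), (i - 1, j + 1)]
        else:
            partners = [(i + 1, j + 1), (i - 1, j - 1)]
        for p in partners:
            key = (min(p), max(p))
            if bridges.get(key) == kind:
                members.update((i, j))
                break
    return members


def _helix_members(hb: np.ndarray, seg_id: np.ndarray) -> set[int]:
    """Alpha-helix residues: two consecutive 4-turns mark i..i+3."""
    n = hb.shape[0]

    def turn4(i: int) -> bool:
        return (
            i + 4 < n
            and seg_id[i] == seg_id[i + 4]
            and hb[i, i + 4]
        )

    members: set[int] = set()
    for i in range(1, n):
        if turn4(i - 1) and turn4(i):
            members.update(range(i, i + 4))
    return members


def assign_secondary_structure(
    chains: list[ChainModel],
) -> dict[str, SecondaryStructureString]:
    """Assign per-residue codes for every chain of a model jointly.

    Beta bridges are detected across chains (a substrate strand pairs
    with receptor strands), so assignment must see the whole complex.
    Returns one SecondaryStructureString per chain id.
    """
    pool = _Pool(chains)
    hb = pool.hbond_matrix()
    bridges = _bridges(hb, pool.seg_id)
    e_set = _ladder_members(bridges)
    h_set = _helix_members(hb, pool.seg_id) - e_set  # E wins conflicts
    codes = ["-"] * len(pool.residues)
    for k in e_set:
        codes[k] = "E"
    for k in h_set:
        codes[k] = "H"
    for res_idx, res in enumerate(pool.residues):
        if not res.has_full_backbone():
            codes[res_idx] = "-"
    for a, b in pool.segments:
        codes[a] = "?"
        codes[b] = "?"
    out: dict[str, SecondaryStructureString] = {}
    for chain_id, lo, hi in pool.chain_slices:
        segs = [
            (a - lo, b - lo)
            for a, b in pool.segments
            if lo <= a and b <= hi
        ]
        out[chain_id] = SecondaryStructureString(
            codes="".join(codes[lo : hi + 1]), segments=segs
        )
    return out


def assign_ss(
    chain: ChainModel, context: list[ChainModel] | None = None
) -> SecondaryStructureString:
    """Secondary structure of one chain, optionally in complex context.

    ``context`` lists partner chains whose strands may pair with this
    chain; without it only intra-chain ladders are visible.
    """
    if len(chain) < 3:
        segs = _segments_of(chain.residues)
        codes = ["-"] * len(chain)
        for a, b in segs:
            codes[a] = "?"
            codes[b] = "?"
        return SecondaryStructureString("".join(codes), segs)
    chains = [chain] + list(context or [])
    return assign_secondary_structure(chains)[chain.chain_id]


def propagate_terminal_E(
    ss: SecondaryStructureString | str,
) -> SecondaryStructureString | str:
    """Resolve terminal '?' codes: 'E' iff the inward neighbour is 'E'.

    Any other '?' becomes '-'; no other position changes.  Accepts a
    plain string (treated as one segment) or a SecondaryStructureString.
    """
    if isinstance(ss, str):
        resolved = propagate_terminal_E(
            SecondaryStructureString(ss, [(0, len(ss) - 1)] if ss else [])
        )
        return resolved.codes
    codes = list(ss.codes)
    for a, b in ss.segments:
        if codes[a] == "?":
            codes[a] = "E" if a + 1 <= b and codes[a + 1] == "E" else "-"
        if codes[b] == "?":
            codes[b] = "E" if b - 1 >= a and codes[b - 1] == "E" else "-"
    codes = ["-" if c == "?" else c for c in codes]
    return SecondaryStructureString("".join(codes), ss.segments)
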