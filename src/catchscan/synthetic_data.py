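"""Synthetic fixtures: idealized capture complexes and simulated screens.

Two families of ground-truthed inputs:

* **Structures** — three-strand antiparallel beta sheets in which a
  substrate strand is sandwiched between two receptor anchor strands at
  realistic inter-strand spacing (plus alpha-helical decoys bound
  nowhere near the anchors), written as standard PDB with pLDDT in the
  B-factor column.  The strand registry between neighbouring strands is
  fixed by a deterministic calibration that maximizes Kabsch-Sander
  hydrogen bonding, so generated sheets genuinely satisfy the "E"
  secondary-structure contract they are meant to exercise.

* **Screens** — multinomial 6-bin read counts for a control and a
  treatment condition with planted stability (dPSI) shifts, implemented
  by moving probability mass along the bin axis so the expected PSI
  change equals the planted effect exactly.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from . import geometry as geom
from .secondary_structure import HBOND_CUTOFF, KS_COUPLING
from .structure_io import ChainModel, ComplexModel, ResidueRecord, write_pdb

ANCHOR_A_SEQ = "TIVELKAQVS"  # 10 residues, lands on 148-157 by default
ANCHOR_B_SEQ = "KVEVTFTA"  # 8 residues, 279-286
REF_AA = "I"  # isoleucine reference residue (default number 309)
DEFAULT_PLDDT = 90.0
CLASH_MIN = 2.2  # Angstrom between backbone heavy atoms
STRAND_AA = "VILFTYEKQA"  # strand/flank alphabet: no Gly (Cbeta) / Pro (H)


@dataclass
class SheetSpec:
    """Parameters of one synthetic capture (or decoy) complex."""

    strand_length: int = 8
    inter_strand_spacing: float = 4.8  # Angstrom
    substrate_sequence: str | None = None  # default: strand + 6-residue flanks
    receptor_numbering_offset: int = 0
    orientation: str = "antiparallel"  # or "parallel"
    flank: int = 6  # flank residues each side when sequence is generated
    seed: int = 0

    def __post_init__(self) -> None:
        if not (4.0 < self.inter_strand_spacing < 5.5):
            raise ValueError(
                f"inter-strand spacing {self.inter_strand_spacing} outside (4.0, 5.5)"
            )
        if self.strand_length < 1:
            raise ValueError("strand_length must be positive")
        if self.orientation not in ("antiparallel", "parallel"):
            raise ValueError("orientation must be antiparallel or parallel")
        if (
            self.substrate_sequence is not None
            and len(self.substrate_sequence) < self.strand_length
        ):
            raise ValueError("substrate sequence shorter than strand length")

    @property
    def anchor_a_start(self) -> int:
        return 148 + self.receptor_numbering_offset

    @property
    def anchor_b_start(self) -> int:
        return 279 + self.receptor_numbering_offset

    @property
    def ref_number(self) -> int:
        return 309 + self.receptor_numbering_offset


@dataclass
class ScreenSimSpec:
    """Parameters of one simulated 6-bin GPS screen."""

    n_genes: int = 1000
    reads_per_gene: int = 500
    effects: dict[str, float] = field(default_factory=dict)  # gene -> dPSI
    baseline: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0, 0.0, 1.0)
    stability_spread: float = 5.0  # span of per-gene stability offsets
    depth_factors: tuple[float, ...] | None = None  # per-bin sequencing depth
    seed: int = 0

    def __post_init__(self) -> None:
        b = np.asarray(self.baseline, dtype=float)
        if b.shape != (6,) or (b < 0).any() or abs(b.sum() - 1.0) > 1e-9:
            raise ValueError("baseline must be a normalized 6-bin distribution")
        for gene, eff in self.effects.items():
            if not -5.0 <= eff <= 5.0:
                raise ValueError(f"effect {eff} for {gene} outside [-5, 5]")


@dataclass
class ComplexFixture:
    """A generated complex plus its planted ground truth."""

    receptor: ChainModel
    substrate: ChainModel
    truth: dict

    def as_model(self, rank: int = 0) -> ComplexModel:
        return ComplexModel(
            receptor=self.receptor, substrate=self.substrate, rank=rank
        )

    def write(self, pdb_path: str, truth_path: str | None = None) -> None:
        write_pdb([self.receptor, self.substrate], pdb_path)
        if truth_path:
            with open(truth_path, "w") as fh:
                json.dump(self.truth, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# strand pairing


def _strand_arrays(residues: list[dict[str, np.ndarray]]) -> dict[str, np.ndarray]:
    arrays = {
        name: np.array([r[name] for r in residues])
        for name in ("N", "CA", "C", "O", "CB")
    }
    h = np.full_like(arrays["N"], np.nan)
    for k in range(1, len(residues)):
        co = residues[k - 1]["C"] - residues[k - 1]["O"]
        h[k] = residues[k]["N"] + co / np.linalg.norm(co)
    arrays["H"] = h
    return arrays


def _pair_hbond_score(a1: dict, a2: dict) -> tuple[int, float]:
    """(bond count, total bonded energy) between two strand atom sets."""
    heavy1 = np.concatenate([a1[n] for n in ("N", "CA", "C", "O", "CB")])
    heavy2 = np.concatenate([a2[n] for n in ("N", "CA", "C", "O", "CB")])
    if cdist(heavy1, heavy2).min() < CLASH_MIN:
        return -1, np.inf
    count, total = 0, 0.0
    for acc, don in ((a1, a2), (a2, a1)):
        with np.errstate(invalid="ignore", divide="ignore"):
            e = KS_COUPLING * (
                1.0 / cdist(acc["O"], don["N"])
                + 1.0 / cdist(acc["C"], don["H"])
                - 1.0 / cdist(acc["O"], don["H"])
                - 1.0 / cdist(acc["C"], don["N"])
            )
        bonded = e < HBOND_CUTOFF
        count += int(np.nansum(bonded))
        total += float(np.nansum(np.where(bonded, e, 0.0)))
    return count, total


_FLIPS = {
    "antiparallel": (
        np.diag([-1.0, 1.0, -1.0]),  # 180 about y
        np.diag([-1.0, -1.0, 1.0]),  # 180 about z
    ),
    "parallel": (
        np.eye(3),
        np.diag([1.0, -1.0, -1.0]),  # 180 about x
    ),
}


@lru_cache(maxsize=64)
def _calibrate_registry(
    spacing: float, len_sub: int, len_anchor: int, side: int, orientation: str
) -> tuple[int, float, float]:
    """Best (flip index, dx, dz) for an anchor at y = side*spacing.

    Deterministic coarse-then-fine grid search over one registry period.
    The objective is lexicographic: most Kabsch-Sander bonds first, then
    most substrate residues with a nearby anchor Calpha (aligned pleats
    make a true sandwich), then lowest total bonded energy.
    """
    sub = _strand_arrays(geom.canonical_strand(len_sub))
    anchor_res = geom.canonical_strand(len_anchor)
    flips = _FLIPS[orientation]
    close_cut = spacing + 0.5  # pairing counts as close within this CA-CA

    def score(fi: int, dx: float, dz: float) -> tuple[int, int, float]:
        shift = np.array([dx, side * spacing, dz])
        moved = geom.transform(anchor_res, flips[fi], shift)
        arrays = _strand_arrays(moved)
        n, e = _pair_hbond_score(sub, arrays)
        n_close = int(
            (cdist(sub["CA"], arrays["CA"]).min(axis=1) < close_cut).sum()
        )
        return n, n_close, e

    def better(a: tuple[int, int, float], b: tuple[int, int, float]) -> bool:
        return (a[0], a[1], -a[2]) > (b[0], b[1], -b[2])

    best = (-2, -1, np.inf)
    best_cand = (0, 0.0, 0.0)
    for fi in range(len(flips)):
        for dx in np.arange(-3.5, 3.51, 0.25):
            for dz in np.arange(-1.5, 1.51, 0.25):
                s = score(fi, float(dx), float(dz))
                if better(s, best):
                    best = s
                    best_cand = (fi, float(dx), float(dz))
    fi, dx0, dz0 = best_cand
    for dx in np.arange(dx0 - 0.25, dx0 + 0.251, 0.05):
        for dz in np.arange(dz0 - 0.25, dz0 + 0.251, 0.05):
            s = score(fi, float(dx), float(dz))
            if better(s, best):
                best = s
                best_cand = (fi, float(dx), float(dz))
    if best[0] <= 0:
        raise RuntimeError(
            f"no hydrogen-bonded registry found at spacing {spacing}"
        )
    return best_cand


# ---------------------------------------------------------------------------
# chain assembly


def _residues_from_atoms(
    atoms_list: list[dict[str, np.ndarray]],
    sequence: str,
    numbers: list[int],
    plddt: float | np.ndarray = DEFAULT_PLDDT,
) -> list[ResidueRecord]:
    plddt_arr = np.broadcast_to(np.asarray(plddt, dtype=float), (len(sequence),))
    records = []
    for atoms, aa, num, score in zip(atoms_list, sequence, numbers, plddt_arr):
        kept = {k: np.asarray(v) for k, v in atoms.items() if k != "H"}
        if aa == "G":
            kept.pop("CB", None)
        records.append(
            ResidueRecord(
                author_number=num, aa=aa, atoms=kept, plddt=float(score)
            )
        )
    return records


def _default_sequence(spec: SheetSpec) -> tuple[str, int]:
    """(substrate sequence, strand start index) for a spec."""
    if spec.substrate_sequence is not None:
        seq = spec.substrate_sequence
        start = (len(seq) - spec.strand_length) // 2
        return seq, start
    rng = np.random.default_rng(spec.seed)
    n = spec.strand_length + 2 * spec.flank
    seq = "".join(rng.choice(list(STRAND_AA), size=n))
    return seq, spec.flank


def _receptor_chain(spec: SheetSpec) -> tuple[ChainModel, dict]:
    """Anchor strands calibrated against the substrate + reference residue."""
    chains_res: list[ResidueRecord] = []
    for seq, start_num, side in (
        (ANCHOR_A_SEQ, spec.anchor_a_start, -1),
        (ANCHOR_B_SEQ, spec.anchor_b_start, +1),
    ):
        fi, dx, dz = _calibrate_registry(
            round(spec.inter_strand_spacing, 3),
            spec.strand_length,
            len(seq),
            side,
            spec.orientation,
        )
        flip = _FLIPS[spec.orientation][fi]
        shift = np.array([dx, side * spec.inter_strand_spacing, dz])
        moved = geom.transform(geom.canonical_strand(len(seq)), flip, shift)
        numbers = list(range(start_num, start_num + len(seq)))
        chains_res.extend(_residues_from_atoms(moved, seq, numbers))
    ref_pos = np.array([0.0, 0.0, -10.0])
    ref_res = geom.build_backbone([(geom.PHI_STRAND, geom.PSI_STRAND)])
    ref_res = geom.transform(ref_res, np.eye(3), ref_pos - ref_res[0]["CA"])
    chains_res.extend(
        _residues_from_atoms(ref_res, REF_AA, [spec.ref_number])
    )
    receptor = ChainModel(chain_id="A", residues=chains_res)
    return receptor, {"ref_point": ref_pos.tolist()}


def build_capture_complex(spec: SheetSpec | None = None) -> ComplexFixture:
    """Idealized three-strand sheet with the substrate strand captured.

    The substrate strand (extended dihedrals) sits between the two
    receptor anchor strands at the requested spacing; flanks are built
    alpha-helical so they neither pair with the anchors nor extend the
    planted strand.  The ground truth records the planted interval and
    the geometric inward (receptor-facing) parity.
    """
    spec = spec or SheetSpec()
    seq, start = _default_sequence(spec)
    L = spec.strand_length
    n_post = len(seq) - start - L
    canon = geom.canonical_strand(L)
    target = np.array([canon[k][n] for k in range(L) for n in ("N", "CA", "C")])

    def assemble(junc_pre, junc_post):
        """Chain with given junction dihedrals, strand superposed on canon."""
        helix = (geom.PHI_HELIX, geom.PSI_HELIX)
        strand = (geom.PHI_STRAND, geom.PSI_STRAND)
        dihedrals = [helix] * start + [strand] * L + [helix] * n_post
        if start > 0:
            dihedrals[start - 1] = junc_pre
        if n_post > 0:
            dihedrals[start + L] = junc_post
        res = geom.build_backbone(dihedrals)
        mobile = np.array(
            [res[start + k][n] for k in range(L) for n in ("N", "CA", "C")]
        )
        rot, shift = geom.kabsch_superpose(mobile, target)
        return geom.transform(res, rot, shift)

    receptor, extra = _receptor_chain(spec)
    anchor_atoms = np.array(
        [
            pos
            for r in receptor.residues
            for pos in r.atoms.values()
        ]
    )

    def clearance(res_list, lo, hi):
        if hi <= lo:
            return np.inf
        pts = np.array(
            [pos for r in res_list[lo:hi] for pos in r.values()]
        )
        return float(cdist(pts, anchor_atoms).min())

    # take-off dihedrals at each strand/flank junction: pick, per side,
    # the candidate steering the flank helix farthest from the anchors
    # among those whose junction residue does not extend the strand's
    # E-coding (the flank must not lengthen the planted strand)
    candidates = [
        (phi, psi)
        for phi in (-57.0, -90.0, 60.0)
        for psi in (-47.0, -30.0, 0.0, 60.0)
    ]

    def junction_ok(res_list, junction_idx: int) -> bool:
        sub = ChainModel(
            chain_id="B",
            residues=_residues_from_atoms(
                res_list, seq, list(range(1, len(seq) + 1))
            ),
        )
        from .secondary_structure import assign_secondary_structure

        codes = assign_secondary_structure([receptor, sub])["B"].codes
        return codes[junction_idx] != "E"

    def pick(junctions, lo, hi, junction_idx, other):
        scored = []
        for cand in junctions:
            res_list = (
                assemble(cand, other) if lo == 0 else assemble(other, cand)
            )
            scored.append(
                (junction_ok(res_list, junction_idx), clearance(res_list, lo, hi), cand)
            )
        scored.sort(key=lambda t: (t[0], t[1]))
        return scored[-1][2]

    default = (geom.PHI_HELIX, geom.PSI_HELIX)
    best_pre, best_post = default, default
    if start > 0:
        best_pre = pick(candidates, 0, start, start - 1, default)
    if n_post > 0:
        best_post = pick(candidates, start + L, len(seq), start + L, best_pre)
    chain_res = assemble(best_pre, best_post)
    numbers = list(range(1, len(seq) + 1))
    substrate = ChainModel(
        chain_id="B", residues=_residues_from_atoms(chain_res, seq, numbers)
    )
    ref_pos = np.array(extra["ref_point"])
    inward = []
    for k in range(start, start + L):
        res = substrate.residues[k]
        if res.cb is None:
            continue
        if np.linalg.norm(res.cb - ref_pos) < np.linalg.norm(res.ca - ref_pos):
            inward.append(res.author_number)
    strand_numbers = numbers[start : start + L]
    positions = {num: k + 1 for k, num in enumerate(strand_numbers)}
    parities = {positions[num] % 2 for num in inward}
    truth = {
        "kind": "capture",
        "interval": [strand_numbers[0], strand_numbers[-1]],
        "strand_sequence": seq[start : start + L],
        "inward_residues": inward,
        "inward_parity": (
            "odd" if parities == {1} else "even" if parities == {0} else "mixed"
        ),
        "spacing": spec.inter_strand_spacing,
        "orientation": spec.orientation,
        **extra,
    }
    return ComplexFixture(receptor=receptor, substrate=substrate, truth=truth)


def build_decoy_complex(
    spec: SheetSpec | None = None, near_anchor: str | None = None
) -> ComplexFixture:
    """Complex with no capture: the substrate folds as an alpha helix.

    By default the helix is docked >= 8 A from both anchors.  With
    ``near_anchor='A'`` (or 'B') the helix is brought within the capture
    cutoff of that anchor only, exercising the both-anchors requirement.
    """
    spec = spec or SheetSpec()
    seq, _ = _default_sequence(spec)
    helix = geom.build_backbone([(geom.PHI_HELIX, geom.PSI_HELIX)] * len(seq))
    centroid = np.array([r["CA"] for r in helix]).mean(axis=0)
    helix = geom.transform(helix, np.eye(3), -centroid)
    capture = build_capture_complex(spec)
    receptor = capture.receptor
    anchors = {
        "A": np.array(
            [r.ca for r in receptor.residues if r.aa != REF_AA and r.author_number < spec.anchor_b_start]
        ),
        "B": np.array(
            [
                r.ca
                for r in receptor.residues
                if spec.anchor_b_start <= r.author_number < spec.ref_number
            ]
        ),
    }

    def min_dists(res_list: list[dict]) -> dict[str, float]:
        cas = np.array([r["CA"] for r in res_list])
        return {k: float(cdist(cas, v).min()) for k, v in anchors.items()}

    if near_anchor is None:
        placed = geom.transform(helix, np.eye(3), np.array([0.0, 0.0, 20.0]))
        d = min_dists(placed)
        step = 0
        while min(d.values()) < 8.0 and step < 50:
            placed = geom.transform(placed, np.eye(3), np.array([0.0, 0.0, 2.0]))
            d = min_dists(placed)
            step += 1
    else:
        side = -1.0 if near_anchor == "A" else 1.0
        other = "B" if near_anchor == "A" else "A"
        placed = None
        for y in np.arange(6.0, 30.0, 0.1):
            cand = geom.transform(
                helix, np.eye(3), np.array([0.0, side * y, 0.0])
            )
            d = min_dists(cand)
            if 4.0 < d[near_anchor] < 5.4 and d[other] > 8.0:
                placed = cand
                break
        if placed is None:
            raise RuntimeError("could not place near-anchor decoy helix")
    substrate = ChainModel(
        chain_id="B",
        residues=_residues_from_atoms(placed, seq, list(range(1, len(seq) + 1))),
    )
    truth = {"kind": "decoy", "interval": None, "near_anchor": near_anchor}
    return ComplexFixture(receptor=receptor, substrate=substrate, truth=truth)


def build_monomer(sequence: str, plddt: float | np.ndarray = DEFAULT_PLDDT) -> ChainModel:
    """Receptor-free substrate monomer (extended backbone) with pLDDT."""
    res = geom.build_backbone(
        [(geom.PHI_STRAND, geom.PSI_STRAND)] * len(sequence)
    )
    return ChainModel(
        chain_id="B",
        residues=_residues_from_atoms(
            res, sequence, list(range(1, len(sequence) + 1)), plddt
        ),
    )


def plant_plddt(
    monomer: ChainModel,
    interval: tuple[int, int],
    in_region: tuple[float, float],
    elsewhere: tuple[float, float],
    seed: int = 0,
) -> ChainModel:
    """Replace pLDDT by draws from two normals, clipped to [0, 100].

    Residues inside ``interval`` (inclusive author numbers) draw from
    ``in_region`` = (mean, sd); the rest from ``elsewhere``.
    """
    lo, hi = interval
    numbers = monomer.numbers()
    if not set(range(lo, hi + 1)) <= set(numbers):
        raise ValueError(f"interval {interval} outside chain numbering")
    rng = np.random.default_rng(seed)
    new_res = []
    for r in monomer.residues:
        mean, sd = in_region if lo <= r.author_number <= hi else elsewhere
        score = float(np.clip(rng.normal(mean, sd), 0.0, 100.0))
        new_res.append(
            ResidueRecord(
                author_number=r.author_number,
                aa=r.aa,
                atoms=dict(r.atoms),
                plddt=score,
            )
        )
    return ChainModel(chain_id=monomer.chain_id, residues=new_res)


# ---------------------------------------------------------------------------
# screen simulation


def shift_distribution(p: np.ndarray, delta: float) -> np.ndarray:
    """Move probability mass ``delta`` bins along the axis, exactly.

    A fractional shift interpolates the two neighbouring integer shifts,
    so the expected bin index changes by exactly ``delta``.  Mass that
    would leave bins 1..6 makes the shift infeasible (error).
    """
    p = np.asarray(p, dtype=float)

    def int_shift(k: int) -> np.ndarray:
        out = np.zeros_like(p)
        for i, mass in enumerate(p):
            if mass == 0:
                continue
            j = i + k
            if j < 0 or j >= p.size:
                raise ValueError(
                    f"shift {delta} infeasible: mass would leave bins 1..{p.size}"
                )
            out[j] = mass
        return out

    k = int(np.floor(delta))
    f = delta - k
    if f == 0:
        return int_shift(k)
    return (1.0 - f) * int_shift(k) + f * int_shift(k + 1)


def simulate_screen(spec: ScreenSimSpec | None = None) -> tuple[pd.DataFrame, dict[str, float]]:
    """Simulated long-format screen counts plus the planted effect map.

    The generator mirrors the two stages of a GPS sort-and-sequence
    screen.  (1) *Cells*: each gene's control bin distribution is the
    baseline shifted down by a gene-specific stability offset; offsets
    are drawn from an end-weighted mixture over ``[-stability_spread, 0]``
    chosen so the pooled control occupancy of the six bins is uniform,
    as FACS gating enforces in the real experiment.  The treatment
    distribution is the control shifted along the bin axis by the gene's
    planted dPSI (restricted to what the bins make feasible), so the
    expected PSI difference equals the planted effect exactly.
    (2) *Sequencing*: each bin is sequenced as its own sample to a fixed
    depth (``reads_per_gene * n_genes / 6``, scaled by the optional
    per-bin ``depth_factors``), drawing reads multinomially from the
    bin's cell composition.  Depth normalization is then exactly the
    correction the data need.
    """
    spec = spec or ScreenSimSpec()
    rng = np.random.default_rng(spec.seed)
    baseline = np.asarray(spec.baseline, dtype=float)
    support = np.nonzero(baseline > 0)[0]
    headroom_down = float(support[0])  # bins below the lowest occupied bin
    headroom_up = float(5 - support[-1])
    genes = [f"gene_{k:05d}" for k in range(spec.n_genes)]
    effects = {g: float(spec.effects.get(g, 0.0)) for g in genes}
    unknown = set(spec.effects) - set(genes)
    if unknown:
        raise ValueError(f"effects for unknown genes: {sorted(unknown)[:3]}")
    # gating-exact offset mixture: atoms at the interval ends restore the
    # half-weight edge bins of a uniform mixture of two-bin distributions
    spread = min(spec.stability_spread, headroom_down)
    cells = {"control": np.empty((spec.n_genes, 6)), "treatment": np.empty((spec.n_genes, 6))}
    for gi, g in enumerate(genes):
        e = effects[g]
        r = rng.random()
        if r < 1.0 / 12.0:
            u = 0.0
        elif r < 2.0 / 12.0:
            u = -spread
        else:
            u = rng.uniform(-spread, 0.0)
        # the two fractional shifts compose through their floors, so the
        # offset bound must leave room for one extra bin of spillover
        u_lo = -headroom_down - float(np.floor(min(e, 0.0)))
        u_hi = min(0.0, headroom_up - float(np.ceil(max(e, 0.0))))
        u = float(np.clip(u, u_lo, u_hi))
        q_control = shift_distribution(baseline, u)
        cells["control"][gi] = q_control
        cells["treatment"][gi] = shift_distribution(q_control, e)
    factors = (
        np.ones(6)
        if spec.depth_factors is None
        else np.asarray(spec.depth_factors, dtype=float)
    )
    bin_depth = np.round(spec.reads_per_gene * spec.n_genes / 6.0 * factors).astype(int)
    rows = []
    for condition in ("control", "treatment"):
        m = cells[condition]
        for b in range(6):
            column = m[:, b]
            total = column.sum()
            counts = (
                rng.multinomial(bin_depth[b], column / total)
                if total > 0
                else np.zeros(spec.n_genes, dtype=int)
            )
            for gi, g in enumerate(genes):
                rows.append(
                    {
                        "gene": g,
                        "barcode": f"{g}_bc1",
                        "condition": condition,
                        "bin": b + 1,
                        "reads": int(counts[gi]),
                    }
                )
    return pd.DataFrame(rows), effects


def write_model_set(
    directory: str,
    spec: SheetSpec,
    n_models: int = 3,
    n_capturing: int = 1,
) -> dict:
    """Write a ranked model set; the first ``n_capturing`` ranks capture.

    Non-capturing ranks are decoys.  Returns the capture ground truth.
    """
    os.makedirs(directory, exist_ok=True)
    truth: dict = {}
    for rank in range(n_models):
        fixture = (
            build_capture_complex(spec)
            if rank < n_capturing
            else build_decoy_complex(spec)
        )
        fixture.write(os.path.join(directory, f"ranked_{rank}.pdb"))
        if rank == 0:
            truth = fixture.truth
    return truth


def receptor_reference_sequence(spec: SheetSpec | None = None) -> str:
    """The synthetic receptor's sequence, for role assignment."""
    return ANCHOR_A_SEQ + ANCHOR_B_SEQ + REF_AA
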