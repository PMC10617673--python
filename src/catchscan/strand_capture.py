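"""Detection of substrate beta strands captured between receptor anchors.

The receptor's Catch domain presents two anchor beta strands (default
author-number ranges 148-157 and 279-286).  A substrate region counts as
captured when a run of consecutive substrate residues lies within a
distance cutoff (default 5.5 A, Calpha-Calpha) of BOTH anchor ranges and
carries extended ("E") secondary structure.  The surviving seed set is
expanded by a fixed pad (default 7 residues) each way, re-intersected
with "E", and the longest contiguous E stretch is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .secondary_structure import (
    SecondaryStructureString,
    assign_secondary_structure,
    propagate_terminal_E,
)
from .structure_io import ChainModel, ComplexModel, StructureError


@dataclass
class CaptureParams:
    """Geometric and sequence parameters of the capture rule."""

    anchor_a: tuple[int, int] = (148, 157)
    anchor_b: tuple[int, int] = (279, 286)
    cutoff: float = 5.5  # Angstrom
    pad: int = 7  # residues of expansion each direction
    min_run: int = 2  # minimum consecutive seed residues

    def __post_init__(self) -> None:
        if self.cutoff < 0:
            raise ValueError("cutoff must be non-negative")
        if self.pad < 0:
            raise ValueError("pad must be non-negative")
        a, b = sorted([self.anchor_a, self.anchor_b])
        if a[1] >= b[0]:
            raise ValueError("anchor ranges must not overlap")


@dataclass
class DistanceMatrix:
    """Substrate x receptor pairwise distances in Angstrom."""

    values: np.ndarray  # shape (n_substrate, n_receptor)
    substrate_numbers: list[int]
    receptor_numbers: list[int]
    atom_kind: str = "CA"


@dataclass
class CapturedStrand:
    """A contiguous substrate interval called as Catch-bound."""

    start: int  # inclusive author numbers
    end: int
    residues: str  # one-letter sequence of the interval
    model_rank: int = 0
    per_residue_ss: str = ""

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class CaptureResult:
    """Aggregate of capture calls over a ranked model set."""

    captured: bool
    representative: CapturedStrand | None
    per_model: list[CapturedStrand | None] = field(default_factory=list)


def calpha_distance_matrix(
    substrate: ChainModel, receptor: ChainModel
) -> DistanceMatrix:
    """Euclidean Calpha-Calpha distance matrix, substrate rows x receptor columns."""
    if len(substrate) == 0 or len(receptor) == 0:
        raise StructureError("empty chain in distance computation")
    d = cdist(substrate.ca_coords(), receptor.ca_coords())
    return DistanceMatrix(
        values=d,
        substrate_numbers=substrate.numbers(),
        receptor_numbers=receptor.numbers(),
        atom_kind="CA",
    )


def _anchor_columns(
    D: DistanceMatrix, anchor: tuple[int, int]
) -> np.ndarray:
    cols = [
        k
        for k, num in enumerate(D.receptor_numbers)
        if anchor[0] <= num <= anchor[1]
    ]
    if not cols:
        raise StructureError(
            f"anchor range {anchor[0]}-{anchor[1]} absent from receptor chain"
        )
    return np.array(cols)


def find_seed_residues(
    D: DistanceMatrix, params: CaptureParams
) -> set[int]:
    """Substrate residues within cutoff of BOTH anchor ranges, in runs.

    A residue qualifies when its minimum distance to each anchor range is
    below the cutoff; only maximal consecutive runs of author numbers of
    length >= min_run are kept.
    """
    cols_a = _anchor_columns(D, params.anchor_a)
    cols_b = _anchor_columns(D, params.anchor_b)
    min_a = D.values[:, cols_a].min(axis=1)
    min_b = D.values[:, cols_b].min(axis=1)
    qualifies = (min_a < params.cutoff) & (min_b < params.cutoff)
    seeds: set[int] = set()
    run: list[int] = []
    numbers = D.substrate_numbers
    for idx, num in enumerate(numbers):
        if qualifies[idx] and (not run or num == run[-1] + 1):
            run.append(num)
            continue
        if len(run) >= params.min_run:
            seeds.update(run)
        run = [num] if qualifies[idx] else []
    if len(run) >= params.min_run:
        seeds.update(run)
    return seeds


def _longest_e_stretch(
    candidates: set[int], e_numbers: set[int]
) -> tuple[int, int] | None:
    """Longest contiguous E run within candidates; N-terminal tie-break."""
    keep = sorted(candidates & e_numbers)
    if not keep:
        return None
    best: tuple[int, int] | None = None
    start = keep[0]
    prev = keep[0]
    for num in keep[1:] + [None]:  # type: ignore[list-item]
        if num is not None and num == prev + 1:
            prev = num
            continue
        if best is None or (prev - start) > (best[1] - best[0]):
            best = (start, prev)
        if num is not None:
            start = prev = num
    return best


def refine_expand_trim(
    seeds: set[int],
    ss: SecondaryStructureString | str,
    substrate: ChainModel,
    params: CaptureParams,
) -> CapturedStrand | None:
    """Apply the E-filter, pad expansion, and longest-stretch rule.

    Steps: (1) keep seeds that are E-coded; (2) expand the survivors by
    ``pad`` positions each direction (sequence space, clipped to chain
    bounds) and keep the E-coded ones; (3) return the longest contiguous
    E stretch, preferring the most N-terminal on ties.  ``ss`` must be
    terminal-propagated already.
    """
    codes = str(ss)
    numbers = substrate.numbers()
    if len(codes) != len(numbers):
        raise ValueError("secondary-structure string does not match chain")
    e_numbers = {num for num, c in zip(numbers, codes) if c == "E"}
    step1 = seeds & e_numbers
    if not step1:
        return None
    number_set = set(numbers)
    expanded: set[int] = set()
    for num in step1:
        expanded.update(
            n
            for n in range(num - params.pad, num + params.pad + 1)
            if n in number_set
        )
    interval = _longest_e_stretch(expanded, e_numbers)
    if interval is None:
        return None
    start, end = interval
    index = {num: k for k, num in enumerate(numbers)}
    seq = "".join(substrate.residues[index[n]].aa for n in range(start, end + 1))
    ss_str = "".join(codes[index[n]] for n in range(start, end + 1))
    return CapturedStrand(start=start, end=end, residues=seq, per_residue_ss=ss_str)


def detect_captured_strand(
    model: ComplexModel, params: CaptureParams | None = None
) -> CapturedStrand | None:
    """Full single-model detection: distance seeds + E-filtering."""
    params = params or CaptureParams()
    if len(model.substrate) == 0:
        raise StructureError("substrate chain is empty")
    D = calpha_distance_matrix(model.substrate, model.receptor)
    seeds = find_seed_residues(D, params)
    if not seeds:
        return None
    ss = assign_secondary_structure([model.receptor, model.substrate])[
        model.substrate.chain_id
    ]
    ss = propagate_terminal_E(ss)
    strand = refine_expand_trim(seeds, ss, model.substrate, params)
    if strand is not None:
        strand.model_rank = model.rank
    return strand


def aggregate_models(
    models: list[ComplexModel], params: CaptureParams | None = None
) -> CaptureResult:
    """Capture call over a ranked model set.

    A substrate is captured iff any model yields a strand; the
    representative interval comes from the best (lowest) qualifying rank.
    Per-model results are retained for cohort statistics.
    """
    if not models:
        raise ValueError("no models supplied")
    params = params or CaptureParams()
    per_model = [detect_captured_strand(m, params) for m in models]
    qualifying = [
        (m.rank, s) for m, s in zip(models, per_model) if s is not None
    ]
    if not qualifying:
        return CaptureResult(False, None, per_model)
    qualifying.sort(key=lambda t: t[0])
    return CaptureResult(True, qualifying[0][1], per_model)
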