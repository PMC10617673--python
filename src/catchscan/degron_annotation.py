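"""Annotation and cohort statistics for captured beta-strand degrons.

Covers four analyses over a cohort of captured strands:

* inward/outward facing of strand side chains relative to the receptor
  core (Cbeta-vs-Calpha distance to a reference receptor residue,
  reconciled to strict odd/even alternation along the strand);
* positional amino-acid enrichment going into the strand from each
  terminus, against the background composition of the substrate cohort;
* hydrophobicity contrast of the strand versus the rest of the substrate
  (paired t-test on per-substrate means);
* pLDDT disorder contrast of the captured region versus the rest of the
  substrate in receptor-free monomer models (paired t-test; lower pLDDT
  approximates disorder).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sstats

from .strand_capture import CapturedStrand
from .structure_io import ChainModel, ComplexModel, StructureError

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Normalized hydrophobicity index at pH 7 (Monera & Hodges scale);
# dimensionless, 100 = most hydrophobic.  Injectable wherever used.
HYDROPHOBICITY_PH7: dict[str, float] = {
    "F": 100.0, "I": 99.0, "W": 97.0, "L": 97.0, "V": 76.0,
    "M": 74.0, "Y": 63.0, "C": 49.0, "A": 41.0, "T": 13.0,
    "H": 8.0, "G": 0.0, "S": -5.0, "Q": -10.0, "R": -14.0,
    "K": -23.0, "N": -28.0, "E": -31.0, "P": -46.0, "D": -55.0,
}


@dataclass
class FacingAnnotation:
    """Inward/outward partition of a strand's residue numbers."""

    inward: set[int]
    outward: set[int]
    parity: str  # 'odd' or 'even' (1-based position within strand, N->C)


@dataclass
class ContrastResult:
    """Paired-means contrast over a substrate cohort."""

    n: int
    mean_in: float  # mean of in-region per-substrate means
    mean_out: float
    mean_difference: float  # in-region minus out-of-region
    t: float
    p: float
    dropped: int = 0


def paired_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided paired Student t-test from the closed form.

    t = mean(d) / (sd(d)/sqrt(n)) with d = a - b and df = n - 1.  All
    differences zero yields t = 0, p = 1; zero spread with a nonzero mean
    yields |t| = inf, p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and equal length")
    n = a.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = a - b
    md = d.mean()
    sd = d.std(ddof=1)
    if sd == 0.0:
        if md == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, md), 0.0
    t = md / (sd / math.sqrt(n))
    p = 2.0 * _sstats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def assign_facing(
    strand: CapturedStrand,
    model: ComplexModel,
    ref_residue: int = 309,
) -> FacingAnnotation:
    """Annotate strand residues as receptor-facing (inward) or outward.

    A residue is raw-called inward when its Cbeta lies strictly closer
    than its Calpha to the Calpha of the receptor reference residue
    (default isoleucine 309, approximating the Catch-domain core).
    Glycine has no Cbeta and is skipped in raw calling.  The raw calls
    are then reconciled to the odd or the even position set, whichever
    they overlap more.
    """
    try:
        ref = model.receptor.residue_by_number(ref_residue)
    except KeyError:
        raise StructureError(
            f"reference residue {ref_residue} absent from receptor"
        ) from None
    ref_ca = ref.ca
    raw_inward: set[int] = set()
    index = {r.author_number: r for r in model.substrate.residues}
    for num in range(strand.start, strand.end + 1):
        res = index[num]
        if res.cb is None:
            continue
        if np.linalg.norm(res.cb - ref_ca) < np.linalg.norm(res.ca - ref_ca):
            raw_inward.add(num)
    return reconcile_parity(raw_inward, strand)


def reconcile_parity(
    raw_inward: set[int], strand: CapturedStrand
) -> FacingAnnotation:
    """Snap raw inward calls to the better-matching odd or even set.

    Positions are 1-based within the strand, N to C.  The inward set
    becomes the full winning parity class; an exact tie is an error
    prompting an explicit parity override.
    """
    if len(strand) < 2:
        raise ValueError("parity reconciliation needs a strand of length >= 2")
    numbers = list(range(strand.start, strand.end + 1))
    odd = {num for k, num in enumerate(numbers, start=1) if k % 2 == 1}
    even = set(numbers) - odd
    n_odd = len(raw_inward & odd)
    n_even = len(raw_inward & even)
    if n_odd == n_even:
        raise ValueError(
            "facing parity tie (odd and even sets match the raw inward "
            "calls equally well); pass --parity to override"
        )
    if n_odd > n_even:
        return FacingAnnotation(inward=odd, outward=even, parity="odd")
    return FacingAnnotation(inward=even, outward=odd, parity="even")


def background_frequencies(sequences: list[str]) -> dict[str, float]:
    """Amino-acid composition pooled over the given sequences."""
    counts = {aa: 0 for aa in AMINO_ACIDS}
    total = 0
    for seq in sequences:
        for aa in seq:
            if aa in counts:
                counts[aa] += 1
                total += 1
    if total == 0:
        raise ValueError("no standard amino acids in background sequences")
    return {aa: c / total for aa, c in counts.items()}


def positional_enrichment(
    strands: list[CapturedStrand],
    background: dict[str, float],
    max_depth: int | None = None,
) -> pd.DataFrame:
    """Positional amino-acid enrichment going into the strands.

    For depth ``n`` from either terminus, only strands of length >= 2n
    contribute (each residue counted once across the two sides).  The
    observed frequency at each (side, depth) is divided by the background
    frequency.  Returns a tidy frame with columns side ('N' or 'C'),
    depth, aa, observed, ratio.
    """
    if not strands:
        raise ValueError("empty strand cohort")
    bg_total = sum(background.get(aa, 0.0) for aa in AMINO_ACIDS)
    if not math.isclose(bg_total, 1.0, abs_tol=1e-6):
        raise ValueError("background frequencies must sum to 1")
    if max_depth is None:
        max_depth = max(len(s) for s in strands) // 2
    rows = []
    for side in ("N", "C"):
        for depth in range(1, max_depth + 1):
            eligible = [s for s in strands if len(s) >= 2 * depth]
            if not eligible:
                continue
            observed = {aa: 0 for aa in AMINO_ACIDS}
            for s in eligible:
                aa = (
                    s.residues[depth - 1]
                    if side == "N"
                    else s.residues[len(s) - depth]
                )
                if aa in observed:
                    observed[aa] += 1
            total = sum(observed.values())
            for aa in AMINO_ACIDS:
                freq = observed[aa] / total if total else 0.0
                bg = background.get(aa, 0.0)
                if bg == 0.0 and freq > 0.0:
                    warnings.warn(
                        f"background frequency 0 for observed residue {aa}",
                        stacklevel=2,
                    )
                    ratio = math.inf
                else:
                    ratio = freq / bg if bg > 0 else 0.0
                rows.append(
                    {
                        "side": side,
                        "depth": depth,
                        "aa": aa,
                        "observed": freq,
                        "ratio": ratio,
                    }
                )
    return pd.DataFrame(rows)


def flanking_frequencies(
    substrates: list[tuple[str, CapturedStrand, int]],
    background: dict[str, float],
) -> pd.DataFrame:
    """Composition of the residues immediately flanking the strands.

    Each cohort entry is (full substrate sequence, strand, sequence
    offset of the first residue, i.e. the author number of sequence
    position 0).  A strand starting at the protein N terminus has no
    preceding flank and one ending at the C terminus no following flank.
    Returns columns side ('preceding' or 'following'), aa, observed,
    ratio.
    """
    rows = []
    for side in ("preceding", "following"):
        observed = {aa: 0 for aa in AMINO_ACIDS}
        for seq, strand, offset in substrates:
            pos = (
                strand.start - offset - 1
                if side == "preceding"
                else strand.end - offset + 1
            )
            if 0 <= pos < len(seq) and seq[pos] in observed:
                observed[seq[pos]] += 1
        total = sum(observed.values())
        for aa in AMINO_ACIDS:
            freq = observed[aa] / total if total else 0.0
            bg = background.get(aa, 0.0)
            ratio = freq / bg if bg > 0 else (math.inf if freq > 0 else 0.0)
            rows.append(
                {"side": side, "aa": aa, "observed": freq, "ratio": ratio}
            )
    return pd.DataFrame(rows)


def hydrophobicity_contrast(
    substrates: list[tuple[str, CapturedStrand, int]],
    scale: dict[str, float] | None = None,
) -> ContrastResult:
    """Strand-vs-rest hydrophobicity, paired across substrates.

    Each entry pairs the mean scale value over the strand residues with
    the mean over the rest of that substrate's sequence; a two-sided
    paired t-test summarizes the cohort.
    """
    scale = scale if scale is not None else HYDROPHOBICITY_PH7
    in_means, out_means = [], []
    for seq, strand, offset in substrates:
        lo = strand.start - offset
        hi = strand.end - offset
        if lo < 0 or hi >= len(seq):
            raise ValueError("strand interval outside substrate sequence")
        strand_vals = [scale[aa] for aa in seq[lo : hi + 1] if aa in scale]
        rest = seq[:lo] + seq[hi + 1 :]
        rest_vals = [scale[aa] for aa in rest if aa in scale]
        if not strand_vals or not rest_vals:
            raise ValueError("substrate with empty strand or complement")
        in_means.append(float(np.mean(strand_vals)))
        out_means.append(float(np.mean(rest_vals)))
    t, p = paired_ttest(np.array(in_means), np.array(out_means))
    return ContrastResult(
        n=len(in_means),
        mean_in=float(np.mean(in_means)),
        mean_out=float(np.mean(out_means)),
        mean_difference=float(np.mean(in_means) - np.mean(out_means)),
        t=t,
        p=p,
    )


def plddt_contrast(
    monomers: list[ChainModel],
    intervals: list[tuple[int, int]],
) -> ContrastResult:
    """Captured-region vs rest pLDDT in receptor-free monomers.

    Pairs the mean pLDDT over each captured interval with the mean over
    the rest of the same monomer; a negative mean difference means the
    captured region is predicted less confidently (more disordered).
    Monomers whose numbering cannot resolve the interval are dropped
    with a warning and counted.
    """
    in_means, out_means = [], []
    dropped = 0
    for chain, (start, end) in zip(monomers, intervals):
        numbers = chain.numbers()
        inside = [
            r.plddt for r in chain.residues if start <= r.author_number <= end
        ]
        outside = [
            r.plddt
            for r in chain.residues
            if not (start <= r.author_number <= end)
        ]
        covered = set(range(start, end + 1)) <= set(numbers)
        if not covered or not inside or not outside:
            dropped += 1
            logger.warning(
                "monomer %s: interval %d-%d not resolvable; dropped",
                chain.chain_id,
                start,
                end,
            )
            continue
        in_means.append(float(np.mean(inside)))
        out_means.append(float(np.mean(outside)))
    t, p = paired_ttest(np.array(in_means), np.array(out_means))
    return ContrastResult(
        n=len(in_means),
        mean_in=float(np.mean(in_means)),
        mean_out=float(np.mean(out_means)),
        mean_difference=float(np.mean(in_means) - np.mean(out_means)),
        t=t,
        p=p,
        dropped=dropped,
    )
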