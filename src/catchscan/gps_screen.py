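"""Protein stability index (PSI) analysis of 6-bin GPS screen counts.

A GPS (Global Protein Stability) screen sorts a barcoded ORF library
into six FACS bins by GFP/DsRed ratio, from bin 1 (most unstable) to
bin 6 (most stable), for a control and a treatment condition.  After
per-bin sequencing-depth correction, each ORF's stability is summarized
as

    PSI = sum_{i=1..6} R_i * i

with R_i the ORF's read proportion in bin i; the treatment-minus-control
difference is dPSI, and ORFs with dPSI strictly below a threshold
(default -0.5) are called destabilized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_BINS = 6
BIN_WEIGHTS = np.arange(1, N_BINS + 1, dtype=float)
DEFAULT_THRESHOLD = -0.5


def depth_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each bin column to the mean library size.

    Rows are ORFs/genes, columns stability bins.  Column sums are
    equalized (total-count normalization) so read proportions are
    comparable across bins; within-bin composition is preserved.  A bin
    with zero total reads is an error naming the bin.
    """
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero) > 0:
        raise ValueError(
            f"bin(s) with zero total reads: {list(zero.index)}"
        )
    target = float(totals.mean())
    return counts * (target / totals)


def compute_psi(R: np.ndarray) -> float:
    """PSI of one read-proportion vector over bins 1..6."""
    R = np.asarray(R, dtype=float)
    if R.shape != (N_BINS,):
        raise ValueError(f"expected a {N_BINS}-vector of proportions")
    if (R < 0).any():
        raise ValueError("proportions must be non-negative")
    if abs(R.sum() - 1.0) > 1e-6:
        raise ValueError(f"proportions sum to {R.sum()}, not 1")
    return float(R @ BIN_WEIGHTS)


def delta_psi(psi_treatment: float, psi_control: float) -> float:
    """Treatment-minus-control PSI difference."""
    return psi_treatment - psi_control


@dataclass
class ScreenTable:
    """Per-gene 6-bin counts for a control and a treatment condition.

    Constructed from a long-format counts table (gene, barcode,
    condition, bin, reads); counts of multiple barcodes of one gene are
    summed before proportions are taken.
    """

    control: pd.DataFrame  # gene x bin raw counts
    treatment: pd.DataFrame

    CONTROL = "control"
    TREATMENT = "treatment"

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "ScreenTable":
        required = {"gene", "condition", "bin", "reads"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"counts table lacks columns {sorted(missing)}")
        mats = {}
        for cond in (cls.CONTROL, cls.TREATMENT):
            sub = df[df["condition"] == cond]
            mat = (
                sub.groupby(["gene", "bin"])["reads"]
                .sum()
                .unstack("bin", fill_value=0)
                .reindex(columns=range(1, N_BINS + 1), fill_value=0)
            )
            mats[cond] = mat.astype(float)
        genes = mats[cls.CONTROL].index.union(mats[cls.TREATMENT].index)
        return cls(
            control=mats[cls.CONTROL].reindex(genes, fill_value=0.0),
            treatment=mats[cls.TREATMENT].reindex(genes, fill_value=0.0),
        )

    def psi_table(self, normalize: bool = True) -> pd.DataFrame:
        """Per-gene PSI for both conditions and dPSI.

        Depth normalization precedes proportion computation.  Genes with
        zero total reads in a condition get a missing PSI and are
        excluded from filtering (their count is logged).
        """
        out = {}
        for name, mat in (("control", self.control), ("treatment", self.treatment)):
            m = depth_normalize(mat) if normalize else mat
            totals = m.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                props = m.div(totals, axis=0)
            psi = props @ BIN_WEIGHTS
            psi[totals == 0] = np.nan
            n_missing = int((totals == 0).sum())
            if n_missing:
                logger.warning(
                    "%d gene(s) with zero reads in %s; PSI set missing",
                    n_missing,
                    name,
                )
            out[f"psi_{name}"] = psi
        table = pd.DataFrame(out)
        table["delta_psi"] = table["psi_treatment"] - table["psi_control"]
        return table


def filter_destabilized(
    psi: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD
) -> list[str]:
    """Genes with dPSI strictly below the threshold, most destabilized first.

    ``psi`` is the frame returned by :meth:`ScreenTable.psi_table`;
    genes with a missing dPSI are excluded.
    """
    ok = psi.dropna(subset=["delta_psi"])
    hits = ok[ok["delta_psi"] < threshold].sort_values(
        ["delta_psi", "psi_control"], kind="mergesort"
    )
    return list(hits.index)
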