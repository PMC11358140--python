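"""Natural-abundance correction and summaries for 13C isotopologue tracing.

A compound with k carbons is measured as an isotopologue vector
(M+0, ..., M+k). Naturally occurring 13C smears a true labeling distribution
x upward in mass: each unlabeled carbon is independently heavy with
probability p13C, so the observed vector is M = C x where C is a
lower-triangular matrix whose column i is the binomial(k - i, p13C) kernel
shifted to start at row i. Correction inverts this convolution exactly by
forward substitution; small negative entries (measurement noise) are clipped
to zero and the vector renormalized, with the clipped mass reported.

The polyamine pathway map encodes how many tracer carbons each product
inherits from U-13C-arginine (6 carbons): ornithine keeps 5 after urea loss,
putrescine 4 after decarboxylation, and spermidine and N-acetyl-spermidine
keep those same 4 backbone carbons (the aminopropyl and acetyl additions are
unlabeled).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.stats import binom

#: Default 13C natural abundance (fraction of carbon atoms).
P13C_NATURAL = 0.0107


@dataclass(frozen=True)
class CorrectionMatrix:
    matrix: np.ndarray
    k: int
    p13c: float


@dataclass(frozen=True)
class CorrectedVector:
    corrected: np.ndarray
    clipped_mass: float


@dataclass(frozen=True)
class PathwayStep:
    """Provenance of a pathway product: its precursor and how many tracer
    carbons it inherits."""

    precursor: str | None
    carbons_inherited: int


#: U-13C-arginine tracing chain through polyamine synthesis.
POLYAMINE_PATHWAY: dict[str, PathwayStep] = {
    "arginine": PathwayStep(None, 6),
    "ornithine": PathwayStep("arginine", 5),
    "putrescine": PathwayStep("ornithine", 4),
    "spermidine": PathwayStep("putrescine", 4),
    "n-acetyl-spermidine": PathwayStep("spermidine", 4),
}


def build_correction_matrix(k: int, p13c: float = P13C_NATURAL) -> CorrectionMatrix:
    """Lower-triangular convolution matrix mapping true -> observed vectors."""
    if k < 1:
        raise ValueError("carbon count k must be >= 1")
    if not 0 <= p13c < 0.5:
        raise ValueError("p13c must lie in [0, 0.5)")
    C = np.zeros((k + 1, k + 1))
    for i in range(k + 1):
        C[i:, i] = binom.pmf(np.arange(k - i + 1), k - i, p13c)
    return CorrectionMatrix(matrix=C, k=k, p13c=p13c)


def convolve_natural_abundance(x: Sequence[float], matrix: CorrectionMatrix) -> np.ndarray:
    """Forward model: apply the natural-abundance kernel to a true vector."""
    x = np.asarray(x, dtype=float)
    if x.shape != (matrix.k + 1,):
        raise ValueError("vector length does not match correction matrix")
    return matrix.matrix @ x


def correct_distribution(measured: Sequence[float], matrix: CorrectionMatrix) -> CorrectedVector:
    """Invert the natural-abundance convolution for one measured vector.

    Solves C x = M by forward substitution, clips negative entries to zero,
    and renormalizes to unit sum. Returns the corrected vector together with
    the total clipped (negative) mass, a diagnostic for noisy inputs.
    """
    m = np.asarray(measured, dtype=float)
    if m.shape != (matrix.k + 1,):
        raise ValueError("vector length does not match correction matrix")
    if np.any(m < 0):
        raise ValueError("measured intensities must be nonnegative")
    x = solve_triangular(matrix.matrix, m, lower=True)
    clipped = float(-x[x < 0].sum())
    x = np.clip(x, 0.0, None)
    total = x.sum()
    if total <= 0:
        raise ValueError("corrected vector has no positive mass")
    return CorrectedVector(corrected=x / total, clipped_mass=clipped)


def total_signal_normalize(areas: pd.DataFrame) -> pd.DataFrame:
    """Normalize peak areas so each sample (column) sums to 1.

    Rows are compounds, columns samples; scale-invariant and idempotent.
    """
    totals = areas.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"sample(s) with no positive signal: {bad}")
    return areas / totals


@dataclass(frozen=True)
class LabelingSummary:
    compound: str
    mean_enrichment: float
    expected_shift: int
    expected_isotopologue_fraction: float


def fractional_labeling(
    corrected: Sequence[float],
    compound: str,
    pathway: Mapping[str, PathwayStep] = POLYAMINE_PATHWAY,
) -> LabelingSummary:
    """Summarize label propagation for one corrected vector.

    ``mean_enrichment`` is the average fraction of labeled carbons,
    sum_i x_i * i / k; the expected-isotopologue fraction is the corrected
    mass at the pathway-predicted shift (e.g. M+4 for putrescine from
    U-13C-arginine).
    """
    x = np.asarray(corrected, dtype=float)
    k = len(x) - 1
    if compound not in pathway:
        raise KeyError(f"compound {compound!r} absent from pathway map")
    step = pathway[compound]
    if step.carbons_inherited > k:
        raise ValueError(
            f"{compound!r} inherits {step.carbons_inherited} carbons but has only {k}"
        )
    enrichment = float(np.dot(x, np.arange(k + 1)) / k)
    return LabelingSummary(
        compound=compound,
        mean_enrichment=enrichment,
        expected_shift=step.carbons_inherited,
        expected_isotopologue_fraction=float(x[step.carbons_inherited]),
    )


def correct_table(table: pd.DataFrame, p13c: float = P13C_NATURAL) -> pd.DataFrame:
    """Correct every row of an isotopologue table.

    Expects columns ``compound``, ``carbons`` and ``M0..Mk`` intensities
    (extra M columns beyond a row's carbon count may be NaN). Returns the
    same layout with corrected fractions plus a ``clipped_mass`` column.
    """
    rows = []
    max_k = int(table["carbons"].max())
    for rec in table.itertuples(index=False):
        k = int(rec.carbons)
        measured = [getattr(rec, f"M{i}") for i in range(k + 1)]
        result = correct_distribution(measured, build_correction_matrix(k, p13c))
        row: dict[str, object] = {"compound": rec.compound, "carbons": k}
        for i in range(max_k + 1):
            row[f"M{i}"] = result.corrected[i] if i <= k else np.nan
        row["clipped_mass"] = result.clipped_mass
        rows.append(row)
    return pd.DataFrame(rows)


def labeling_summary_table(
    corrected: pd.DataFrame,
    pathway: Mapping[str, PathwayStep] = POLYAMINE_PATHWAY,
) -> pd.DataFrame:
    """Per-compound labeling summary for a corrected isotopologue table."""
    rows = []
    for rec in corrected.itertuples(index=False):
        k = int(rec.carbons)
        vec = [getattr(rec, f"M{i}") for i in range(k + 1)]
        summary = fractional_labeling(vec, str(rec.compound), pathway)
        rows.append(
            {
                "compound": summary.compound,
                "carbons": k,
                "mean_enrichment": summary.mean_enrichment,
                "expected_shift": summary.expected_shift,
                "expected_isotopologue_fraction": summary.expected_isotopologue_fraction,
            }
        )
    return pd.DataFrame(rows)
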