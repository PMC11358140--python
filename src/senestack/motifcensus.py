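"""Tripeptide-motif census over protein sets and a chi-square comparison.

eIF5A relieves ribosome stalling at tripeptide motifs rich in proline,
glycine, and charged residues. This module counts qualifying tripeptides per
protein with a sliding window (stride 1, overlaps counted), bins the
per-protein counts, and compares two protein sets' binned distributions with
a two-way homogeneity chi-square test (bins with small expected counts are
merged into neighbors first).

The motif definition is an input: either an explicit list of length-3
patterns or a residue-class rule counting windows whose three residues all
belong to a qualifying alphabet. The default rule alphabet
{P, G, D, E, K, R} is an explicit stand-in for published eIF5A motif
catalogs, not a reproduction of any specific list.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .synthdata import AMINO_ACIDS, QUALIFYING_RESIDUES

#: Default per-protein count bins: 0, 1-3, 4-6, 7-10, >10 motifs.
DEFAULT_BIN_EDGES = (0, 1, 4, 7, 11)


@dataclass(frozen=True)
class MotifSet:
    """Either an explicit tripeptide list or a residue-class rule."""

    patterns: frozenset[str] | None = None
    alphabet: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if (self.patterns is None) == (self.alphabet is None):
            raise ValueError("provide exactly one of patterns or alphabet")
        if self.patterns is not None:
            for p in self.patterns:
                if len(p) != 3 or any(c not in AMINO_ACIDS for c in p):
                    raise ValueError(f"invalid tripeptide pattern {p!r}")
        if self.alphabet is not None:
            for c in self.alphabet:
                if c not in AMINO_ACIDS:
                    raise ValueError(f"invalid residue {c!r} in rule alphabet")

    @classmethod
    def rule(cls, alphabet: str = QUALIFYING_RESIDUES) -> "MotifSet":
        return cls(alphabet=frozenset(alphabet.upper()))

    @classmethod
    def from_patterns(cls, patterns: Sequence[str]) -> "MotifSet":
        return cls(patterns=frozenset(p.upper() for p in patterns))

    @classmethod
    def from_file(cls, path: str | Path) -> "MotifSet":
        """One tripeptide per line; blank lines and '#' comments ignored."""
        patterns = [
            line.strip().upper()
            for line in Path(path).read_text().splitlines()
            if line.strip() and not line.startswith("#")
        ]
        return cls.from_patterns(patterns)


def count_motifs(sequence: str, motifs: MotifSet) -> int:
    """Qualifying tripeptide windows in a protein (stride 1, overlapping).

    Sequences shorter than 3 residues count 0 by convention.
    """
    seq = sequence.upper()
    invalid = set(seq) - set(AMINO_ACIDS)
    if invalid:
        raise ValueError(f"invalid residue(s) {sorted(invalid)} in sequence")
    if len(seq) < 3:
        return 0
    if motifs.alphabet is not None:
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        qual = np.isin(arr, np.frombuffer("".join(sorted(motifs.alphabet)).encode(), np.uint8))
        return int((qual[:-2] & qual[1:-1] & qual[2:]).sum())
    return sum(seq[i : i + 3] in motifs.patterns for i in range(len(seq) - 2))


def _bin_labels(edges: Sequence[int]) -> list[str]:
    labels = []
    for i, lo in enumerate(edges):
        hi = edges[i + 1] - 1 if i + 1 < len(edges) else None
        if hi is None:
            labels.append(f">{lo - 1}")
        elif hi == lo:
            labels.append(str(lo))
        else:
            labels.append(f"{lo}-{hi}")
    return labels


@dataclass
class MotifCensus:
    """Per-protein motif counts and binned distributions for two sets."""

    counts_a: pd.Series
    counts_b: pd.Series
    bin_edges: tuple[int, ...]
    bin_labels: list[str]
    binned_a: np.ndarray
    binned_b: np.ndarray

    @property
    def freq_a(self) -> np.ndarray:
        return self.binned_a / self.binned_a.sum()

    @property
    def freq_b(self) -> np.ndarray:
        return self.binned_b / self.binned_b.sum()


def census(
    set_a: Mapping[str, str],
    set_b: Mapping[str, str],
    motifs: MotifSet,
    bin_edges: Sequence[int] = DEFAULT_BIN_EDGES,
) -> MotifCensus:
    """Motif census of two protein sets with shared count bins."""
    if not set_a or not set_b:
        raise ValueError("both protein sets must be nonempty")
    edges = tuple(int(e) for e in bin_edges)
    if list(edges) != sorted(set(edges)):
        raise ValueError("bin edges must be strictly increasing")
    counts_a = pd.Series({name: count_motifs(seq, motifs) for name, seq in set_a.items()})
    counts_b = pd.Series({name: count_motifs(seq, motifs) for name, seq in set_b.items()})
    hist_edges = list(edges) + [np.inf]
    binned_a, _ = np.histogram(counts_a, bins=hist_edges)
    binned_b, _ = np.histogram(counts_b, bins=hist_edges)
    return MotifCensus(
        counts_a=counts_a,
        counts_b=counts_b,
        bin_edges=edges,
        bin_labels=_bin_labels(edges),
        binned_a=binned_a,
        binned_b=binned_b,
    )


@dataclass
class SetComparison:
    statistic: float
    df: int
    pvalue: float
    observed: np.ndarray  # 2 x bins after merging
    expected: np.ndarray
    bin_labels: list[str]


def chisq_homogeneity(
    obs_a: Sequence[float],
    obs_b: Sequence[float],
    labels: Sequence[str] | None = None,
    min_expected: float = 5.0,
) -> SetComparison:
    """Two-way homogeneity chi-square on binned counts, no continuity
    correction. Adjacent bins are merged (into the left neighbor where
    possible) until every expected cell reaches ``min_expected``."""
    a = np.asarray(obs_a, dtype=float)
    b = np.asarray(obs_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("observed vectors must be 1-D and of equal length")
    labels = list(labels) if labels is not None else [str(i) for i in range(len(a))]

    def expected_cells(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        table = np.vstack([a, b])
        return np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()

    while len(a) > 1:
        exp = expected_cells(a, b)
        bad = np.flatnonzero(exp.min(axis=0) < min_expected)
        if bad.size == 0:
            break
        j = int(bad[0])
        k = j - 1 if j > 0 else j + 1
        lo, hi = min(j, k), max(j, k)
        a[lo] += a[hi]
        b[lo] += b[hi]
        labels[lo] = f"{labels[lo]}+{labels[hi]}"
        a = np.delete(a, hi)
        b = np.delete(b, hi)
        del labels[hi]
    if len(a) < 2:
        raise ValueError("fewer than 2 bins after merging")

    table = np.vstack([a, b])
    if np.array_equal(a, b):
        # identical distributions: statistic is exactly 0
        return SetComparison(0.0, len(a) - 1, 1.0, table, expected_cells(a, b), labels)
    result = chi2_contingency(table, correction=False)
    return SetComparison(
        statistic=float(result.statistic),
        df=int(result.dof),
        pvalue=float(result.pvalue),
        observed=table,
        expected=result.expected_freq,
        bin_labels=labels,
    )


def compare_sets(cen: MotifCensus, min_expected: float = 5.0) -> SetComparison:
    """Chi-square comparison of the two binned motif-count distributions."""
    return chisq_homogeneity(
        cen.binned_a, cen.binned_b, labels=cen.bin_labels, min_expected=min_expected
    )


def census_table(cen: MotifCensus) -> pd.DataFrame:
    """Tidy per-protein table (set, protein, motifs)."""
    rows = [
        {"set": "A", "protein": name, "motifs": int(m)} for name, m in cen.counts_a.items()
    ] + [
        {"set": "B", "protein": name, "motifs": int(m)} for name, m in cen.counts_b.items()
    ]
    return pd.DataFrame(rows)
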