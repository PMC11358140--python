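"""Ribosome-stalling analyses from RPF 5'-end alignments.

Two complementary views of elongation pausing:

* **5'-end density**: a metagene profile of footprint 5'-end counts in a
  61-nt window centered on every CDS instance of an anchor codon or amino
  acid, each instance normalized by its own window mean. A ribosome paused
  with the anchor in its A site piles 5' ends ``o_A`` nt upstream of the
  anchor codon start.
* **Subsequence (site occupancy)**: each footprint is assigned E/P/A-site
  codons through fixed 5'-end offsets (9/12/15 nt to the first nucleotide of
  each site codon), and observed counts per codon identity, amino acid, or
  E-P-A tripeptide are compared to the expectation under uniform elongation.
  The pause score is observed/expected; the expectation is coverage-weighted
  by default so transcript abundance does not confound codon usage.
"""
from __future__ import annotations

from dataclasses import dataclass
from collections import Counter

import numpy as np
import pandas as pd

from .transcripts import Transcriptome


@dataclass(frozen=True)
class OffsetConfig:
    """Distances (nt) from the RPF 5' end to the first nucleotide of the
    E-, P-, and A-site codons. Canonical ribosome geometry forces 3-nt
    spacing."""

    o_e: int = 9
    o_p: int = 12
    o_a: int = 15

    def __post_init__(self) -> None:
        if not self.o_e < self.o_p < self.o_a:
            raise ValueError("offsets must satisfy o_e < o_p < o_a")
        if self.o_p - self.o_e != 3 or self.o_a - self.o_p != 3:
            raise ValueError("E/P/A offsets must be spaced 3 nt apart")


@dataclass
class OccupancyProfile:
    """Average normalized 5'-end density around an anchor codon."""

    anchor: str
    positions: np.ndarray  # nt relative to anchor codon start
    density: np.ndarray
    n_instances: int


def assign_sites(
    rpf: pd.DataFrame, transcriptome: Transcriptome, offsets: OffsetConfig = OffsetConfig()
) -> tuple[pd.DataFrame, int]:
    """Map each footprint to its E/P/A-site codon indices.

    A read is in frame when its A-site position lands on the first
    nucleotide of a CDS codon; reads whose site codons fall outside the CDS
    or out of frame are excluded. Returns the assigned table (input columns
    plus ``e_codon``/``p_codon``/``a_codon``) and the total excluded read
    count; assigned + excluded equals the input read total.
    """
    missing = set(rpf["transcript"]) - set(transcriptome.cds)
    if missing:
        raise KeyError(f"transcript(s) absent from annotation: {sorted(missing)[:3]}")
    ann = pd.DataFrame(
        {
            "transcript": list(transcriptome.cds),
            "_cds_start": [transcriptome.cds_start(t) for t in transcriptome.cds],
            "_n_codons": [transcriptome.n_codons(t) for t in transcriptome.cds],
        }
    )
    merged = rpf.merge(ann, on="transcript", how="left")
    rel = merged["five_prime_pos"] + offsets.o_a - merged["_cds_start"]
    in_frame = (rel % 3 == 0) & (rel >= 0)
    a_codon = rel // 3
    keep = in_frame & (a_codon - 2 >= 0) & (a_codon < merged["_n_codons"])
    assigned = merged.loc[keep].copy()
    assigned["a_codon"] = a_codon[keep].astype(int)
    assigned["p_codon"] = assigned["a_codon"] - 1
    assigned["e_codon"] = assigned["a_codon"] - 2
    excluded = int(merged.loc[~keep, "count"].sum())
    return assigned.drop(columns=["_cds_start", "_n_codons"]), excluded


def _coverage(rpf: pd.DataFrame, transcriptome: Transcriptome) -> dict[str, np.ndarray]:
    """Per-transcript arrays of summed 5'-end counts."""
    cov = {
        name: np.zeros(len(seq), dtype=float)
        for name, seq in transcriptome.sequences.items()
    }
    pooled = rpf.groupby(["transcript", "five_prime_pos"])["count"].sum()
    for (name, pos), count in pooled.items():
        cov[name][pos] += count
    return cov


def _anchor_indices(transcriptome: Transcriptome, name: str, anchor: str) -> list[int]:
    anchor = anchor.upper()
    if len(anchor) == 1:
        peptide = transcriptome.peptide(name)
        return [i for i, aa in enumerate(peptide) if aa == anchor]
    if len(anchor) == 3:
        return [i for i, c in enumerate(transcriptome.cds_codons(name)) if c == anchor]
    raise ValueError("anchor must be a 1-letter amino acid or a 3-nt codon")


def codon_region_profile(
    rpf: pd.DataFrame,
    transcriptome: Transcriptome,
    anchor: str,
    window: int = 61,
) -> OccupancyProfile:
    """Metagene 5'-end density over ``window`` nt centered on anchor codons.

    Every CDS instance of the anchor whose window fits inside the transcript
    contributes its 5'-end counts, normalized by the instance's own window
    mean (zero-coverage instances dropped); instances are then averaged.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be a positive odd number of nucleotides")
    half = (window - 1) // 2
    cov = _coverage(rpf, transcriptome)
    total = np.zeros(window)
    n_instances = 0
    for name in transcriptome.cds:
        start = transcriptome.cds_start(name)
        tx_cov = cov[name]
        for c in _anchor_indices(transcriptome, name, anchor):
            center = start + 3 * c
            lo, hi = center - half, center + half + 1
            if lo < 0 or hi > len(tx_cov):
                continue
            win = tx_cov[lo:hi]
            mean = win.sum() / window
            if mean == 0:
                continue
            total += win / mean
            n_instances += 1
    if n_instances == 0:
        raise ValueError(f"no anchor instance of {anchor!r} with nonzero coverage")
    return OccupancyProfile(
        anchor=anchor,
        positions=np.arange(-half, half + 1),
        density=total / n_instances,
        n_instances=n_instances,
    )


def site_pause_scores(
    rpf: pd.DataFrame,
    transcriptome: Transcriptome,
    offsets: OffsetConfig = OffsetConfig(),
    level: str = "aa",
    edge_exclude: int = 5,
    expectation: str = "coverage",
) -> pd.DataFrame:
    """Observed/expected occupancy per category at each ribosomal site.

    ``level`` is ``"aa"`` (amino acid), ``"codon"``, or ``"tripeptide"``
    (the joint E-P-A amino-acid triplet). The first and last
    ``edge_exclude`` codons of each CDS are dropped from both observation
    and expectation to avoid initiation/termination artifacts. Expected
    counts are each transcript's in-frame read total multiplied by the
    category's frequency among that transcript's eligible codons
    (``expectation="coverage"``), or pooled frequencies across transcripts
    (``expectation="uniform"``).
    """
    if level not in {"aa", "codon", "tripeptide"}:
        raise ValueError("level must be 'aa', 'codon', or 'tripeptide'")
    if expectation not in {"coverage", "uniform"}:
        raise ValueError("expectation must be 'coverage' or 'uniform'")
    assigned, _ = assign_sites(rpf, transcriptome, offsets)
    if assigned["count"].sum() == 0:
        raise ValueError("no in-frame assigned reads")

    peptides = {t: transcriptome.peptide(t) for t in transcriptome.cds}
    codons = {t: transcriptome.cds_codons(t) for t in transcriptome.cds}

    def category(tx: str, idx: int) -> str:
        return peptides[tx][idx] if level == "aa" else codons[tx][idx]

    results = []
    if level == "tripeptide":
        site_defs = [("EPA", None)]
    else:
        site_defs = [("E", "e_codon"), ("P", "p_codon"), ("A", "a_codon")]

    for site, col in site_defs:
        observed: Counter[str] = Counter()
        n_reads_tx: Counter[str] = Counter()
        for rec in assigned.itertuples(index=False):
            tx = rec.transcript
            n = transcriptome.n_codons(tx)
            lo, hi = edge_exclude, n - edge_exclude
            if site == "EPA":
                if not (rec.e_codon >= lo and rec.a_codon < hi):
                    continue
                cat = (
                    peptides[tx][rec.e_codon]
                    + peptides[tx][rec.p_codon]
                    + peptides[tx][rec.a_codon]
                )
            else:
                idx = getattr(rec, col)
                if not lo <= idx < hi:
                    continue
                cat = category(tx, idx)
            observed[cat] += rec.count
            n_reads_tx[tx] += rec.count

        # category frequencies among eligible positions, per transcript
        tx_freq: dict[str, Counter[str]] = {}
        tx_sizes: dict[str, int] = {}
        for tx in transcriptome.cds:
            n = transcriptome.n_codons(tx)
            lo, hi = edge_exclude, n - edge_exclude
            counts: Counter[str] = Counter()
            if site == "EPA":
                for c in range(lo + 2, hi):
                    counts[peptides[tx][c - 2 : c + 1]] += 1
            else:
                for c in range(lo, hi):
                    counts[category(tx, c)] += 1
            size = sum(counts.values())
            if size:
                tx_freq[tx] = counts
                tx_sizes[tx] = size

        if not tx_freq:
            raise ValueError("empty category universe after edge exclusion")
        expected: dict[str, float] = {}
        if expectation == "coverage":
            for tx, n_reads in n_reads_tx.items():
                if tx not in tx_freq:
                    continue
                size = tx_sizes[tx]
                for cat, cnt in tx_freq[tx].items():
                    expected[cat] = expected.get(cat, 0.0) + n_reads * cnt / size
        else:
            pooled: Counter[str] = Counter()
            for counts in tx_freq.values():
                pooled.update(counts)
            universe = sum(pooled.values())
            total_reads = sum(n_reads_tx.values())
            for cat, cnt in pooled.items():
                expected[cat] = total_reads * cnt / universe

        for cat in sorted(set(observed) | set(expected)):
            obs = float(observed.get(cat, 0))
            exp = float(expected.get(cat, 0.0))
            score = obs / exp if exp > 0 else np.nan
            results.append(
                {"site": site, "category": cat, "observed": obs,
                 "expected": exp, "score": score}
            )
    return pd.DataFrame(results, columns=["site", "category", "observed", "expected", "score"])


def compare_conditions(
    scores_a: pd.DataFrame, scores_b: pd.DataFrame, pseudocount: float = 0.0
) -> pd.DataFrame:
    """Per-category ratio of pause scores between two conditions.

    Requires matched (site, category) universes; ``ratio`` inverts exactly
    under swapping the conditions when ``pseudocount`` is 0.
    """
    merged = scores_a.merge(
        scores_b, on=["site", "category"], how="outer",
        suffixes=("_a", "_b"), validate="1:1", indicator=True,
    )
    if (merged["_merge"] != "both").any():
        bad = merged.loc[merged["_merge"] != "both", ["site", "category"]]
        raise ValueError(f"mismatched categories between conditions: {bad.values[:3]}")
    merged = merged.drop(columns="_merge")
    merged["ratio"] = (merged["score_a"] + pseudocount) / (merged["score_b"] + pseudocount)
    return merged[["site", "category", "score_a", "score_b", "ratio"]]
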