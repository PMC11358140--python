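"""Scoring of a FACS-sorted CRISPR knockout screen.

Per-guide enrichment is the log2 ratio of a guide's normalized frequency in
the sorted (low protein-synthesis) population versus the unsorted day-0
population. Gene scores use the standardized mean of guide residuals,

    z = (x - mu) / (sigma / sqrt(n)),

where x is the mean residual of the gene's guides and mu, sigma are the
mean and (population) standard deviation of the residuals of all guides in
the library, negative controls included. The "residual" is the enrichment
score for a single-condition analysis or the between-condition LFC for a
contrast. Two conditions are contrasted by the Z-ratio: the per-gene
difference of z scores, centered and scaled by its standard deviation over
genes.
"""
from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

from .synthdata import CONTROL_GENE


def _count_columns(table: pd.DataFrame) -> list[str]:
    cols = [c for c in table.columns if c.startswith("count_")]
    if not cols:
        raise ValueError("guide table has no count_<sample> columns")
    return cols


def normalize_frequencies(table: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Add ``freq_<sample>`` columns: (count + pseudocount) / column total."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    out = table.copy()
    for col in _count_columns(table):
        counts = table[col].to_numpy(dtype=float)
        if (counts < 0).any():
            raise ValueError(f"negative counts in {col}")
        if counts.sum() == 0:
            raise ValueError(f"sample {col} has no reads")
        adjusted = counts + pseudocount
        out[col.replace("count_", "freq_", 1)] = adjusted / adjusted.sum()
    return out


def enrichment_scores(
    table: pd.DataFrame, sorted_sample: str, baseline_sample: str
) -> pd.DataFrame:
    """Per-guide enrichment e = log2(f_sorted / f_baseline)."""
    f_sorted = f"freq_{sorted_sample}"
    f_base = f"freq_{baseline_sample}"
    for col in (f_sorted, f_base):
        if col not in table.columns:
            raise KeyError(f"missing frequency column {col!r}; normalize first")
    if (table[f_base] <= 0).any():
        raise ValueError("zero baseline frequency; use a positive pseudocount")
    out = table[["guide_id", "gene"]].copy()
    out["enrichment"] = np.log2(table[f_sorted] / table[f_base])
    return out


def guide_lfc(scores_a: pd.DataFrame, scores_b: pd.DataFrame) -> pd.DataFrame:
    """Per-guide LFC: enrichment in condition a minus condition b."""
    merged = scores_a.merge(
        scores_b, on=["guide_id", "gene"], suffixes=("_a", "_b"), validate="1:1"
    )
    merged["lfc"] = merged["enrichment_a"] - merged["enrichment_b"]
    return merged[["guide_id", "gene", "lfc"]]


def gene_zscores(
    residuals: pd.DataFrame,
    value: str = "enrichment",
    controls_only: bool = False,
    control_gene: str = CONTROL_GENE,
) -> pd.DataFrame:
    """Gene-level z scores from per-guide residuals.

    mu and sigma are computed over the residuals of all guides (or only the
    negative-control guides when ``controls_only``); sigma is the population
    standard deviation. Controls appear in the output as the pseudo-gene
    ``control_gene``. Raises on degenerate input (sigma == 0).
    """
    vals = residuals[value].to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("non-finite residuals; check pseudocount handling")
    ref = vals
    if controls_only:
        ref = residuals.loc[residuals["gene"] == control_gene, value].to_numpy(dtype=float)
        if len(ref) == 0:
            raise ValueError("no control guides for controls-only standardization")
    mu = float(ref.mean())
    sigma = float(ref.std(ddof=0))
    if sigma == 0:
        raise ValueError("zero residual dispersion; z scores undefined")
    grouped = residuals.groupby("gene", sort=True)[value]
    stats = grouped.agg(n="size", x="mean").reset_index()
    stats["mu"] = mu
    stats["sigma"] = sigma
    stats["z"] = (stats["x"] - mu) / (sigma / np.sqrt(stats["n"]))
    return stats


def z_ratio(stats_a: pd.DataFrame, stats_b: pd.DataFrame) -> pd.DataFrame:
    """Standardized per-gene difference of z scores between two conditions.

    Zr = (d - mean(d)) / sd(d), d = z_a - z_b, sd with ddof=1 over genes.
    Antisymmetric under swapping the conditions.
    """
    genes_a, genes_b = set(stats_a["gene"]), set(stats_b["gene"])
    if genes_a != genes_b:
        raise ValueError("gene sets differ between conditions")
    merged = stats_a[["gene", "z"]].merge(
        stats_b[["gene", "z"]], on="gene", suffixes=("_a", "_b"), validate="1:1"
    )
    diff = merged["z_a"] - merged["z_b"]
    sd = float(diff.std(ddof=1))
    if not sd > 0:
        raise ValueError("z differences have zero spread; Z-ratio undefined")
    merged["z_ratio"] = (diff - diff.mean()) / sd
    return merged


def rank_hits(
    ratios: pd.DataFrame, column: str = "z_ratio", direction: str = "descending"
) -> pd.DataFrame:
    """Stable ranking by ``column``; ties broken lexicographically by gene."""
    if direction not in {"ascending", "descending"}:
        raise ValueError("direction must be 'ascending' or 'descending'")
    if not np.isfinite(ratios[column]).all():
        raise ValueError(f"non-finite values in {column}")
    out = ratios.sort_values(
        [column, "gene"], ascending=[direction == "ascending", True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def score_screen(
    counts: Mapping[str, pd.DataFrame],
    sorted_sample: str = "sorted",
    baseline_sample: str = "d0",
    contrast: tuple[str, str] | None = None,
    pseudocount: float = 0.5,
    controls_only: bool = False,
) -> pd.DataFrame:
    """Full screen scoring across conditions.

    ``counts`` maps condition name -> guide table with ``count_d0`` and
    ``count_sorted`` columns. Computes per-condition enrichment and gene z
    scores; when ``contrast=(a, b)`` is given, adds the gene z of the guide
    LFC (a minus b), the Z-ratio between the two conditions' z scores, and a
    hit rank (descending Z-ratio).
    """
    per_condition: dict[str, pd.DataFrame] = {}
    scores: dict[str, pd.DataFrame] = {}
    for name, table in counts.items():
        normalized = normalize_frequencies(table, pseudocount=pseudocount)
        e = enrichment_scores(normalized, sorted_sample, baseline_sample)
        scores[name] = e
        per_condition[name] = gene_zscores(e, controls_only=controls_only)

    result: pd.DataFrame | None = None
    for name, stats in per_condition.items():
        cols = stats.rename(
            columns={"x": f"x_{name}", "z": f"z_{name}"}
        )[["gene", "n", f"x_{name}", f"z_{name}"]]
        result = cols if result is None else result.merge(cols, on=["gene", "n"])
    assert result is not None

    if contrast is not None:
        a, b = contrast
        lfc = guide_lfc(scores[a], scores[b])
        z_lfc = gene_zscores(lfc, value="lfc", controls_only=controls_only)
        result = result.merge(
            z_lfc.rename(columns={"x": "x_lfc", "z": "z_lfc"})[["gene", "x_lfc", "z_lfc"]],
            on="gene",
        )
        ratios = z_ratio(per_condition[a], per_condition[b])
        result = result.merge(ratios[["gene", "z_ratio"]], on="gene")
        result = rank_hits(result, column="z_ratio", direction="descending")
    return result
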