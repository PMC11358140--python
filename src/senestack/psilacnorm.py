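"""Normalization of nascent-proteome pSILAC ratios.

Nascent (AHA-enriched) samples have no fixed heavy/intermediate mixing
anchor, so their log2 SILAC ratios are median-normalized to the mean ratio
of the most abundant proteins in the paired global proteome: the reference
is the top-n protein groups by iBAQ, and the nascent ratios are shifted
additively so their median equals the reference mean. The shift preserves
all pairwise differences between nascent proteins exactly.

Tables are long-format with columns ``protein``, ``replicate``,
``log2_ratio``, ``ibaq``; the reference is computed per replicate by
default.
"""
from __future__ import annotations

import numpy as np
import pandas as pd


def top_ibaq_reference(global_table: pd.DataFrame, n_top: int = 1000) -> tuple[pd.Index, float]:
    """Reference protein set and mean log2 ratio from one global sample.

    Picks the ``n_top`` highest-iBAQ protein groups (ties broken by stable
    protein-id order) among rows with both an iBAQ and a ratio value, and
    returns their ids together with the mean of their log2 ratios.
    """
    quantified = global_table.dropna(subset=["ibaq", "log2_ratio"])
    if (quantified["ibaq"] <= 0).any():
        raise ValueError("iBAQ intensities must be positive")
    if len(quantified) < n_top:
        raise ValueError(
            f"only {len(quantified)} quantified proteins; need n_top={n_top}"
        )
    ordered = quantified.sort_values(
        ["ibaq", "protein"], ascending=[False, True], kind="mergesort"
    ).head(n_top)
    return pd.Index(ordered["protein"]), float(ordered["log2_ratio"].mean())


def normalize_nascent(nascent: pd.DataFrame, reference_mean: float) -> pd.DataFrame:
    """Shift nascent log2 ratios so their median equals ``reference_mean``."""
    if nascent.empty:
        raise ValueError("nascent table is empty")
    out = nascent.copy()
    shift = reference_mean - float(out["log2_ratio"].median())
    out["log2_ratio"] = out["log2_ratio"] + shift
    return out


def normalize_psilac(
    nascent: pd.DataFrame,
    global_table: pd.DataFrame,
    n_top: int = 1000,
    per_replicate: bool = True,
) -> pd.DataFrame:
    """Median-normalize nascent ratios to the global top-iBAQ reference.

    With ``per_replicate`` (default) the reference mean and the shift are
    computed within each replicate; otherwise both tables are pooled.
    """
    if not per_replicate or "replicate" not in nascent.columns:
        _, g = top_ibaq_reference(global_table, n_top)
        return normalize_nascent(nascent, g)
    parts = []
    for rep, nas_rep in nascent.groupby("replicate", sort=True):
        glo_rep = global_table[global_table["replicate"] == rep]
        if glo_rep.empty:
            raise ValueError(f"replicate {rep!r} missing from global table")
        _, g = top_ibaq_reference(glo_rep, n_top)
        parts.append(normalize_nascent(nas_rep, g))
    return pd.concat(parts, ignore_index=True)


def filter_quantified(
    table: pd.DataFrame, min_ratios: int = 2, min_replicates: int = 3
) -> pd.DataFrame:
    """Keep protein groups quantified broadly enough for downstream tests.

    A group is retained when it has at least ``min_ratios`` non-missing
    ratio values and those values span at least ``min_replicates`` distinct
    replicates.
    """
    present = table.dropna(subset=["log2_ratio"])
    by_protein = present.groupby("protein")
    n_values = by_protein["log2_ratio"].size()
    n_reps = by_protein["replicate"].nunique()
    keep = n_values.index[(n_values >= min_ratios) & (n_reps >= min_replicates)]
    return table[table["protein"].isin(keep)].reset_index(drop=True)
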