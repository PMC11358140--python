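"""Synthetic inputs for every pipeline stage.

Generators here produce data with the statistical structure the downstream
analyses assume: a sorted CRISPR screen with programmed fluorescence effects
and an exact bottom-fraction sort gate, ribosome footprints with programmed
per-codon pauses, protein sets with controlled tripeptide-motif density,
isotopologue vectors convolved with the 13C natural-abundance kernel, and
paired nascent/global pSILAC tables. Every generator is deterministic under
a fixed seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .tracecorrect import (
    P13C_NATURAL,
    build_correction_matrix,
    convolve_natural_abundance,
)
from .transcripts import PauseSite, SynthTranscriptome

#: Reserved gene label for negative-control guides.
CONTROL_GENE = "NEG_CTRL"

#: The 20 standard amino acids.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Residues qualifying for the default eIF5A-dependent motif rule
#: (proline, glycine, charged). A stand-in: see `senestack.motifcensus`.
QUALIFYING_RESIDUES = "DEGKPR"

_SENSE_CODONS = sorted(standard_dna_table.forward_table)
_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon in _SENSE_CODONS:
    _AA_TO_CODONS.setdefault(standard_dna_table.forward_table[_codon], []).append(_codon)


# ---------------------------------------------------------------------------
# CRISPR screen
# ---------------------------------------------------------------------------

def make_library_manifest(
    n_genes: int, guides_per_gene: int, n_controls: int
) -> pd.DataFrame:
    """Guide library manifest: ``n_genes * guides_per_gene`` targeting guides
    plus ``n_controls`` negative controls under the reserved gene label.

    Naming is deterministic and lexicographically stable:
    ``GENE001_g1 ... ; ctrl_001 ...``.
    """
    if min(n_genes, guides_per_gene, n_controls) < 0:
        raise ValueError("library dimensions must be nonnegative")
    rows = []
    for g in range(1, n_genes + 1):
        gene = f"GENE{g:03d}"
        for j in range(1, guides_per_gene + 1):
            rows.append({"guide_id": f"{gene}_g{j}", "gene": gene, "is_control": False})
    for j in range(1, n_controls + 1):
        rows.append({"guide_id": f"ctrl_{j:03d}", "gene": CONTROL_GENE, "is_control": True})
    return pd.DataFrame(rows, columns=["guide_id", "gene", "is_control"])


@dataclass
class SortSimulation:
    """Per-cell record of one simulated FACS sort."""

    guide_of_cell: np.ndarray
    log_fluorescence: np.ndarray
    gate_fraction: float
    effect_map: dict[str, float]
    gate_cells: np.ndarray  # indices of cells inside the low gate


def simulate_sorted_screen(
    manifest: pd.DataFrame,
    n_cells: int,
    effect_map: Mapping[str, float] | None = None,
    gate_fraction: float = 0.15,
    dispersion: float = 0.01,
    seed: int = 0,
    fluor_sigma: float = 0.5,
    day0_depth: int | None = None,
    sorted_depth: int | None = None,
    return_cells: bool = False,
):
    """Simulate a FACS-sorted knockout screen on protein-synthesis readout.

    Cells carry one guide each (day-0 guide frequencies are
    Dirichlet-multinomial with concentration 1/``dispersion`` per guide).
    Per-cell fluorescence is log-normal; a gene's effect acts
    multiplicatively on the mean, so effects < 1 push that gene's cells into
    the low gate. The gate keeps exactly ``floor(gate_fraction * n_cells)``
    cells (ties broken by stable cell order). Day-0 counts are resampled to
    ``day0_depth`` reads (default ``n_cells``); sorted counts are the gate
    tallies, optionally resampled to ``sorted_depth``.

    Returns a guide table with ``count_d0`` and ``count_sorted`` columns
    (and the per-cell :class:`SortSimulation` when ``return_cells``).
    """
    n_guides = len(manifest)
    if n_guides == 0:
        raise ValueError("empty library manifest")
    if n_cells < n_guides:
        raise ValueError("n_cells too small to represent the library")
    if not 0 < gate_fraction < 1:
        raise ValueError("gate_fraction must lie in (0, 1)")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng(seed)
    effects = dict(effect_map or {})

    p0 = rng.dirichlet(np.full(n_guides, 1.0 / dispersion))
    day0_depth = n_cells if day0_depth is None else int(day0_depth)
    count_d0 = rng.multinomial(day0_depth, p0)

    cells_per_guide = rng.multinomial(n_cells, p0)
    guide_of_cell = np.repeat(np.arange(n_guides), cells_per_guide)
    gene_effect = np.array(
        [float(effects.get(g, 1.0)) for g in manifest["gene"]], dtype=float
    )
    log_f = np.log(gene_effect[guide_of_cell])
    if fluor_sigma > 0:
        log_f = log_f + rng.normal(0.0, fluor_sigma, size=n_cells)
    n_gate = math.floor(gate_fraction * n_cells)
    order = np.argsort(log_f, kind="stable")
    gate_cells = order[:n_gate]
    gate_counts = np.bincount(guide_of_cell[gate_cells], minlength=n_guides)

    if sorted_depth is None:
        count_sorted = gate_counts
    else:
        count_sorted = rng.multinomial(int(sorted_depth), gate_counts / n_gate)

    table = manifest[["guide_id", "gene"]].copy()
    table["count_d0"] = count_d0
    table["count_sorted"] = count_sorted
    if return_cells:
        sim = SortSimulation(
            guide_of_cell=guide_of_cell,
            log_fluorescence=log_f,
            gate_fraction=gate_fraction,
            effect_map=effects,
            gate_cells=gate_cells,
        )
        return table, sim
    return table


# ---------------------------------------------------------------------------
# Ribosome profiling
# ---------------------------------------------------------------------------

def make_transcriptome(
    n_transcripts: int = 10,
    n_codons: int = 200,
    utr5: int = 30,
    utr3: int = 30,
    pauses: Sequence[tuple[str, int, str, float]] | Sequence[PauseSite] = (),
    seed: int = 0,
    background_aas: str | None = None,
) -> SynthTranscriptome:
    """Random transcriptome with programmed pause codons.

    Each transcript has ``n_codons`` sense codons followed by a TAA stop;
    background codons are drawn uniformly from the sense codons (optionally
    restricted to ``background_aas``). At each pause site the first
    (alphabetical) codon of the stated amino acid is substituted, so the
    pause codon provably translates to that amino acid. Transcripts are
    named ``tx0000, tx0001, ...``.
    """
    rng = np.random.default_rng(seed)
    pause_sites = [
        p if isinstance(p, PauseSite) else PauseSite(*p) for p in pauses
    ]
    if background_aas is None:
        codon_pool = _SENSE_CODONS
    else:
        codon_pool = [c for c in _SENSE_CODONS
                      if standard_dna_table.forward_table[c] in set(background_aas)]
        if not codon_pool:
            raise ValueError("background_aas leaves no codons to sample")
    names = [f"tx{i:04d}" for i in range(n_transcripts)]
    by_tx: dict[str, list[PauseSite]] = {}
    for p in pause_sites:
        if p.transcript not in names:
            raise KeyError(f"pause references unknown transcript {p.transcript!r}")
        if not 0 <= p.codon_index < n_codons:
            raise IndexError(f"pause codon {p.codon_index} outside CDS")
        by_tx.setdefault(p.transcript, []).append(p)

    sequences: dict[str, str] = {}
    cds: dict[str, tuple[int, int]] = {}
    nt = np.array(list("ACGT"))
    for name in names:
        codons = list(rng.choice(codon_pool, size=n_codons))
        for p in by_tx.get(name, ()):
            codons[p.codon_index] = _AA_TO_CODONS[p.amino_acid][0]
        body = "".join(codons) + "TAA"
        left = "".join(rng.choice(nt, size=utr5))
        right = "".join(rng.choice(nt, size=utr3))
        sequences[name] = left + body + right
        cds[name] = (utr5, utr5 + len(body))
    return SynthTranscriptome(sequences=sequences, cds=cds, pause_spec=pause_sites)


def simulate_rpf(
    transcriptome: SynthTranscriptome,
    depth: int,
    a_site_offset: int = 15,
    read_lengths: Sequence[int] = (28, 29, 30, 31),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate ribosome-protected-fragment 5' ends with programmed pauses.

    A ribosome occupying codon c (A site) leaves a footprint whose 5' end is
    ``a_site_offset`` nt upstream of the codon start. Occupancy is sampled
    per sense codon with probability proportional to pause strength (1 for
    unpaused codons); the stop codon is not part of the sampling universe.
    Read lengths are uniform over ``read_lengths``. Exactly ``depth`` reads
    are emitted, as a BED-like table (transcript, five_prime_pos,
    read_length, count).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if a_site_offset < 0:
        raise ValueError("a_site_offset must be >= 0")
    rng = np.random.default_rng(seed)
    max_len = max(read_lengths)

    strength: dict[tuple[str, int], float] = {
        (p.transcript, p.codon_index): p.strength for p in transcriptome.pause_spec
    }
    tx_ids: list[str] = []
    positions: list[int] = []
    weights: list[float] = []
    for name in transcriptome.sequences:
        if name not in transcriptome.cds:
            continue
        start = transcriptome.cds_start(name)
        n_cod = transcriptome.n_codons(name)
        codons = transcriptome.cds_codons(name)
        tx_len = len(transcriptome.sequences[name])
        for c in range(n_cod):
            if codons[c] in {"TAA", "TAG", "TGA"}:
                continue
            fp = start + 3 * c - a_site_offset
            placeable = fp >= 0 and fp + max_len <= tx_len
            w = strength.get((name, c), 1.0)
            if not placeable:
                if (name, c) in strength:
                    raise ValueError(
                        f"pause codon {name}:{c} too close to transcript edge "
                        f"for offset {a_site_offset}"
                    )
                continue
            tx_ids.append(name)
            positions.append(fp)
            weights.append(w)
    if not positions:
        raise ValueError("no codon can host a footprint at this offset")

    probs = np.asarray(weights, dtype=float)
    probs /= probs.sum()
    counts = rng.multinomial(depth, probs)
    lengths = np.asarray(read_lengths)
    per_len = rng.multinomial(counts, np.full(len(lengths), 1.0 / len(lengths)))

    rows = []
    for i in np.flatnonzero(counts):
        for j in np.flatnonzero(per_len[i]):
            rows.append(
                {
                    "transcript": tx_ids[i],
                    "five_prime_pos": positions[i],
                    "read_length": int(lengths[j]),
                    "count": int(per_len[i, j]),
                }
            )
    out = pd.DataFrame(rows, columns=["transcript", "five_prime_pos", "read_length", "count"])
    return out.sort_values(["transcript", "five_prime_pos", "read_length"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Isotopologue tracing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabelingDesign:
    """True labeling state of a tracing experiment.

    ``carbons`` maps compound -> carbon count; ``labeled_fraction`` maps
    compound -> fraction of molecules carrying the fully labeled backbone.
    """

    carbons: Mapping[str, int]
    labeled_fraction: Mapping[str, float]
    p13c: float = P13C_NATURAL

    def __post_init__(self) -> None:
        for name, k in self.carbons.items():
            if k < 1:
                raise ValueError(f"carbon count of {name!r} must be >= 1")
        for name, f in self.labeled_fraction.items():
            if not 0 <= f <= 1:
                raise ValueError(f"labeled fraction of {name!r} outside [0, 1]")


def simulate_isotopologues(
    design: LabelingDesign, noise_sd: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Forward-simulate measured isotopologue vectors.

    Each compound's true vector is a two-point mixture of unlabeled (M+0)
    and fully labeled (M+k) species, convolved with the binomial
    natural-abundance kernel at ``design.p13c``, plus truncated Gaussian
    noise. Vectors are renormalized to sum to 1. Columns: compound, carbons,
    M0..Mmax (NaN beyond a compound's carbon count).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    max_k = max(design.carbons.values())
    rows = []
    for compound, k in design.carbons.items():
        f = float(design.labeled_fraction.get(compound, 0.0))
        x = np.zeros(k + 1)
        x[0] = 1.0 - f
        x[k] += f
        observed = convolve_natural_abundance(x, build_correction_matrix(k, design.p13c))
        if noise_sd > 0:
            observed = np.clip(observed + rng.normal(0.0, noise_sd, k + 1), 0.0, None)
        observed = observed / observed.sum()
        row: dict[str, object] = {"compound": compound, "carbons": k}
        for i in range(max_k + 1):
            row[f"M{i}"] = observed[i] if i <= k else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Protein sets with controlled motif density
# ---------------------------------------------------------------------------

def simulate_protein_sets(
    n_a: int,
    n_b: int,
    length: int = 300,
    motif_rate_a: float = 0.02,
    motif_rate_b: float = 0.02,
    seed: int = 0,
    qualifying: str = QUALIFYING_RESIDUES,
) -> tuple[dict[str, str], dict[str, str]]:
    """Two protein sets whose tripeptide windows qualify at stated rates.

    Residues are i.i.d.: qualifying with probability ``rate ** (1/3)`` so a
    window of three consecutive residues is all-qualifying with probability
    ``rate``. Returns (set_a, set_b) as name -> sequence mappings.
    """
    if length < 3:
        raise ValueError("protein length must be >= 3")
    for rate in (motif_rate_a, motif_rate_b):
        if not 0 <= rate <= 1:
            raise ValueError("motif rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    qual = np.array(sorted(set(qualifying)))
    nonq = np.array(sorted(set(AMINO_ACIDS) - set(qualifying)))

    def one_set(n: int, rate: float, prefix: str) -> dict[str, str]:
        q = rate ** (1.0 / 3.0) if rate > 0 else 0.0
        is_q = rng.random((n, length)) < q
        letters = np.where(
            is_q,
            qual[rng.integers(0, len(qual), (n, length))],
            nonq[rng.integers(0, len(nonq), (n, length))],
        )
        return {f"{prefix}{i:04d}": "".join(row) for i, row in enumerate(letters)}

    return one_set(n_a, motif_rate_a, "A_"), one_set(n_b, motif_rate_b, "B_")


# ---------------------------------------------------------------------------
# Paired pSILAC tables
# ---------------------------------------------------------------------------

def simulate_psilac(
    n_proteins: int = 2000,
    n_replicates: int = 3,
    seed: int = 0,
    ibaq_sigma: float = 2.0,
    ratio_sd: float = 0.5,
    replicate_shift_sd: float = 0.3,
    nascent_offset: float = 1.0,
    missing_rate: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired nascent/global protein quantification tables.

    Global iBAQ intensities are log-normal over proteins; log2 SILAC ratios
    are Gaussian around a per-replicate shift (mimicking mixing-ratio drift,
    the artifact the top-iBAQ normalization removes). Nascent ratios carry an
    additional constant offset and random missingness. Long format:
    protein, replicate, log2_ratio, ibaq.
    """
    rng = np.random.default_rng(seed)
    proteins = [f"P{i:05d}" for i in range(n_proteins)]
    ibaq_base = rng.lognormal(mean=10.0, sigma=ibaq_sigma, size=n_proteins)
    shifts = rng.normal(0.0, replicate_shift_sd, size=n_replicates)

    global_rows, nascent_rows = [], []
    for r in range(1, n_replicates + 1):
        ratios_g = shifts[r - 1] + rng.normal(0.0, ratio_sd, n_proteins)
        ratios_n = shifts[r - 1] + nascent_offset + rng.normal(0.0, ratio_sd, n_proteins)
        missing = rng.random(n_proteins) < missing_rate
        for i, prot in enumerate(proteins):
            global_rows.append(
                {"protein": prot, "replicate": r,
                 "log2_ratio": ratios_g[i], "ibaq": ibaq_base[i]}
            )
            nascent_rows.append(
                {"protein": prot, "replicate": r,
                 "log2_ratio": np.nan if missing[i] else ratios_n[i],
                 "ibaq": ibaq_base[i]}
            )
    return pd.DataFrame(nascent_rows), pd.DataFrame(global_rows)
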