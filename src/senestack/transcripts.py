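"""Transcript sequences with CDS annotation.

Transcripts are plain nucleotide strings keyed by id; each annotated CDS is a
0-based half-open interval ``[start, end)`` on the transcript whose length is a
multiple of 3. Translation uses the standard codon table via Biopython.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass
class Transcriptome:
    """Container mapping transcript id -> sequence and id -> CDS interval."""

    sequences: dict[str, str]
    cds: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        for name, (start, end) in self.cds.items():
            if name not in self.sequences:
                raise KeyError(f"CDS annotated for unknown transcript {name!r}")
            seq = self.sequences[name]
            if not (0 <= start < end <= len(seq)):
                raise ValueError(
                    f"CDS [{start}, {end}) out of bounds for {name!r} "
                    f"(length {len(seq)})"
                )
            if (end - start) % 3:
                raise ValueError(f"CDS length of {name!r} not divisible by 3")

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def cds_start(self, name: str) -> int:
        return self.cds[name][0]

    def n_codons(self, name: str) -> int:
        start, end = self.cds[name]
        return (end - start) // 3

    def codon(self, name: str, index: int) -> str:
        start, end = self.cds[name]
        pos = start + 3 * index
        if not (start <= pos < end):
            raise IndexError(f"codon {index} outside CDS of {name!r}")
        return self.sequences[name][pos : pos + 3].upper()

    def cds_codons(self, name: str) -> list[str]:
        start, end = self.cds[name]
        seq = self.sequences[name].upper()
        return [seq[i : i + 3] for i in range(start, end, 3)]

    def peptide(self, name: str) -> str:
        """Amino-acid string of the CDS; a terminal stop translates to ``*``."""
        start, end = self.cds[name]
        return str(Seq(self.sequences[name][start:end]).translate())

    @classmethod
    def from_files(cls, fasta_path: str | Path, cds_path: str | Path) -> "Transcriptome":
        seqs = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(fasta_path), "fasta")
        }
        ann = pd.read_csv(cds_path, sep="\t")
        cds = {
            str(r.transcript): (int(r.cds_start), int(r.cds_end))
            for r in ann.itertuples(index=False)
        }
        return cls(sequences=seqs, cds=cds)

    def to_files(self, fasta_path: str | Path, cds_path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.sequences.items()
        ]
        SeqIO.write(records, str(fasta_path), "fasta")
        pd.DataFrame(
            [
                {"transcript": name, "cds_start": start, "cds_end": end}
                for name, (start, end) in self.cds.items()
            ]
        ).to_csv(cds_path, sep="\t", index=False)


@dataclass(frozen=True)
class PauseSite:
    """A programmed elongation pause at one CDS codon.

    ``strength`` is the multiplicative sampling weight of the codon relative
    to an unpaused codon (>= 1 means at least background occupancy).
    """

    transcript: str
    codon_index: int
    amino_acid: str
    strength: float

    def __post_init__(self) -> None:
        if self.strength < 1:
            raise ValueError("pause strength must be >= 1")


@dataclass
class SynthTranscriptome(Transcriptome):
    """Transcriptome plus the pause sites programmed into it."""

    pause_spec: list[PauseSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        super().__post_init__()
        for pause in self.pause_spec:
            codon = self.codon(pause.transcript, pause.codon_index)
            aa = str(Seq(codon).translate())
            if aa != pause.amino_acid:
                raise ValueError(
                    f"pause at {pause.transcript}:{pause.codon_index} is codon "
                    f"{codon} ({aa}), not {pause.amino_acid}"
                )
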