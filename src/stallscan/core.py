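"""Core domain objects shared by every stage of the stalling analysis.

Coordinates are 0-based and half-open everywhere inside the package; the
wiggle I/O boundary is the only place 1-based positions appear.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import cached_property

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

_TABLE = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.stop_codons))
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.forward_table))
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
AMINO_ACIDS: tuple[str, ...] = tuple(sorted(set(CODON_TO_AA.values())))
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Charge classes used by the composite enrichment tests.
POSITIVE_AAS = frozenset("KRH")
NEGATIVE_AAS = frozenset("DE")


class InputError(ValueError):
    """Raised when an input violates a stage's preconditions."""


@dataclass(frozen=True)
class CodingRegion:
    """A gene's CDS (frame 0, including the terminal stop codon if present)."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", seq)
        if len(seq) == 0 or len(seq) % 3 != 0:
            raise InputError(
                f"{self.gene_id}: CDS length {len(seq)} is not a positive multiple of 3"
            )

    @property
    def n_nucleotides(self) -> int:
        return len(self.sequence)

    @property
    def n_codons(self) -> int:
        return len(self.sequence) // 3

    @cached_property
    def codons(self) -> tuple[str, ...]:
        s = self.sequence
        return tuple(s[i : i + 3] for i in range(0, len(s), 3))

    @cached_property
    def aa_string(self) -> str:
        """Translation of every codon, '*' for stops (terminal stop included)."""
        return str(Seq(self.sequence).translate())

    @cached_property
    def protein(self) -> str:
        """Amino-acid sequence without the terminal stop."""
        aa = self.aa_string
        return aa[:-1] if aa.endswith("*") else aa


@dataclass
class NucleotideProfile:
    """Per-CDS-nucleotide read counts (or densities) for one gene and assay."""

    gene_id: str
    values: np.ndarray
    assay: str  # {"ribo", "mrna"}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise InputError(f"{self.gene_id}: profile must be 1-D")
        if np.any(self.values < 0):
            raise InputError(f"{self.gene_id}: negative values in {self.assay} profile")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class CodonProfile:
    """Per-codon values with a validity mask (False = excluded from statistics)."""

    gene_id: str
    values: np.ndarray
    assay: str  # {"ribo", "mrna", "rd_over_mrna"}
    mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.ones(len(self.values), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise InputError(f"{self.gene_id}: mask/values length mismatch")

    def __len__(self) -> int:
        return len(self.values)

    def copy(self) -> "CodonProfile":
        return CodonProfile(self.gene_id, self.values.copy(), self.assay, self.mask.copy())


@dataclass
class DatasetBundle:
    """One dataset's paired codon-resolution profiles over a common gene set."""

    dataset_id: str
    organism: str
    domain_of_life: str  # {"eukaryote", "prokaryote"}
    ribo: dict[str, CodonProfile]
    mrna: dict[str, CodonProfile] | None = None
    rd_over_mrna: dict[str, CodonProfile] | None = None

    def __post_init__(self) -> None:
        if self.domain_of_life not in ("eukaryote", "prokaryote"):
            raise InputError(f"unknown domain_of_life {self.domain_of_life!r}")
        if self.mrna is not None:
            if set(self.mrna) != set(self.ribo):
                raise InputError(f"{self.dataset_id}: ribo/mRNA gene sets differ")
            for g, p in self.ribo.items():
                if len(p) != len(self.mrna[g]):
                    raise InputError(f"{self.dataset_id}:{g}: ribo/mRNA length mismatch")

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.ribo)


@dataclass
class Peak:
    """A codon position whose RD/mRNA value exceeds the gene's mean + k·SD.

    ``codon_index`` is the 0-based codon of the ribosomal A-site at the stall;
    ``usr`` is the translation of the ``tunnel_window`` codons immediately
    upstream (N- to C-terminal order, so ``usr[-1]`` is P-site adjacent).
    """

    gene_id: str
    codon_index: int
    value: float
    usr: str | None = None
    usr_complete: bool = False
    sd_flagged: bool = False
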