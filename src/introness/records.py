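"""Core domain records: introns, genes, and essentiality labels.

The unit of analysis is a gene together with the ordered introns of one
chosen transcript.  Intron sequences are always stored strand-corrected,
i.e. written 5'->3' in the orientation of the transcript, so that the 5'
splice donor is at the start of the string and the 3' acceptor at the end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: IUPAC nucleotide codes accepted in intron sequences.
IUPAC_DNA = set("ACGTRYSWKMBDHVN")

CATEGORIES = ("essential", "conditional", "nonessential")
BINARY = ("essential", "nonessential", "discarded")


@dataclass(frozen=True)
class EssentialityLabel:
    """Three-way study label plus the binary mapping used for training.

    ``category`` is the label as curated (essential / conditional /
    nonessential).  ``binary`` collapses conditional genes using the
    majority-of-studies rule: a conditional gene called essential in at
    least half of the studies is grouped with essential genes, otherwise
    it is discarded from binary classification.
    """

    category: str
    binary: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.binary not in BINARY:
            raise ValueError(f"unknown binary label {self.binary!r}")


@dataclass
class IntronRecord:
    """One intron of one transcript, 5'->3'.

    ``ordinal`` is 1-based: ordinal 1 is the first intron in transcript
    order, which carries distinct regulatory signal and is treated
    separately throughout the analysis.
    """

    gene_id: str
    transcript_id: str
    ordinal: int
    sequence: str

    def __post_init__(self) -> None:
        if self.ordinal < 1:
            raise ValueError(f"ordinal must be >= 1, got {self.ordinal}")
        bad = set(self.sequence.upper()) - IUPAC_DNA
        if bad:
            raise ValueError(
                f"intron {self.gene_id}:{self.ordinal} contains non-IUPAC "
                f"characters {sorted(bad)}"
            )
        self.sequence = self.sequence.upper()

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_first(self) -> bool:
        return self.ordinal == 1


@dataclass
class GeneRecord:
    """A gene with its ordered introns and (optionally) its label."""

    gene_id: str
    strand: str
    introns: list[IntronRecord] = field(default_factory=list)
    label: EssentialityLabel | None = None
    essential_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        ordinals = [i.ordinal for i in self.introns]
        if len(set(ordinals)) != len(ordinals):
            raise ValueError(f"gene {self.gene_id}: duplicate intron ordinals")
        self.introns.sort(key=lambda i: i.ordinal)
        if self.essential_fraction is not None and not (
            0.0 <= self.essential_fraction <= 1.0
        ):
            raise ValueError("essential_fraction must lie in [0, 1]")

    @property
    def n_introns(self) -> int:
        return len(self.introns)

    @property
    def total_intronic_bp(self) -> int:
        return sum(i.length for i in self.introns)
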