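"""Sequence-level features: CDS translation, transit-peptide cleavage and
ionogenic-residue censuses."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio.Seq import Seq

__all__ = [
    "CodingSequence",
    "ProteinRecord",
    "SequenceError",
    "translate",
    "cleave_transit_peptide",
    "ionogenic_census",
    "read_fasta_sequence",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}
IONOGENIC = "RKYED"
AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")


class SequenceError(ValueError):
    pass


@dataclass
class CodingSequence:
    """A protein-coding nucleotide sequence: ATG...stop, length % 3 == 0."""

    nucleotides: str
    id: str = ""

    def __post_init__(self):
        nts = self.nucleotides.upper().replace("U", "T")
        bad = set(nts) - set("ACGT")
        if bad:
            raise SequenceError(f"{self.id}: non-ACGT characters {sorted(bad)}")
        if len(nts) % 3 != 0:
            raise SequenceError(f"{self.id}: length {len(nts)} not divisible by 3")
        if not nts.startswith("ATG"):
            raise SequenceError(f"{self.id}: CDS must start with ATG")
        if nts[-3:] not in STOP_CODONS:
            raise SequenceError(f"{self.id}: CDS must end with a stop codon")
        self.nucleotides = nts

    def __len__(self) -> int:
        return len(self.nucleotides)


@dataclass
class ProteinRecord:
    sequence: str
    transit_peptide_length: int = 0
    id: str = ""

    def __post_init__(self):
        bad = set(self.sequence) - AA_LETTERS
        if bad:
            raise SequenceError(f"{self.id}: invalid residue letters {sorted(bad)}")
        if not 0 <= self.transit_peptide_length < max(len(self.sequence), 1):
            raise SequenceError(
                f"{self.id}: transit peptide length {self.transit_peptide_length} "
                f"outside protein of {len(self.sequence)} residues"
            )

    @property
    def mature_start(self) -> int:
        return self.transit_peptide_length

    @property
    def mature_sequence(self) -> str:
        return self.sequence[self.transit_peptide_length:]

    def __len__(self) -> int:
        return len(self.sequence)


def translate(cds: CodingSequence, transit_peptide_length: int = 0) -> ProteinRecord:
    """Standard-genetic-code translation, stop removed.

    Internal stop codons raise with the offending codon index.
    """
    coding = cds.nucleotides[:-3]
    for i in range(0, len(coding), 3):
        if coding[i : i + 3] in STOP_CODONS:
            raise SequenceError(f"{cds.id}: internal stop codon at codon index {i // 3}")
    protein = str(Seq(coding).translate(table=1))
    return ProteinRecord(sequence=protein, transit_peptide_length=transit_peptide_length, id=cds.id)


def cleave_transit_peptide(protein: ProteinRecord, n: int) -> str:
    """Mature sequence after removing the N-terminal ``n`` residues.

    Reported residue numbering elsewhere stays in full-precursor
    coordinates (a mature residue keeps its precursor index).
    """
    if n >= len(protein.sequence):
        raise SequenceError(f"cannot cleave {n} residues from a {len(protein.sequence)}-aa protein")
    if n < 0:
        raise SequenceError("transit peptide length must be non-negative")
    return protein.sequence[n:]


def ionogenic_census(sequence: str) -> dict[str, int]:
    """Counts of R, K, Y, E, D (plus H, C) and their R/K/Y/E/D total."""
    bad = set(sequence) - AA_LETTERS
    if bad:
        raise SequenceError(f"invalid residue letters {sorted(bad)}")
    counts = {aa: sequence.count(aa) for aa in "RKYEDHC"}
    counts["total"] = sum(counts[aa] for aa in IONOGENIC)
    return counts


def read_fasta_sequence(path: str | Path) -> CodingSequence:
    """First record of a FASTA (or bare-sequence text) file as a CDS."""
    text = Path(path).read_text().strip()
    if text.startswith(">"):
        lines = text.splitlines()
        name = lines[0][1:].split()[0]
        body = "".join(l.strip() for l in lines[1:] if not l.startswith(">"))
    else:
        name = Path(path).stem
        body = "".join(text.split())
    return CodingSequence(nucleotides=body, id=name)
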