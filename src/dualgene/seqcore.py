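"""Alphabets, the genetic code, substitution matrices and sequence containers.

Everything downstream (overlap geometry, the design dynamic program, the
coding-capacity analysis) works on the small vocabulary defined here: protein
and DNA sequences over the standard alphabets, a replaceable genetic-code
value, Blosum-style substitution matrices, and named partitions of the amino
acids into physico-chemical classes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# Canonical orderings.  Nucleotides are ordered A < C < G < T so that numeric
# codes 0..3 sort identically to the lexicographic tie-break used in design.
NUCLEOTIDES = "ACGT"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
STOP = "*"
GAP_CHARS = frozenset("-.")

NT_INDEX: Mapping[str, int] = {n: i for i, n in enumerate(NUCLEOTIDES)}
AA_INDEX: Mapping[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}
STOP_INDEX = 20  # numeric amino-acid code reserved for stop

CODONS = ["".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3)]


class SequenceError(ValueError):
    """Invalid sequence content."""


class StopCodonError(ValueError):
    """A stop codon occurred where an amino acid was required."""

    def __init__(self, codon_index: int, codon: str, frame: str | None = None):
        self.codon_index = codon_index
        self.codon = codon
        self.frame = frame
        where = f" in frame {frame}" if frame else ""
        super().__init__(
            f"stop codon {codon} at codon index {codon_index}{where}"
        )


@dataclass(frozen=True)
class ProteinSeq:
    """An amino-acid sequence over the 20 standard one-letter codes."""

    id: str
    residues: str

    def __post_init__(self):
        if len(self.residues) < 1:
            raise SequenceError(f"{self.id}: empty protein sequence")
        bad = set(self.residues) - set(AMINO_ACIDS)
        if bad:
            raise SequenceError(
                f"{self.id}: non-standard residues {sorted(bad)} "
                "(stops and ambiguity codes are not allowed)"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def codes(self) -> np.ndarray:
        """Residues as integer codes into ``AMINO_ACIDS``."""
        return np.array([AA_INDEX[a] for a in self.residues], dtype=np.int64)


@dataclass(frozen=True)
class DnaSeq:
    """A DNA sequence over {A, C, G, T}."""

    id: str
    nucleotides: str

    def __post_init__(self):
        if len(self.nucleotides) < 1:
            raise SequenceError(f"{self.id}: empty DNA sequence")
        bad = set(self.nucleotides) - set(NUCLEOTIDES)
        if bad:
            raise SequenceError(f"{self.id}: invalid nucleotides {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.nucleotides)

    def reverse_complement(self) -> "DnaSeq":
        return DnaSeq(self.id + "_rc", reverse_complement(self.nucleotides))


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def complement(nt: str) -> str:
    return _COMPLEMENT[nt]


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[n] for n in reversed(seq))


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid table plus the base-pairing complement map.

    The code is an ordinary value so that alternative codes can be swapped in;
    only the standard nuclear code ships.
    """

    name: str
    table: Mapping[str, str]  # codon -> one-letter aa or "*"
    complement: Mapping[str, str] = field(
        default_factory=lambda: dict(_COMPLEMENT)
    )

    def __post_init__(self):
        missing = set(CODONS) - set(self.table)
        if missing:
            raise ValueError(f"genetic code {self.name}: unmapped codons {sorted(missing)[:3]}...")

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, a in self.table.items() if a == STOP)

    def is_stop(self, codon: str) -> bool:
        return self.table[codon] == STOP

    def codons_for(self, aa: str) -> list[str]:
        """Synonymous codons of ``aa``, in lexicographic order."""
        return sorted(c for c, a in self.table.items() if a == aa)

    def aa_codes(self) -> np.ndarray:
        """Length-64 array: codon index -> aa code (``STOP_INDEX`` for stops)."""
        out = np.empty(64, dtype=np.int64)
        for i, c in enumerate(CODONS):
            aa = self.table[c]
            out[i] = STOP_INDEX if aa == STOP else AA_INDEX[aa]
        return out


def _standard_code() -> GeneticCode:
    table = dict(standard_dna_table.forward_table)
    for c in standard_dna_table.stop_codons:
        table[c] = STOP
    return GeneticCode("standard", table)


STANDARD_CODE = _standard_code()


def codon_index(codon: str) -> int:
    return NT_INDEX[codon[0]] * 16 + NT_INDEX[codon[1]] * 4 + NT_INDEX[codon[2]]


def translate(
    dna: DnaSeq,
    offset: int = 0,
    strand: str = "sense",
    code: GeneticCode = STANDARD_CODE,
) -> ProteinSeq:
    """Translate a reading frame of ``dna``.

    ``antisense`` reverse-complements first, then reads 5'->3' from ``offset``.
    Raises :class:`StopCodonError` (carrying the 0-based codon index) if a stop
    falls inside the translated region.
    """
    if strand not in ("sense", "antisense"):
        raise ValueError(f"unknown strand {strand!r}")
    seq = dna.nucleotides if strand == "sense" else reverse_complement(dna.nucleotides)
    usable = seq[offset:]
    if len(usable) == 0 or len(usable) % 3 != 0:
        raise SequenceError(
            f"{dna.id}: usable length {len(usable)} after offset {offset} "
            "is not a positive multiple of 3"
        )
    residues = []
    for k in range(0, len(usable), 3):
        codon = usable[k : k + 3]
        aa = code.table[codon]
        if aa == STOP:
            raise StopCodonError(k // 3, codon)
        residues.append(aa)
    return ProteinSeq(f"{dna.id}_{strand}+{offset}", "".join(residues))


def back_translate_min(protein: str, code: GeneticCode = STANDARD_CODE) -> str:
    """Deterministic back-translation: lexicographically smallest codon per residue."""
    return "".join(code.codons_for(a)[0] for a in protein)


# ---------------------------------------------------------------------------
# Substitution matrices


class MatrixFormatError(ValueError):
    """Malformed or non-symmetric substitution-matrix input."""


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric 20x20 amino-acid similarity matrix (Blosum62 by default)."""

    name: str
    matrix: np.ndarray  # (20, 20) float, indexed by AA_INDEX

    def __post_init__(self):
        m = self.matrix
        if m.shape != (20, 20):
            raise MatrixFormatError(f"{self.name}: expected 20x20, got {m.shape}")
        if not np.array_equal(m, m.T):
            raise MatrixFormatError(f"{self.name}: matrix is not symmetric")

    def score(self, a: str, b: str) -> float:
        return float(self.matrix[AA_INDEX[a], AA_INDEX[b]])


def _from_biopython(name: str, arr) -> SubstitutionMatrix:
    alpha = list(arr.alphabet)
    missing = set(AMINO_ACIDS) - set(alpha)
    if missing:
        raise MatrixFormatError(f"{name}: missing residues {sorted(missing)}")
    idx = [alpha.index(a) for a in AMINO_ACIDS]
    m = np.asarray(arr, dtype=float)[np.ix_(idx, idx)]
    return SubstitutionMatrix(name, m)


def load_matrix(name_or_path: str | Path = "BLOSUM62") -> SubstitutionMatrix:
    """Load a built-in matrix by name (e.g. ``BLOSUM62``) or an NCBI-format file."""
    name = str(name_or_path)
    if name.upper() in substitution_matrices.load():
        return _from_biopython(name.upper(), substitution_matrices.load(name.upper()))
    path = Path(name_or_path)
    if not path.exists():
        raise MatrixFormatError(f"no built-in matrix or file named {name!r}")
    try:
        arr = substitution_matrices.read(str(path))
    except Exception as exc:  # Biopython raises bare ValueError/IndexError here
        raise MatrixFormatError(f"{path}: cannot parse matrix file: {exc}") from exc
    # Biopython zero-fills absent rows; insist every alphabet row is present.
    row_labels = set()
    for line in path.read_text().splitlines():
        tokens = line.split()
        if len(tokens) >= 2 and len(tokens[0]) == 1:
            try:
                float(tokens[1])
            except ValueError:
                continue  # header line
            row_labels.add(tokens[0])
    missing = (set(arr.alphabet) & set(AMINO_ACIDS)) - row_labels
    if missing:
        raise MatrixFormatError(f"{path}: missing matrix rows for {sorted(missing)}")
    return _from_biopython(path.stem, arr)


# ---------------------------------------------------------------------------
# Amino-acid class schemes


@dataclass(frozen=True)
class ClassScheme:
    """A named partition of the amino-acid alphabet into classes.

    A scheme may leave residues unclassified (``class_of`` returns ``None``),
    as the 4-class capacity scheme does for C and W.
    """

    name: str
    classes: Mapping[str, frozenset[str]]

    def __post_init__(self):
        seen: set[str] = set()
        for label, members in self.classes.items():
            if seen & members:
                raise ValueError(f"{self.name}: classes overlap at {seen & members}")
            seen |= members

    @property
    def classified(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.classes.values():
            out |= members
        return frozenset(out)

    def class_of(self, aa: str) -> str | None:
        for label, members in self.classes.items():
            if aa in members:
                return label
        return None


#: 6-class scheme used for conservation entropies.
SIX_CLASS = ClassScheme(
    "six-class",
    {
        "aliphatic": frozenset("LVIMC"),
        "aromatic": frozenset("FYW"),
        "glycine": frozenset("G"),
        "small": frozenset("ASTP"),
        "acidic-amide": frozenset("EDNQ"),
        "basic": frozenset("KRH"),
    },
)

#: 4-class scheme of the capacity analysis: size x polarity; C and W are
#: deliberately unclassified.
FOUR_CLASS = ClassScheme(
    "four-class",
    {
        "large-polar": frozenset("NKHQRDE"),      # Pi
        "large-nonpolar": frozenset("LFYIM"),     # Phi
        "small-polar": frozenset("SG"),           # pi
        "small-nonpolar": frozenset("TPVA"),      # phi
    },
)

#: Conventional Greek labels for the 4-class scheme, for reports.
FOUR_CLASS_GREEK = {
    "large-polar": "Pi",
    "large-nonpolar": "Phi",
    "small-polar": "pi",
    "small-nonpolar": "phi",
}


# ---------------------------------------------------------------------------
# FASTA I/O (wrapped at 60 columns on output)


def read_fasta_proteins(path: str | Path) -> list[ProteinSeq]:
    recs = list(SeqIO.parse(str(path), "fasta"))
    if not recs:
        raise SequenceError(f"{path}: no FASTA records")
    return [ProteinSeq(r.id, str(r.seq).upper()) for r in recs]


def read_fasta_dna(path: str | Path) -> list[DnaSeq]:
    recs = list(SeqIO.parse(str(path), "fasta"))
    if not recs:
        raise SequenceError(f"{path}: no FASTA records")
    return [DnaSeq(r.id, str(r.seq).upper()) for r in recs]


def write_fasta(seqs: Iterable[ProteinSeq | DnaSeq], path: str | Path) -> None:
    recs = []
    for s in seqs:
        letters = s.residues if isinstance(s, ProteinSeq) else s.nucleotides
        recs.append(SeqRecord(Seq(letters), id=s.id, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(recs)
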