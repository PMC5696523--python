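"""Synthetic fixtures: random proteins, toy alignments, self-consistent targets.

Everything here is reproducible from a seed and constructed so that expected
results are known in closed form:

* random proteins drawn uniformly over the 20 residues, 70-100 residues long
  by default (the domain-length range the designer is aimed at);
* toy alignments whose columns each spread over a prescribed number ``c`` of
  the six conservation classes in equal proportion, so the column entropy is
  exactly ln c and the weight exactly 1/c;
* "self-consistent" target sets obtained by decoding a random stop-free DNA
  region under a scheme — for these a perfect design exists and the optimum
  equals the diagonal-sum bound.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .geometry import OverlapScheme, decode
from .seqcore import (
    AMINO_ACIDS,
    DnaSeq,
    GeneticCode,
    NUCLEOTIDES,
    ProteinSeq,
    SIX_CLASS,
    STANDARD_CODE,
    STOP,
    write_fasta,
)


def random_protein(rng: np.random.Generator, length: int, seq_id: str = "rand") -> ProteinSeq:
    letters = rng.choice(list(AMINO_ACIDS), size=length)
    return ProteinSeq(seq_id, "".join(letters))


def random_proteins(
    rng: np.random.Generator,
    n: int,
    length_range: tuple[int, int] = (70, 100),
) -> list[ProteinSeq]:
    lo, hi = length_range
    return [
        random_protein(rng, int(rng.integers(lo, hi + 1)), f"prot{i:03d}")
        for i in range(n)
    ]


_CLASS_ORDER = sorted(SIX_CLASS.classes)
_CLASS_REP = {label: min(SIX_CLASS.classes[label]) for label in _CLASS_ORDER}


def toy_alignment(
    target: ProteinSeq,
    classes_per_column,
    n_rows: int = 12,
) -> MultipleSeqAlignment:
    """An alignment whose column i spreads equally over ``classes_per_column[i]``
    of the six classes (the target's own class always included), giving column
    entropy exactly ln c.  ``n_rows`` must be divisible by every requested c.
    """
    if isinstance(classes_per_column, int):
        classes_per_column = [classes_per_column] * len(target)
    if len(classes_per_column) != len(target):
        raise ValueError("one class count per target position required")
    rows = [[] for _ in range(n_rows)]
    for a, c in zip(target.residues, classes_per_column):
        if not 1 <= c <= 6:
            raise ValueError(f"classes per column must be in 1..6, got {c}")
        if n_rows % c:
            raise ValueError(f"n_rows={n_rows} not divisible by c={c}")
        k0 = _CLASS_ORDER.index(SIX_CLASS.class_of(a))
        for r in range(n_rows):
            label = _CLASS_ORDER[(k0 + r % c) % 6]
            rows[r].append(a if r % c == 0 else _CLASS_REP[label])
    records = [
        SeqRecord(Seq("".join(row)), id=target.id if r == 0 else f"row{r}", description="")
        for r, row in enumerate(rows)
    ]
    return MultipleSeqAlignment(records)


def self_consistent_targets(
    rng: np.random.Generator,
    scheme: OverlapScheme,
    n_codons: int,
    code: GeneticCode = STANDARD_CODE,
) -> tuple[DnaSeq, list[ProteinSeq]]:
    """A random stop-free region under ``scheme`` and its decoded proteins.

    Windows are sampled left to right, re-drawing each window's free
    nucleotides until no frame's codon in that window is a stop.
    """
    wl = scheme.window_len
    digits: list[int] = []
    for k in range(n_codons):
        fixed = digits[-1:] if (wl == 4 and k > 0) else []
        n_free = wl - len(fixed)
        while True:
            cand = fixed + [int(x) for x in rng.integers(0, 4, size=n_free)]
            window = "".join(NUCLEOTIDES[d] for d in cand)
            if _window_stop_free(window, scheme, code):
                break
        digits.extend(cand if k == 0 or wl == 3 else cand[1:])
    dna = DnaSeq("self_consistent", "".join(NUCLEOTIDES[d] for d in digits))
    proteins = decode(dna, scheme, code=code)
    targets = [
        ProteinSeq(f"target{i}", p.residues) for i, p in enumerate(proteins)
    ]
    return dna, targets


def _window_stop_free(window: str, scheme: OverlapScheme, code: GeneticCode) -> bool:
    for f in scheme.frames:
        nts = [window[p] for p in f.window_positions]
        if f.strand == "antisense":
            nts = [code.complement[x] for x in nts]
        if code.table["".join(nts)] == STOP:
            return False
    return True


@dataclass(frozen=True)
class FixtureSpec:
    n_proteins: int = 4
    length_range: tuple[int, int] = (70, 100)
    alignment_rows: int = 12
    max_classes_per_column: int = 3

    def __post_init__(self):
        if self.n_proteins < 1 or self.length_range[0] < 1:
            raise ValueError(f"invalid fixture spec {self}")
        if self.length_range[0] > self.length_range[1]:
            raise ValueError("empty length range")


def make_fixtures(seed: int, spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Write reproducible protein FASTA and toy alignments; returns the paths.

    Each protein gets an aligned-FASTA family alignment whose per-column class
    counts cycle deterministically through 1..max_classes_per_column, so the
    expected conservation weights are 1, 1/2, ..., in closed form.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    proteins = random_proteins(rng, spec.n_proteins, spec.length_range)
    paths = {"proteins": outdir / "proteins.fasta"}
    write_fasta(proteins, paths["proteins"])
    for p in proteins:
        counts = [(i % spec.max_classes_per_column) + 1 for i in range(len(p))]
        aln = toy_alignment(p, counts, n_rows=spec.alignment_rows)
        path = outdir / f"aln_{p.id}.fasta"
        with open(path, "w") as fh:
            for rec in aln:
                fh.write(f">{rec.id}\n{rec.seq}\n")
        paths[f"aln_{p.id}"] = path
    return paths
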