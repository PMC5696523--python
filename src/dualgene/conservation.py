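"""Per-position conservation weights from family alignments.

The design score weights each target position by how conserved it is among
natural homologs.  Conservation is measured as the Shannon entropy (in nats)
of the alignment column, computed over a reduced 6-class amino-acid alphabet
rather than the 20 types, so the exponentiated entropy e^S ranges from 1
(single class) to 6 (uniform over all classes).  The weight at a position is
e^{-S}: 1 for perfectly conserved columns, down to 1/6 for maximally variable
ones.  Gaps are excluded from the column tally, not treated as a 7th class.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment

from .seqcore import GAP_CHARS, ClassScheme, SIX_CLASS


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class ConservationWeights:
    """Weights (one per target position) and the column entropies behind them."""

    weights: np.ndarray           # (L,), each in [1/6, 1] for the 6-class scheme
    entropies: np.ndarray | None  # (L,) in nats, None for uniform weights

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size < 1:
            raise AlignmentError("weights must be a non-empty vector")
        if np.any(w <= 0) or np.any(w > 1 + 1e-12):
            raise AlignmentError("weights must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.weights)


def column_entropy(column, scheme: ClassScheme = SIX_CLASS) -> float:
    """Shannon entropy (nats) of the class distribution in one alignment column.

    ``column`` is an iterable of residues and gap symbols; gaps are skipped.
    Raises if the column has no residues or contains a residue the scheme does
    not classify.
    """
    counts: Counter[str] = Counter()
    for sym in column:
        if sym in GAP_CHARS:
            continue
        label = scheme.class_of(sym)
        if label is None:
            raise AlignmentError(
                f"residue {sym!r} is not covered by scheme {scheme.name!r}"
            )
        counts[label] += 1
    total = sum(counts.values())
    if total == 0:
        raise AlignmentError("column contains only gaps")
    freqs = np.array(list(counts.values()), dtype=float) / total
    return float(-np.sum(freqs * np.log(freqs)))


def uniform_weights(length: int) -> ConservationWeights:
    """Unit weights: the score reduces to an unweighted Blosum sum."""
    if length < 1:
        raise AlignmentError(f"length must be >= 1, got {length}")
    return ConservationWeights(np.ones(length), None)


def load_alignment(path: str | Path, fmt: str | None = None) -> MultipleSeqAlignment:
    """Read an alignment; format inferred from the suffix unless given.

    Stockholm (.sto/.stk/.stockholm) and aligned FASTA are supported.
    """
    path = Path(path)
    if fmt is None:
        fmt = "stockholm" if path.suffix.lower() in {".sto", ".stk", ".stockholm"} else "fasta"
    try:
        return AlignIO.read(str(path), fmt)
    except Exception as exc:
        raise AlignmentError(f"{path}: cannot read {fmt} alignment: {exc}") from exc


def weights_from_alignment(
    alignment: MultipleSeqAlignment,
    target_id: str,
    scheme: ClassScheme = SIX_CLASS,
) -> ConservationWeights:
    """Weights e^{-S_i} for each ungapped position of the target row.

    Columns where the target row carries a gap are skipped, so the weight
    vector length equals the target's ungapped length.
    """
    target_row = None
    for rec in alignment:
        if rec.id == target_id:
            target_row = str(rec.seq).upper()
            break
    if target_row is None:
        raise AlignmentError(f"target row {target_id!r} not found in alignment")
    columns = [str(rec.seq).upper() for rec in alignment]
    entropies = []
    for j, sym in enumerate(target_row):
        if sym in GAP_CHARS:
            continue
        entropies.append(column_entropy((row[j] for row in columns), scheme))
    if not entropies:
        raise AlignmentError(f"target row {target_id!r} is all gaps")
    S = np.array(entropies)
    return ConservationWeights(np.exp(-S), S)
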