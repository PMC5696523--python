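"""Coding capacity of overlap schemes under the genetic code.

Why do some overlap geometries accommodate arbitrary protein pairs so much
better than others?  Two analyses answer this for the sense:antisense frames:

* ``F = 0`` (codons fully base-paired, central bases opposite): a codon and
  its reverse complement jointly fix both amino acids, so only a small set of
  amino-acid type pairs is encodable at all.
* ``F = -2`` (shared first bases; each strand's central base pairs with the
  other's wobble base): because the wobble base rarely changes the amino
  acid, the two central bases are nearly free.  Classifying residues into
  four classes by size and polarity, almost every (sense class, antisense
  class) combination can be guaranteed regardless of the wobble bases.

"Guaranteed" is operationalized as: there is a choice of the shared
first-base pair and the two independent central bases such that every
stop-free wobble completion yields the required class on both strands.
Unclassified residues (C, W) defeat a guarantee, as do completions that only
avoid the class by being stops on both offered wobbles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd

from .seqcore import (
    ClassScheme,
    FOUR_CLASS,
    FOUR_CLASS_GREEK,
    GeneticCode,
    NUCLEOTIDES,
    STANDARD_CODE,
    STOP,
    reverse_complement,
)


def f0_pair_inventory(code: GeneticCode = STANDARD_CODE) -> frozenset[tuple[str, str]]:
    """Ordered (sense aa, antisense aa) pairs encodable with full base pairing.

    Enumerates the 64 codons; a codon contributes the pair (aa(c),
    aa(revcomp(c))) when neither strand decodes a stop.  The set is closed
    under swap because reverse complementation is an involution.
    """
    pairs = set()
    for c, aa in code.table.items():
        rc_aa = code.table[reverse_complement(c)]
        if aa != STOP and rc_aa != STOP:
            pairs.add((aa, rc_aa))
    return frozenset(pairs)


def f0_pair_count(code: GeneticCode = STANDARD_CODE, ordered: bool = False) -> int:
    """Number of amino-acid type pairs encodable in the F = 0 frame.

    By default counts unordered type pairs {a, b} (the conventional way of
    counting "pairs of amino acid types"); ``ordered=True`` counts directed
    (sense, antisense) pairs, exactly twice as many here since no codon
    decodes the same residue as its reverse complement.
    """
    inv = f0_pair_inventory(code)
    if ordered:
        return len(inv)
    return len({frozenset(p) for p in inv})


# ---------------------------------------------------------------------------
# F = -2: shared first bases, central-vs-wobble pairing


@dataclass(frozen=True)
class CodonCell:
    """Wobble-marginalized content of one (first base, central base) codon stem."""

    amino_acids: frozenset[str]
    classes: frozenset[str]        # classes of the (classified) amino acids
    has_stop: bool
    guaranteed: str | None         # the single class if every stop-free wobble
                                   # lands in it, else None

def _cell(code: GeneticCode, first: str, central: str, classes: ClassScheme) -> CodonCell:
    aas = set()
    has_stop = False
    for w in NUCLEOTIDES:
        aa = code.table[first + central + w]
        if aa == STOP:
            has_stop = True
        else:
            aas.add(aa)
    labels = {classes.class_of(a) for a in aas}
    guaranteed = None
    if aas and len(labels) == 1 and None not in labels:
        guaranteed = labels.pop()
    return CodonCell(frozenset(aas), frozenset(l for l in labels if l), has_stop, guaranteed)


def fm2_class_table(
    code: GeneticCode = STANDARD_CODE,
    classes: ClassScheme = FOUR_CLASS,
) -> dict[tuple[str, str], CodonCell]:
    """All 16 (first base, central base) codon stems with their wobble sets.

    In the F = -2 geometry the sense and antisense codons share base-paired
    first bases while each central base pairs with the *other* strand's
    wobble; both strands' cells therefore come from this one single-strand
    table, the antisense codon read with first base complement(sense first).
    """
    return {
        (f, c): _cell(code, f, c, classes)
        for f in NUCLEOTIDES
        for c in NUCLEOTIDES
    }


@dataclass(frozen=True)
class ClassCombos:
    """Which (sense class, antisense class) combinations F = -2 can guarantee."""

    free: tuple[tuple[str, str], ...]
    excluded: tuple[tuple[str, str], ...]
    partial: tuple[tuple[str, str], ...]  # guaranteed on one strand, attainable
                                          # (but ambiguous) on the other

    @property
    def n_free(self) -> int:
        return len(self.free)


def fm2_free_class_combinations(
    code: GeneticCode = STANDARD_CODE,
    classes: ClassScheme = FOUR_CLASS,
) -> ClassCombos:
    """Count class combinations encodable regardless of the wobble bases.

    A combination (cs, ca) is *free* if some shared first-base pair and some
    pair of central bases guarantee class cs on the sense strand and ca on
    the antisense strand for every stop-free wobble completion.  Combinations
    that are not free but where one strand can be guaranteed while the other
    attains the class ambiguously are reported as *partial*.
    """
    table = fm2_class_table(code, classes)
    labels = sorted(classes.classes)
    free, excluded, partial = [], [], []
    for cs, ca in itertools.product(labels, repeat=2):
        is_free = is_partial = False
        for f in NUCLEOTIDES:
            fa = code.complement[f]
            for c2, c2a in itertools.product(NUCLEOTIDES, repeat=2):
                sense, anti = table[(f, c2)], table[(fa, c2a)]
                if sense.guaranteed == cs and anti.guaranteed == ca:
                    is_free = True
                if (sense.guaranteed == cs and ca in anti.classes) or (
                    anti.guaranteed == ca and cs in sense.classes
                ):
                    is_partial = True
        if is_free:
            free.append((cs, ca))
        else:
            excluded.append((cs, ca))
            if is_partial:
                partial.append((cs, ca))
    return ClassCombos(tuple(free), tuple(excluded), tuple(partial))


# ---------------------------------------------------------------------------
# Reports


def _rna(nt: str) -> str:
    return "U" if nt == "T" else nt


def fm2_table_frame(code: GeneticCode = STANDARD_CODE, classes: ClassScheme = FOUR_CLASS) -> pd.DataFrame:
    """The F = -2 stem table as a tidy DataFrame (RNA letters, Greek classes)."""
    rows = []
    table = fm2_class_table(code, classes)
    for (f, c), cell in sorted(table.items()):
        rows.append(
            {
                "first": _rna(f),
                "first_paired": _rna(code.complement[f]),
                "central": _rna(c),
                "amino_acids": ",".join(sorted(cell.amino_acids)),
                "classes": ",".join(
                    sorted(FOUR_CLASS_GREEK.get(l, l) for l in cell.classes)
                ),
                "has_stop": cell.has_stop,
                "guaranteed_class": FOUR_CLASS_GREEK.get(cell.guaranteed, cell.guaranteed)
                if cell.guaranteed
                else "",
            }
        )
    return pd.DataFrame(rows)


def capacity_summary(code: GeneticCode = STANDARD_CODE) -> str:
    """One-page text summary of both capacity counts."""
    inv = f0_pair_inventory(code)
    combos = fm2_free_class_combinations(code)
    greek = lambda p: f"({FOUR_CLASS_GREEK[p[0]]}, {FOUR_CLASS_GREEK[p[1]]})"
    lines = [
        f"Genetic code: {code.name}",
        "",
        "F = 0 (codons fully base-paired):",
        f"  encodable amino-acid type pairs: {f0_pair_count(code)} of {20 * 20 // 2 + 10}"
        f" unordered ({len(inv)} ordered of 400)",
        "",
        "F = -2 (shared first bases, central-vs-wobble pairing):",
        f"  class combinations guaranteed on both strands: {combos.n_free} of 16",
        f"  not freely encodable: {', '.join(greek(p) for p in combos.excluded)}",
        f"  of those, guaranteed on one strand only: "
        f"{', '.join(greek(p) for p in combos.partial) or 'none'}",
        "",
    ]
    return "\n".join(lines)
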