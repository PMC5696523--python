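"""Overlap reading frames, quartet windows, and placements.

Frame conventions
-----------------
The reference protein is read on the sense strand on the codon grid starting
at nucleotide 0.  A second (or third) protein sits in one of five frames F:

* ``F = 0``  — antisense, in register: each codon base-pairs with exactly one
  reference codon.
* ``F = -2`` — antisense, shifted so that each reference codon's middle base
  pairs with the other frame's wobble base and vice versa; two consecutive
  codons on opposite strands share their first bases.
* ``F = +1`` — sense strand, codon grid shifted +1 nucleotide.
* ``F = -1`` and ``F = +2`` exist geometrically but their codons span two
  quartet windows, which the 4-nucleotide/1-state machinery cannot represent;
  ``F = +2`` is equivalent to ``F = +1`` with the two proteins' roles swapped,
  so only ``F = +1`` is built.  The two remaining frames raise
  :class:`UnsupportedSchemeError`.

Quartet windows
---------------
The overlap region is represented as N linked windows, one per reference
codon.  With any shifted frame present the window is 4 nucleotides, and
consecutive windows share one nucleotide: ``Q_{k+1}(1) = Q_k(4)``.  With only
the in-register antisense frame the window degenerates to the 3-nucleotide
codon and no linkage exists.  A shifted frame's last codon needs one
nucleotide past the final reference codon; that nucleotide is part of the
optimized region, so the region length is ``3N + c`` with ``c`` in {0, 1}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqcore import (
    DnaSeq,
    GeneticCode,
    ProteinSeq,
    STANDARD_CODE,
    STOP,
    StopCodonError,
    complement,
)

SUPPORTED_FRAMES = ("ref", "0", "-2", "+1")
UNSUPPORTED_FRAMES = ("-1", "+2")


class UnsupportedSchemeError(ValueError):
    pass


class PlacementError(ValueError):
    pass


@dataclass(frozen=True)
class FrameSpec:
    """One reading frame: label, strand, and its codon's window positions.

    ``window_positions`` lists the 0-based positions inside a window that form
    the frame's codon, in the codon's own 5'->3' order (antisense positions
    are complemented when decoding).
    """

    label: str

    def __post_init__(self):
        if self.label not in SUPPORTED_FRAMES + UNSUPPORTED_FRAMES:
            raise UnsupportedSchemeError(f"unknown frame label {self.label!r}")

    @property
    def strand(self) -> str:
        return "antisense" if self.label in ("0", "-1", "-2") else "sense"

    @property
    def is_reference(self) -> bool:
        return self.label == "ref"

    @property
    def window_positions(self) -> tuple[int, int, int]:
        return {
            "ref": (0, 1, 2),
            "+1": (1, 2, 3),
            "0": (2, 1, 0),
            "-2": (3, 2, 1),
        }[self.label]


REF = FrameSpec("ref")


def frame(label: str | int) -> FrameSpec:
    """Frame factory accepting ``"ref"`` or an integer/str F label."""
    if isinstance(label, int):
        label = f"+{label}" if label > 0 else str(label)
    return FrameSpec(label)


@dataclass(frozen=True)
class OverlapScheme:
    """An ordered set of frames sharing one DNA segment; frames[0] is the reference."""

    frames: tuple[FrameSpec, ...]

    @property
    def window_len(self) -> int:
        # Degenerate 3-nt windows only for the pure in-register antisense pair.
        labels = {f.label for f in self.frames}
        return 3 if labels == {"ref", "0"} else 4

    @property
    def extra_nt(self) -> int:
        return 1 if self.window_len == 4 else 0

    @property
    def name(self) -> str:
        return "/".join("F" + f.label if not f.is_reference else "ref" for f in self.frames)


def build_scheme(frames) -> OverlapScheme:
    """Validate and build an overlap scheme from frame labels or FrameSpecs.

    Supports 1-3 frames (more would require quintet windows).  The reference
    frame must be present; frames must be distinct and individually
    representable in a 4-nucleotide window.
    """
    specs = tuple(f if isinstance(f, FrameSpec) else frame(f) for f in frames)
    if len(specs) > 3:
        raise UnsupportedSchemeError(
            f"{len(specs)} frames would require quintet windows; at most 3 supported"
        )
    if len(specs) < 1 or not any(f.is_reference for f in specs):
        raise UnsupportedSchemeError("scheme must include the reference frame")
    labels = [f.label for f in specs]
    if len(set(labels)) != len(labels):
        raise UnsupportedSchemeError(f"duplicate frames in {labels}")
    for f in specs:
        if f.label in UNSUPPORTED_FRAMES:
            raise UnsupportedSchemeError(
                f"frame {f.label} codons span two windows; use F=+1 with the "
                "proteins' roles swapped instead of F=+2"
            )
    # keep the reference first, preserving the order of the rest
    ordered = tuple(sorted(specs, key=lambda f: not f.is_reference))
    return OverlapScheme(ordered)


PAIR_F0 = build_scheme(["ref", "0"])
PAIR_FM2 = build_scheme(["ref", "-2"])
PAIR_FP1 = build_scheme(["ref", "+1"])
TRIPLE_DEFAULT = build_scheme(["ref", "-2", "+1"])


@dataclass(frozen=True)
class Placement:
    """Where the embedded (shorter) coding region starts, in codons of the longer."""

    offset: int
    mode: str = "explicit-offset"

    def __post_init__(self):
        if self.offset < 0:
            raise PlacementError(f"negative placement offset {self.offset}")


def enumerate_placements(len_long: int, len_short: int, mode: str = "ends") -> list[Placement]:
    """Placements of a ``len_short``-codon region inside ``len_long`` codons.

    ``ends`` mode gives the start-aligned and end-aligned placements (one if
    the lengths are equal); ``exhaustive`` gives all of them.
    """
    if len_short > len_long:
        raise PlacementError(f"short ({len_short}) exceeds long ({len_long})")
    if len_short < 1:
        raise PlacementError("lengths must be >= 1 codon")
    last = len_long - len_short
    if mode == "ends":
        offsets = [0] if last == 0 else [0, last]
        return [Placement(o, "start-aligned" if o == 0 else "end-aligned") for o in offsets]
    if mode == "exhaustive":
        return [Placement(o) for o in range(last + 1)]
    raise PlacementError(f"unknown placement mode {mode!r}")


@dataclass(frozen=True)
class RegionLayout:
    """Resolved geometry of one design problem.

    ``res_maps[f][k]`` is the residue index (into target ``f``) encoded by
    window ``k``.  ``allowed_first``/``allowed_last`` constrain the region's
    terminal nucleotides when a flanking codon of a longer protein shares
    them (so the flank stays back-translatable).
    """

    scheme: OverlapScheme
    placement: Placement
    lengths: tuple[int, ...]
    n_windows: int
    res_maps: tuple[np.ndarray, ...]
    allowed_first: frozenset[str] | None = None
    allowed_last: frozenset[str] | None = None

    @property
    def region_len(self) -> int:
        return 3 * self.n_windows + self.scheme.extra_nt


def _first_nts(code: GeneticCode, aa: str) -> frozenset[str]:
    return frozenset(c[0] for c in code.codons_for(aa))


def _last_nts(code: GeneticCode, aa: str) -> frozenset[str]:
    return frozenset(c[2] for c in code.codons_for(aa))


def region_layout(
    scheme: OverlapScheme,
    placement: Placement,
    targets: list[ProteinSeq],
    code: GeneticCode = STANDARD_CODE,
) -> RegionLayout:
    """Resolve window count, residue maps and edge constraints for a design."""
    if len(targets) != len(scheme.frames):
        raise PlacementError(
            f"{len(scheme.frames)} frames but {len(targets)} target proteins"
        )
    lengths = tuple(len(t) for t in targets)

    if len(scheme.frames) == 3:
        if len(set(lengths)) != 1:
            raise PlacementError(
                f"triple designs require equal-length targets, got {lengths}"
            )
        if placement.offset != 0:
            raise PlacementError("triple designs support only offset 0")
        N = lengths[0]
        maps = []
        for f in scheme.frames:
            if f.strand == "sense":
                maps.append(np.arange(N))
            else:
                maps.append(np.arange(N - 1, -1, -1))
        return RegionLayout(scheme, placement, lengths, N, tuple(maps))

    if len(scheme.frames) == 1:
        return RegionLayout(scheme, placement, lengths, lengths[0], (np.arange(lengths[0]),))

    other = scheme.frames[1]
    Lr, Lo = lengths
    off = placement.offset
    allowed_first = allowed_last = None

    if Lr <= Lo:
        # reference protein fully covered; the other protein extends beyond
        N = Lr
        if off + N > Lo:
            raise PlacementError(f"offset {off} pushes the overlap past the longer protein")
        ref_map = np.arange(N)
        if other.strand == "sense":  # F = +1
            other_map = off + np.arange(N)
            if off > 0:
                # the preceding codon's wobble base is the region's first nt
                allowed_first = _last_nts(code, targets[1].residues[off - 1])
        else:
            other_map = off + np.arange(N - 1, -1, -1)
            if other.label == "-2" and off + N < Lo:
                # the next antisense codon's first base pairs the region's first nt
                aa = targets[1].residues[off + N]
                allowed_first = frozenset(complement(n) for n in _first_nts(code, aa))
    else:
        # the other protein is embedded inside the reference protein
        N = Lo
        if off + N > Lr:
            raise PlacementError(f"offset {off} pushes the overlap past the reference")
        ref_map = off + np.arange(N)
        if other.strand == "sense":
            other_map = np.arange(N)
        else:
            other_map = np.arange(N - 1, -1, -1)
        if scheme.extra_nt and off + N < Lr:
            # the extra nucleotide is the first base of the next reference codon
            allowed_last = _first_nts(code, targets[0].residues[off + N])

    return RegionLayout(
        scheme, placement, lengths, N, (ref_map, other_map), allowed_first, allowed_last
    )


# ---------------------------------------------------------------------------
# Window decomposition and decoding


def windows_of(dna: DnaSeq, scheme: OverlapScheme) -> list[str]:
    """The linked window strings of a region (``Q_{k+1}(1) = Q_k(4)``)."""
    w = scheme.window_len
    seq = dna.nucleotides
    n = (len(seq) - scheme.extra_nt) // 3
    if len(seq) != 3 * n + scheme.extra_nt or n < 1:
        raise PlacementError(
            f"region length {len(seq)} incompatible with {scheme.name}"
        )
    return [seq[3 * k : 3 * k + w] for k in range(n)]


def decode(
    dna: DnaSeq,
    scheme: OverlapScheme,
    placement: Placement | None = None,
    code: GeneticCode = STANDARD_CODE,
) -> list[ProteinSeq]:
    """Read every frame of an overlap region; antisense frames 5'->3' on the
    complementary strand.  Raises :class:`StopCodonError` naming the frame and
    codon if any frame contains a stop.
    """
    seq = dna.nucleotides
    n = (len(seq) - scheme.extra_nt) // 3
    if len(seq) != 3 * n + scheme.extra_nt or n < 1:
        raise PlacementError(
            f"region length {len(seq)} incompatible with {scheme.name}"
        )
    proteins = []
    for f in scheme.frames:
        codons = []
        for k in range(n):
            base = 3 * k
            nts = [seq[base + p] for p in f.window_positions]
            if f.strand == "antisense":
                nts = [complement(x) for x in nts]
            codons.append("".join(nts))
        if f.strand == "antisense":
            codons.reverse()  # the frame's 5' end is at the region's 3' end
        residues = []
        for i, c in enumerate(codons):
            aa = code.table[c]
            if aa == STOP:
                raise StopCodonError(i, c, frame=f.label)
            residues.append(aa)
        proteins.append(ProteinSeq(f"{dna.id}|frame_{f.label}", "".join(residues)))
    return proteins
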