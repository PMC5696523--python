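"""Exact design of overlapping coding sequences.

Given 2-3 target proteins and an overlap scheme, find the DNA region whose
frames decode to homologs maximizing the conservation-weighted Blosum score

    S = sum_i p_i B(X_i, X'_i) + sum_j q_j B(Y_j, Y'_j) [+ Z term]

For the in-register antisense pair (F = 0) each base-paired codon pair is
independent, so the optimum is a per-codon argmax over the 64 codons.  For
every other scheme the region is a chain of linked 4-nucleotide windows
(quartets) and the optimum is found by dynamic programming over the 4-valued
window state (the window's last nucleotide), followed by a traceback.  The
cost is linear in the number of reference codons: each column examines
4 states x 64 windows.

Stop codons in any encoded frame are excluded via a minus-infinity sentinel.
Ties are broken toward the lexicographically smallest nucleotide string
(A < C < G < T), making designs deterministic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conservation import ConservationWeights, uniform_weights
from .geometry import (
    OverlapScheme,
    PAIR_F0,
    Placement,
    RegionLayout,
    build_scheme,
    decode,
    enumerate_placements,
    region_layout,
)
from .seqcore import (
    DnaSeq,
    GeneticCode,
    NT_INDEX,
    NUCLEOTIDES,
    ProteinSeq,
    STANDARD_CODE,
    STOP_INDEX,
    SubstitutionMatrix,
    load_matrix,
)

NEG_INF = float("-inf")


@dataclass(frozen=True)
class ScoringModel:
    """Substitution matrix plus one conservation-weight vector per target."""

    matrix: SubstitutionMatrix
    weights: tuple[ConservationWeights, ...]

    @classmethod
    def unit(cls, n_targets: int, lengths, matrix: SubstitutionMatrix | None = None):
        matrix = matrix or load_matrix("BLOSUM62")
        return cls(matrix, tuple(uniform_weights(L) for L in lengths[:n_targets]))

    def validate(self, targets: list[ProteinSeq]) -> None:
        if len(self.weights) != len(targets):
            raise ValueError(
                f"{len(self.weights)} weight vectors for {len(targets)} targets"
            )
        for w, t in zip(self.weights, targets):
            if len(w) != len(t):
                raise ValueError(
                    f"weight vector length {len(w)} != target {t.id} length {len(t)}"
                )

    def padded(self) -> np.ndarray:
        """(20, 21) matrix with a -inf column for the stop code."""
        m = np.full((20, 21), NEG_INF)
        m[:, :20] = self.matrix.matrix
        return m


def unit_model(targets: list[ProteinSeq], matrix: SubstitutionMatrix | None = None) -> ScoringModel:
    return ScoringModel.unit(len(targets), [len(t) for t in targets], matrix)


@dataclass(frozen=True)
class DPTable:
    """The 4xN score table with per-cell optimal windows.

    ``best[k, s]`` is the window (as a base-4 integer, digits in sequence
    order) achieving ``scores[k, s]``; its first digit is the back-pointer to
    the previous column's state.
    """

    scores: np.ndarray  # (N, 4)
    best: np.ndarray    # (N, 4) window indices

    def prev_state(self, k: int, s: int) -> int:
        return int(self.best[k, s]) >> 6


@dataclass(frozen=True)
class DesignResult:
    """A designed overlap region and everything needed to audit it."""

    dna: DnaSeq
    proteins: tuple[ProteinSeq, ...]       # designed homolog, overlap region only
    full_proteins: tuple[ProteinSeq, ...]  # overlap splice + copied flanks
    score: float                           # optimized overlap score (Eq-style sum)
    window_scores: np.ndarray
    scheme: OverlapScheme
    placement: Placement
    identity: tuple[float, ...]            # % identity to target, overlap region
    similarity: tuple[float, ...]          # % Blosum-positive positions
    flank_score: float                     # diagonal score of copied flanks (not in `score`)
    table: DPTable | None = None


# ---------------------------------------------------------------------------
# Window scoring


def _frame_codon_indices(scheme: OverlapScheme) -> list[np.ndarray]:
    """Per frame: array mapping window index -> codon index (0..63)."""
    wl = scheme.window_len
    n_windows = 4 ** wl
    q = np.arange(n_windows)
    digits = [(q >> (2 * (wl - 1 - p))) & 3 for p in range(wl)]
    out = []
    for f in scheme.frames:
        d = [digits[p] for p in f.window_positions]
        if f.strand == "antisense":
            d = [3 - x for x in d]
        out.append(d[0] * 16 + d[1] * 4 + d[2])
    return out


def _score_tables(
    layout: RegionLayout,
    targets: list[ProteinSeq],
    model: ScoringModel,
    code: GeneticCode,
) -> np.ndarray:
    """(N, 4^window_len) window scores, -inf where any frame hits a stop or an
    edge constraint is violated."""
    scheme = layout.scheme
    wl = scheme.window_len
    aa64 = code.aa_codes()
    bpad = model.padded()
    cidx = _frame_codon_indices(scheme)
    n = layout.n_windows
    tables = np.zeros((n, 4 ** wl))
    for fi, f in enumerate(scheme.frames):
        aa = aa64[cidx[fi]]                       # (4^wl,) decoded aa codes
        res = layout.res_maps[fi]                 # (N,) target residue indices
        t_codes = targets[fi].codes()[res]        # (N,)
        w = np.asarray(model.weights[fi].weights)[res]  # (N,)
        contrib = bpad[t_codes[:, None], aa[None, :]]   # (N, 4^wl)
        tables += np.where(np.isneginf(contrib), NEG_INF, w[:, None] * contrib)
    q = np.arange(4 ** wl)
    if layout.allowed_first is not None:
        ok = np.isin(q >> (2 * (wl - 1)), [NT_INDEX[x] for x in layout.allowed_first])
        tables[0, ~ok] = NEG_INF
    if layout.allowed_last is not None:
        ok = np.isin(q & 3, [NT_INDEX[x] for x in layout.allowed_last])
        tables[-1, ~ok] = NEG_INF
    return tables


def window_score(
    window: str,
    k: int,
    scheme: OverlapScheme,
    placement: Placement,
    targets: list[ProteinSeq],
    model: ScoringModel,
    code: GeneticCode = STANDARD_CODE,
) -> float:
    """Contribution s(Q) of window k's codons to the total score (-inf on a stop)."""
    if len(window) != scheme.window_len:
        raise ValueError(f"window {window!r} has length {len(window)}, expected {scheme.window_len}")
    layout = region_layout(scheme, placement, targets, code)
    total = 0.0
    for fi, f in enumerate(scheme.frames):
        nts = [window[p] for p in f.window_positions]
        if f.strand == "antisense":
            nts = [code.complement[x] for x in nts]
        aa = code.table["".join(nts)]
        if aa == "*":
            return NEG_INF
        res = int(layout.res_maps[fi][k])
        w = float(model.weights[fi].weights[res])
        total += w * model.matrix.score(targets[fi].residues[res], aa)
    return total


# ---------------------------------------------------------------------------
# Result assembly


def _digits_to_dna(digits: list[int]) -> str:
    return "".join(NUCLEOTIDES[d] for d in digits)


def _make_result(
    region: str,
    layout: RegionLayout,
    targets: list[ProteinSeq],
    model: ScoringModel,
    window_scores: np.ndarray,
    code: GeneticCode,
    table: DPTable | None,
    dna_id: str,
) -> DesignResult:
    scheme = layout.scheme
    dna = DnaSeq(dna_id, region)
    designed = decode(dna, scheme, layout.placement, code)
    total = float(np.sum(window_scores))

    score = 0.0
    idents, sims, fulls = [], [], []
    flank = 0.0
    for fi, t in enumerate(targets):
        res = layout.res_maps[fi]
        lo, hi = int(res.min()), int(res.max())
        d = designed[fi].residues
        assert len(d) == hi - lo + 1
        w = np.asarray(model.weights[fi].weights)
        match = 0
        pos = 0
        for i, a in enumerate(d):
            tgt = t.residues[lo + i]
            b = model.matrix.score(tgt, a)
            score += w[lo + i] * b
            match += tgt == a
            pos += b > 0
        idents.append(100.0 * match / len(d))
        sims.append(100.0 * pos / len(d))
        for j in itertools.chain(range(0, lo), range(hi + 1, len(t))):
            flank += w[j] * model.matrix.score(t.residues[j], t.residues[j])
        fulls.append(
            ProteinSeq(t.id + "_designed", t.residues[:lo] + d + t.residues[hi + 1 :])
        )
    # audit: the DP total must equal the score recomputed from the decoded proteins
    if not np.isclose(score, total, rtol=1e-9, atol=1e-9):
        raise AssertionError(
            f"score audit failed: windows sum to {total}, recomputed {score}"
        )
    return DesignResult(
        dna=dna,
        proteins=tuple(designed),
        full_proteins=tuple(fulls),
        score=score,
        window_scores=window_scores,
        scheme=scheme,
        placement=layout.placement,
        identity=tuple(idents),
        similarity=tuple(sims),
        flank_score=flank,
        table=table,
    )


# ---------------------------------------------------------------------------
# Exact optimization


def design_dp(
    targets: list[ProteinSeq],
    scheme: OverlapScheme,
    placement: Placement | None = None,
    model: ScoringModel | None = None,
    code: GeneticCode = STANDARD_CODE,
    keep_table: bool = False,
) -> DesignResult:
    """Globally optimal design for any supported scheme.

    Runs the quartet DP with traceback; for the degenerate in-register
    antisense pair the windows are unlinked and the DP reduces to independent
    per-codon maxima.
    """
    placement = placement or Placement(0, "start-aligned")
    model = model or unit_model(targets)
    model.validate(targets)
    layout = region_layout(scheme, placement, targets, code)
    tables = _score_tables(layout, targets, model, code)
    n = layout.n_windows
    wl = scheme.window_len
    dna_id = "design_" + scheme.name.replace("/", "_")

    if wl == 3:
        # unlinked: closed form, one argmax over 64 codons per position
        choice = np.argmax(tables, axis=1)  # first max = lex smallest codon
        wscores = tables[np.arange(n), choice]
        if np.any(np.isneginf(wscores)):
            raise AssertionError("no stop-free codon at some position")
        digits: list[int] = []
        for q in choice:
            digits.extend([(int(q) >> 4) & 3, (int(q) >> 2) & 3, int(q) & 3])
        return _make_result(
            _digits_to_dna(digits), layout, targets, model, wscores, code, None, dna_id
        )

    q = np.arange(256)
    first = q >> 6
    M = np.zeros((n, 4))
    best = np.zeros((n, 4), dtype=np.int64)
    m_prev = np.zeros(4)
    for k in range(n):
        cand = m_prev[first] + tables[k]
        for s in range(4):
            sub = cand[s::4]  # windows ending in state s, ascending (lex) order
            i = int(np.argmax(sub))
            M[k, s] = sub[i]
            best[k, s] = s + 4 * i
        m_prev = M[k]
    s_star = int(np.argmax(M[n - 1]))
    if np.isneginf(M[n - 1, s_star]):
        raise AssertionError("no stop-free window chain exists")
    # traceback, concatenating optimal windows backwards
    chosen = np.empty(n, dtype=np.int64)
    s = s_star
    for k in range(n - 1, -1, -1):
        chosen[k] = best[k, s]
        s = int(chosen[k]) >> 6
    digits = []
    for k, qk in enumerate(chosen):
        d = [(int(qk) >> (2 * (3 - p))) & 3 for p in range(4)]
        digits.extend(d if k == 0 else d[1:])
    wscores = tables[np.arange(n), chosen]
    table = DPTable(M, best) if keep_table else None
    return _make_result(
        _digits_to_dna(digits), layout, targets, model, wscores, code, table, dna_id
    )


def design_f0(
    x: ProteinSeq,
    y: ProteinSeq,
    placement: Placement | None = None,
    model: ScoringModel | None = None,
    code: GeneticCode = STANDARD_CODE,
) -> DesignResult:
    """Closed-form F = 0 design: per base-paired codon pair, the best of 64 codons."""
    return design_dp([x, y], PAIR_F0, placement, model, code)


def diagonal_bound(
    targets: list[ProteinSeq],
    layout: RegionLayout,
    model: ScoringModel,
) -> float:
    """Upper bound on the overlap score: every position decoded identically."""
    total = 0.0
    for fi, t in enumerate(targets):
        res = layout.res_maps[fi]
        w = np.asarray(model.weights[fi].weights)[res]
        codes = t.codes()[res]
        total += float(np.sum(w * model.matrix.matrix[codes, codes]))
    return total


def brute_force_design(
    targets: list[ProteinSeq],
    scheme: OverlapScheme,
    placement: Placement | None = None,
    model: ScoringModel | None = None,
    code: GeneticCode = STANDARD_CODE,
    max_nt: int = 12,
) -> DesignResult:
    """Exact maximum by enumerating every stop-free region sequence.

    A test oracle: scores each of the 4^L candidate regions directly from its
    decoded codons (no window chaining), so it is independent of the DP.
    Refuses regions longer than ``max_nt`` nucleotides.
    """
    placement = placement or Placement(0, "start-aligned")
    model = model or unit_model(targets)
    model.validate(targets)
    layout = region_layout(scheme, placement, targets, code)
    L = layout.region_len
    if L > max_nt:
        raise ValueError(f"region of {L} nt exceeds brute-force guard ({max_nt})")
    aa64 = code.aa_codes()
    bpad = model.padded()
    bpad_safe = np.where(np.isneginf(bpad), 0.0, bpad)

    # per-frame global nucleotide positions and per-codon targets/weights
    frames = []
    for fi, f in enumerate(layout.scheme.frames):
        res = layout.res_maps[fi]
        t_codes = targets[fi].codes()[res]
        w = np.asarray(model.weights[fi].weights)[res]
        pos = np.array(
            [[3 * k + p for p in f.window_positions] for k in range(layout.n_windows)]
        )
        frames.append((f.strand == "antisense", pos, t_codes, w))

    shifts = 2 * np.arange(L - 1, -1, -1)
    best_val, best_q = NEG_INF, -1
    chunk = 4 ** 9
    for start in range(0, 4 ** L, chunk):
        qs = np.arange(start, min(start + chunk, 4 ** L))
        digits = ((qs[:, None] >> shifts[None, :]) & 3).astype(np.int64)
        scores = np.zeros(len(qs))
        valid = np.ones(len(qs), dtype=bool)
        for anti, pos, t_codes, w in frames:
            for k in range(layout.n_windows):
                d = digits[:, pos[k]]
                if anti:
                    d = 3 - d
                aa = aa64[d[:, 0] * 16 + d[:, 1] * 4 + d[:, 2]]
                valid &= aa != STOP_INDEX
                scores += w[k] * bpad_safe[t_codes[k], aa]
        if layout.allowed_first is not None:
            valid &= np.isin(digits[:, 0], [NT_INDEX[x] for x in layout.allowed_first])
        if layout.allowed_last is not None:
            valid &= np.isin(digits[:, -1], [NT_INDEX[x] for x in layout.allowed_last])
        scores[~valid] = NEG_INF
        i = int(np.argmax(scores))
        if scores[i] > best_val:  # strict: first/lowest q wins ties globally
            best_val, best_q = float(scores[i]), int(qs[i])
    if best_q < 0 or best_val == NEG_INF:
        raise AssertionError("no stop-free sequence exists for this region")
    digits = [(best_q >> int(s)) & 3 for s in shifts]
    # window contributions recomputed so the shared result audit applies
    region = _digits_to_dna(digits)
    tables = _score_tables(layout, targets, model, code)
    wl = layout.scheme.window_len
    widx = np.empty(layout.n_windows, dtype=np.int64)
    for k in range(layout.n_windows):
        w_digits = digits[3 * k : 3 * k + wl]
        widx[k] = int("".join(str(d) for d in w_digits), 4)
    wscores = tables[np.arange(layout.n_windows), widx]
    return _make_result(
        region, layout, targets, model, wscores, code, None, "brute_force"
    )


# ---------------------------------------------------------------------------
# Screening many pairs


def plan_screen(n_items: int, n_schemes: int = 3, runs_per_scheme: int = 2) -> dict:
    """Run-count arithmetic for a screen over all unordered pairs (self included)."""
    pairs = n_items * (n_items + 1) // 2
    return {
        "items": n_items,
        "pairs": pairs,
        "schemes": n_schemes,
        "runs_per_scheme": runs_per_scheme,
        "runs": pairs * n_schemes * runs_per_scheme,
    }


def all_pairs(proteins: list[ProteinSeq]) -> list[tuple[ProteinSeq, ProteinSeq]]:
    """All unordered pairs, self-pairs included."""
    return [
        (proteins[i], proteins[j])
        for i in range(len(proteins))
        for j in range(i, len(proteins))
    ]


def _runs_for(scheme, a, b, placement_mode):
    """(ref_target, other_target, placement, variant label) runs for one pair."""
    if any(f.label == "+1" for f in scheme.frames if not f.is_reference) and len(scheme.frames) == 2:
        # sense:sense: beginnings aligned, either protein takes the shifted frame
        runs = [(a, b, Placement(0, "start-aligned"), f"{b.id}-shifted")]
        if a.id != b.id or a.residues != b.residues:
            runs.append((b, a, Placement(0, "start-aligned"), f"{a.id}-shifted"))
        else:
            runs.append((a, b, Placement(0, "start-aligned"), f"{a.id}-shifted"))
        return runs
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    placements = (
        enumerate_placements(len(long_), len(short), "ends")
        if placement_mode == "ends"
        else placement_mode
    )
    return [(short, long_, p, p.mode) for p in placements]


def design_screen(
    pairs: list[tuple[ProteinSeq, ProteinSeq]],
    schemes: list[OverlapScheme] | None = None,
    placement_mode="ends",
    matrix: SubstitutionMatrix | None = None,
    weights: dict[str, ConservationWeights] | None = None,
) -> pd.DataFrame:
    """One design run per (pair, scheme, placement); failures recorded per row.

    ``weights`` maps protein ids to conservation weights; unlisted proteins
    get unit weights.
    """
    if schemes is None:
        schemes = [build_scheme(["ref", f]) for f in ("-2", "0", "+1")]
    matrix = matrix or load_matrix("BLOSUM62")
    weights = weights or {}
    rows = []
    for a, b in pairs:
        for scheme in schemes:
            for ref_t, other_t, placement, variant in _runs_for(scheme, a, b, placement_mode):
                targets = [ref_t, other_t]
                model = ScoringModel(
                    matrix,
                    tuple(
                        weights.get(t.id, uniform_weights(len(t))) for t in targets
                    ),
                )
                row = {
                    "id_ref": ref_t.id,
                    "id_other": other_t.id,
                    "scheme": scheme.name,
                    "placement": placement.offset,
                    "variant": variant,
                }
                try:
                    res = design_dp(targets, scheme, placement, model)
                    row.update(
                        score=res.score,
                        flank_score=res.flank_score,
                        identity_ref=res.identity[0],
                        identity_other=res.identity[1],
                        similarity_ref=res.similarity[0],
                        similarity_other=res.similarity[1],
                        dna=res.dna.nucleotides,
                        error="",
                    )
                except Exception as exc:  # recorded, not fatal
                    row.update(score=np.nan, error=str(exc))
                rows.append(row)
    return pd.DataFrame(rows)
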