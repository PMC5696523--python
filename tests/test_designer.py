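"""The exact optimizer: closed form, quartet DP, oracle agreement, screening."""

import itertools

import numpy as np
import pytest

from dualgene.conservation import ConservationWeights, uniform_weights
from dualgene.designer import (
    NEG_INF,
    ScoringModel,
    all_pairs,
    brute_force_design,
    design_dp,
    design_f0,
    design_screen,
    diagonal_bound,
    plan_screen,
    unit_model,
    window_score,
)
from dualgene.fixtures import random_protein, self_consistent_targets
from dualgene.geometry import (
    PAIR_F0,
    PAIR_FM2,
    PAIR_FP1,
    Placement,
    TRIPLE_DEFAULT,
    enumerate_placements,
    region_layout,
)
from dualgene.seqcore import CODONS, ProteinSeq, STANDARD_CODE, complement

SCHEMES = [PAIR_F0, PAIR_FM2, PAIR_FP1, TRIPLE_DEFAULT]
PLC0 = Placement(0, "start-aligned")


def _random_model(rng, targets, matrix, real_weights):
    if not real_weights:
        return unit_model(targets, matrix)
    ws = tuple(
        ConservationWeights(rng.uniform(1 / 6, 1.0, size=len(t)), None)
        for t in targets
    )
    return ScoringModel(matrix, ws)


def _random_instance(rng, scheme, matrix, real_weights=False, max_codons=3):
    n_frames = len(scheme.frames)
    if n_frames == 3:
        n = int(rng.integers(1, max_codons))
        targets = [random_protein(rng, n, f"t{i}") for i in range(3)]
        placement = PLC0
    else:
        n_short = int(rng.integers(1, max_codons + 1))
        n_long = n_short + int(rng.integers(0, 2))
        a = random_protein(rng, n_short, "short")
        b = random_protein(rng, n_long, "long")
        targets = [a, b] if rng.integers(2) else [b, a]
        offs = enumerate_placements(n_long, n_short, "exhaustive")
        placement = offs[int(rng.integers(len(offs)))]
    return targets, placement, _random_model(rng, targets, matrix, real_weights)


# ---------------------------------------------------------------------------
# window_score


def test_window_score_identity_decoding_includes_diagonal(blosum62):
    # reference codon AAA decodes K against target K: diagonal entry present
    x, y = ProteinSeq("x", "K"), ProteinSeq("y", "C")
    model = unit_model([x, y], blosum62)
    s = window_score("AAAG", 0, PAIR_FM2, PLC0, [x, y], model)
    # antisense codon from positions (3,2,1) complemented: C,T,T -> CTT = L
    assert s == blosum62.score("K", "K") + blosum62.score("C", "L")


def test_window_score_stop_gives_minus_infinity(blosum62):
    x, y = ProteinSeq("x", "K"), ProteinSeq("y", "C")
    model = unit_model([x, y], blosum62)
    assert window_score("TAAT", 0, PAIR_FM2, PLC0, [x, y], model) == NEG_INF


def test_window_score_triple_equals_sum_of_codon_terms(rng, blosum62):
    """Per-codon recomputation oracle for the triple scheme."""
    targets = [random_protein(rng, 2, f"t{i}") for i in range(3)]
    model = unit_model(targets, blosum62)
    for _ in range(50):
        w = "".join(rng.choice(list("ACGT"), size=4))
        got = window_score(w, 1, TRIPLE_DEFAULT, PLC0, targets, model)
        ref_c = w[0:3]
        anti_c = "".join(complement(x) for x in (w[3], w[2], w[1]))
        p1_c = w[1:4]
        codons = [ref_c, anti_c, p1_c]
        residues = [targets[0].residues[1], targets[1].residues[0], targets[2].residues[1]]
        if any(STANDARD_CODE.is_stop(c) for c in codons):
            assert got == NEG_INF
        else:
            expected = sum(
                blosum62.score(r, STANDARD_CODE.table[c])
                for r, c in zip(residues, codons)
            )
            assert got == expected


# ---------------------------------------------------------------------------
# F = 0 closed form


def _f0_codon_oracle(x_aa, y_aa, blosum62):
    """Exhaustive max over the 64 codons for one base-paired codon pair."""
    best = NEG_INF
    for c in CODONS:
        rc = "".join(complement(n) for n in reversed(c))
        a, b = STANDARD_CODE.table[c], STANDARD_CODE.table[rc]
        if a == "*" or b == "*":
            continue
        best = max(best, blosum62.score(x_aa, a) + blosum62.score(y_aa, b))
    return best


def test_design_f0_single_pair_known_optimum(blosum62):
    x, y = ProteinSeq("x", "K"), ProteinSeq("y", "F")
    res = design_f0(x, y)
    assert res.score == blosum62.score("K", "K") + blosum62.score("F", "F") == 11
    assert res.dna.nucleotides == "AAA"
    assert [p.residues for p in res.proteins] == ["K", "F"]


def test_design_f0_equals_per_position_oracle(rng, blosum62):
    for _ in range(30):
        n = int(rng.integers(1, 6))
        x, y = random_protein(rng, n, "x"), random_protein(rng, n, "y")
        res = design_f0(x, y)
        # antisense target residue for reference position k is y[n-1-k]
        expected = sum(
            _f0_codon_oracle(x.residues[k], y.residues[n - 1 - k], blosum62)
            for k in range(n)
        )
        assert res.score == expected


# ---------------------------------------------------------------------------
# DP vs brute force and bounds


@pytest.mark.parametrize("scheme", SCHEMES, ids=lambda s: s.name)
@pytest.mark.parametrize("real_weights", [False, True], ids=["unit", "real"])
def test_dp_matches_brute_force(rng, blosum62, scheme, real_weights):
    for _ in range(12):
        targets, placement, model = _random_instance(rng, scheme, blosum62, real_weights)
        a = design_dp(targets, scheme, placement, model)
        b = brute_force_design(targets, scheme, placement, model)
        if real_weights:
            assert np.isclose(a.score, b.score, rtol=1e-12, atol=1e-12)
        else:
            assert a.score == b.score


@pytest.mark.parametrize("scheme", SCHEMES, ids=lambda s: s.name)
def test_self_consistent_targets_reach_diagonal_bound(rng, blosum62, scheme):
    for _ in range(10):
        n = int(rng.integers(2, 25))
        _, targets = self_consistent_targets(rng, scheme, n)
        model = unit_model(targets, blosum62)
        res = design_dp(targets, scheme, PLC0, model)
        lay = region_layout(scheme, PLC0, targets)
        assert res.score == diagonal_bound(targets, lay, model)


@pytest.mark.parametrize("scheme", SCHEMES, ids=lambda s: s.name)
def test_score_never_exceeds_diagonal_bound(rng, blosum62, scheme):
    for _ in range(20):
        targets, placement, model = _random_instance(
            rng, scheme, blosum62, real_weights=True, max_codons=6
        )
        res = design_dp(targets, scheme, placement, model)
        lay = region_layout(scheme, placement, targets)
        assert res.score <= diagonal_bound(targets, lay, model) + 1e-9


def test_design_is_deterministic(rng, blosum62):
    targets = [random_protein(rng, 15, "x"), random_protein(rng, 20, "y")]
    model = unit_model(targets, blosum62)
    first = design_dp(targets, PAIR_FM2, PLC0, model)
    for _ in range(3):
        again = design_dp(targets, PAIR_FM2, PLC0, model)
        assert again.dna == first.dna and again.score == first.score


def test_score_audit_and_window_sum(rng, blosum62):
    """Total = sum of window contributions = Eq-style recomputation."""
    targets = [random_protein(rng, 10, "x"), random_protein(rng, 14, "y")]
    model = unit_model(targets, blosum62)
    res = design_dp(targets, PAIR_FM2, Placement(4), model)
    assert res.score == float(np.sum(res.window_scores))
    lay = region_layout(PAIR_FM2, Placement(4), targets)
    recomputed = 0.0
    for fi, t in enumerate(targets):
        lo = int(lay.res_maps[fi].min())
        for i, aa in enumerate(res.proteins[fi].residues):
            recomputed += blosum62.score(t.residues[lo + i], aa)
    assert recomputed == res.score


def test_dp_table_columns_depend_only_on_previous_column(rng, blosum62):
    targets = [random_protein(rng, 6, "x"), random_protein(rng, 6, "y")]
    model = unit_model(targets, blosum62)
    res = design_dp(targets, PAIR_FM2, PLC0, model, keep_table=True)
    M = res.table.scores
    for k in range(1, 6):
        for s_idx, s_nt in enumerate("ACGT"):
            best = NEG_INF
            for q in range(256):
                if q & 3 != s_idx:
                    continue
                w = "".join("ACGT"[(q >> (2 * (3 - p))) & 3] for p in range(4))
                sq = window_score(w, k, PAIR_FM2, PLC0, targets, model)
                best = max(best, M[k - 1, q >> 6] + sq)
            assert M[k, s_idx] == best


def test_no_decoded_frame_contains_a_stop(rng, blosum62):
    for scheme in SCHEMES:
        targets, placement, model = _random_instance(rng, scheme, blosum62, max_codons=3)
        res = design_dp(targets, scheme, placement, model)
        for p in res.proteins:
            assert "*" not in p.residues  # decode() would have raised anyway


def test_brute_force_refuses_large_regions(rng, blosum62):
    targets = [random_protein(rng, 10, "x"), random_protein(rng, 10, "y")]
    with pytest.raises(ValueError):
        brute_force_design(targets, PAIR_FM2, PLC0, unit_model(targets, blosum62))


def test_flank_score_reported_separately(rng, blosum62):
    x = random_protein(rng, 3, "x")
    y = random_protein(rng, 8, "y")
    model = unit_model([x, y], blosum62)
    res = design_dp([x, y], PAIR_FM2, Placement(2), model)
    flank_res = [y.residues[j] for j in range(8) if not 2 <= j <= 4]
    assert res.flank_score == sum(blosum62.score(a, a) for a in flank_res)
    # full proteins: flanks copied unchanged, overlap replaced by the design
    assert res.full_proteins[1].residues[:2] == y.residues[:2]
    assert res.full_proteins[1].residues[5:] == y.residues[5:]
    assert res.full_proteins[1].residues[2:5] == res.proteins[1].residues


# ---------------------------------------------------------------------------
# Screening


def test_plan_screen_run_arithmetic():
    plan = plan_screen(500)
    assert plan["pairs"] == 125_250
    assert plan["runs"] == 751_500
    assert plan_screen(2)["pairs"] == 3


def test_all_pairs_includes_self_pairs(rng):
    ps = [random_protein(rng, 4, f"p{i}") for i in range(2)]
    pairs = all_pairs(ps)
    assert [(a.id, b.id) for a, b in pairs] == [("p0", "p0"), ("p0", "p1"), ("p1", "p1")]


def test_design_screen_row_count_and_parity(rng, blosum62):
    ps = [random_protein(rng, 5, "A"), random_protein(rng, 5, "B")]
    df = design_screen(all_pairs(ps), [PAIR_FM2], matrix=blosum62)
    # equal lengths: one paper placement per pair -> 3 rows (AA, AB, BB)
    assert len(df) == 3
    direct = design_dp(ps, PAIR_FM2, PLC0, unit_model(ps, blosum62))
    row = df[(df.id_ref == "A") & (df.id_other == "B")].iloc[0]
    assert row["score"] == direct.score
    assert row["dna"] == direct.dna.nucleotides
    assert (df["error"] == "").all()


def test_design_screen_sense_sense_tries_both_shifted_roles(rng, blosum62):
    ps = [random_protein(rng, 4, "A"), random_protein(rng, 6, "B")]
    df = design_screen(all_pairs(ps), [PAIR_FP1], matrix=blosum62)
    ab = df[(df.id_ref.isin(["A", "B"])) & (df.id_other.isin(["A", "B"]))
            & (df.id_ref != df.id_other)]
    assert sorted(ab["variant"]) == ["A-shifted", "B-shifted"]
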