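"""Dot-bracket parsing, the weighted maximum-pairing folder, base-pair
distance and inverse folding, checked against brute-force enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracle_utils import best_weight_bruteforce, pair_weight
from termscan.structure import (
    basepair_distance,
    fold_nussinov,
    gc_content,
    generate_pretraining_set,
    inverse_fold,
    pairs_to_dotbracket,
    parse_dotbracket,
    structure_weight,
)


class TestParseDotbracket:
    @pytest.mark.parametrize(
        "db,expected",
        [
            ("((...))", {(0, 6), (1, 5)}),
            ("......", set()),
            ("(((...)))", {(0, 8), (1, 7), (2, 6)}),
            ("", set()),
        ],
    )
    def test_examples(self, db, expected):
        assert parse_dotbracket(db) == expected

    @pytest.mark.parametrize("db", ["(()", "())", "(.x.)"])
    def test_invalid(self, db):
        with pytest.raises(ValueError):
            parse_dotbracket(db)

    def test_roundtrip(self):
        db = "..((((...))))((...)).."
        assert pairs_to_dotbracket(parse_dotbracket(db), len(db)) == db


class TestFoldNussinov:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("GGGAAACCC", {(0, 8), (1, 7), (2, 6)}),
            ("AAAAA", set()),
            ("GAAAC", {(0, 4)}),
        ],
    )
    def test_examples(self, seq, expected):
        assert fold_nussinov(seq) == expected

    def test_min_loop_respected(self):
        # G and C closer than min_loop apart cannot pair
        assert fold_nussinov("GAAC") == set()

    def test_rejects_ambiguous(self):
        with pytest.raises(ValueError):
            fold_nussinov("GANAC")

    def test_matches_bruteforce_on_random_panel(self):
        """Returned structure is valid, nested, respects min_loop, and
        attains the brute-force maximum weight (lengths 4-12)."""
        rng = np.random.default_rng(42)
        for _ in range(40):
            n = int(rng.integers(4, 13))
            seq = "".join(rng.choice(list("ACGU"), n))
            pairs = fold_nussinov(seq)
            for i, j in pairs:
                assert j - i > 3 and pair_weight(seq[i], seq[j]) > 0
            flat = [p for ij in pairs for p in ij]
            assert len(flat) == len(set(flat)), "position paired twice"
            assert structure_weight(seq, pairs) == best_weight_bruteforce(seq)


class TestBasepairDistance:
    def test_identical_zero(self):
        assert basepair_distance({(0, 6), (1, 5)}, {(0, 6), (1, 5)}) == 0

    def test_examples(self):
        assert basepair_distance({(0, 6), (1, 5)}, {(1, 5)}) == 1
        assert basepair_distance(set(), {(0, 6), (1, 5)}) == 2

    def test_symmetric(self):
        a, b = {(0, 9), (2, 7)}, {(0, 9), (3, 8)}
        assert basepair_distance(a, b) == basepair_distance(b, a) == 2


class TestInverseFold:
    def test_hairpin_reaches_target(self):
        result = inverse_fold("(((...)))", seed=11)
        assert result.achieved_distance == 0
        assert fold_nussinov(result.sequence) == parse_dotbracket("(((...)))")

    def test_unpaired_target(self):
        result = inverse_fold(".....", seed=0)
        assert result.achieved_distance == 0
        assert len(result.sequence) == 5

    def test_parse_error(self):
        with pytest.raises(ValueError):
            inverse_fold("(()", seed=0)

    def test_seed_determinism(self):
        r1 = inverse_fold("..((((....))))..", seed=5)
        r2 = inverse_fold("..((((....))))..", seed=5)
        assert r1.sequence == r2.sequence
        assert r1.iterations == r2.iterations

    def test_vienna_backend(self):
        result = inverse_fold("(((((.....)))))", seed=1, backend="vienna")
        assert result.backend == "vienna"
        assert len(result.sequence) == 15


class TestPretrainingSet:
    def test_counts_and_lengths(self):
        structures = ["..(((....)))..", "((((...))))"]
        pset = generate_pretraining_set(structures, 6, seed=1)
        pos = [r for r in pset.records if r.label == 1]
        neg = [r for r in pset.records if r.label == 0]
        assert len(pos) == len(neg) == 6
        assert sorted(len(r.sequence) for r in pos) == sorted(
            len(r.sequence) for r in neg
        )

    def test_split_fractions(self):
        structures = ["..((((...))))..."]
        pset = generate_pretraining_set(structures, 20, seed=2)
        # 85% / 15% per class
        assert len(pset.pretrain_idx) == 2 * 17
        assert len(pset.earlystop_idx) == 2 * 3
        union = set(pset.pretrain_idx) | set(pset.earlystop_idx)
        assert union == set(range(40))

    def test_positives_refold_to_target(self):
        structures = ["...((((....))))...", ".((((((...)))))). "]
        structures = [s.strip() for s in structures]
        pset = generate_pretraining_set(structures, 4, seed=3)
        for k, rec in enumerate(r for r in pset.records if r.label == 1):
            target = parse_dotbracket(structures[k % len(structures)])
            assert fold_nussinov(rec.sequence) == target

    def test_parse_error_propagates(self):
        with pytest.raises(ValueError):
            generate_pretraining_set(["(()"], 2, seed=0)

    def test_context_padding(self):
        """With pad_to, positives embed the inverse-folded element in random
        context; the element slice still refolds to its target exactly."""
        structures = ["..((((...)))).."]
        pset = generate_pretraining_set(structures, 4, seed=7, pad_to=40)
        for rec in pset.records:
            assert len(rec.sequence) == 40
        for rec in (r for r in pset.records if r.label == 1):
            core = rec.sequence[
                rec.core_start : rec.core_start + len(rec.target)
            ]
            assert fold_nussinov(core) == parse_dotbracket(rec.target)


class TestGCContent:
    def test_trivial_values(self):
        out = gc_content([("GGGG", 1), ("AUAU", 0)])
        assert out[1]["mean"] == 1.0
        assert out[0]["mean"] == 0.0

    def test_uniform_negatives_near_half(self):
        rng = np.random.default_rng(0)
        seqs = [
            ("".join(rng.choice(list("ACGU"), 75)), 0) for _ in range(300)
        ]
        out = gc_content(seqs)
        assert abs(out[0]["mean"] - 0.5) < 3 * np.sqrt(0.25 / (75 * 300))

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            gc_content([])


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_inverse_fold_reports_distance_honestly(seed):
    """achieved_distance always equals the oracle-checked distance between
    the fold of the returned sequence and the target."""
    rng = np.random.default_rng(seed)
    stem = int(rng.integers(2, 7))
    loop = int(rng.integers(3, 6))
    pad = int(rng.integers(0, 6))
    target = "." * pad + "(" * stem + "." * loop + ")" * stem
    result = inverse_fold(target, seed=seed, max_iter=3000)
    actual = basepair_distance(
        fold_nussinov(result.sequence), parse_dotbracket(target)
    )
    assert result.achieved_distance == actual
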