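"""Section and structure mutations and the relative-impact statistics,
validated with analytic toy models with known closed forms."""

import numpy as np
import pytest

from termscan.mutagenesis import (
    MutationSpec,
    detection_impact,
    impacts_to_frame,
    mutate_section,
    mutate_stem_pairs,
    section_impact,
    structure_impact,
)
from termscan.structure import PAIRING_DINUCLEOTIDES
from termscan.synthetic import SECTION_ORDER

_PAIRS = set(PAIRING_DINUCLEOTIDES)


def _hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


class TestMutateSection:
    def test_half_of_section_mutated(self, terminator_panel):
        rec = terminator_panel[0]
        for section in SECTION_ORDER:
            start, end = rec.sections[section]
            mutant = mutate_section(rec, section, seed=1)
            expected = max(1, (end - start) // 2)
            assert _hamming(rec.sequence, mutant) == expected
            assert mutant[:start] == rec.sequence[:start]
            assert mutant[end:] == rec.sequence[end:]

    def test_seed_determinism(self, terminator_panel):
        rec = terminator_panel[1]
        assert mutate_section(rec, "u_tail", seed=3) == mutate_section(
            rec, "u_tail", seed=3
        )

    def test_unknown_section(self, terminator_panel):
        with pytest.raises(ValueError):
            mutate_section(terminator_panel[0], "stem")

    def test_length_never_changes(self, terminator_panel):
        rng = np.random.default_rng(0)
        for rec in terminator_panel[:10]:
            for section in SECTION_ORDER:
                assert len(mutate_section(rec, section, rng)) == len(rec)


class TestMutateStemPairs:
    def test_retain_on_gc_pair(self, fixed_stem_records):
        """A retained G-C pair becomes one of CG, AU, UA, UG (both changed,
        still pairing)."""
        rec = fixed_stem_records[0]
        pairs = rec.stem_pairs()
        gc_pairs = [
            (i, j)
            for i, j in pairs
            if rec.sequence[i] + rec.sequence[j] == "GC"
        ]
        assert gc_pairs, "fixture should contain a G-C pair"
        seen = set()
        for seed in range(80):
            mutant = mutate_stem_pairs(rec, len(pairs), "retain", seed=seed)
            for i, j in gc_pairs:
                new = mutant[i] + mutant[j]
                assert new in {"CG", "AU", "UA", "UG"}
                seen.add(new)
        assert seen == {"CG", "AU", "UA", "UG"}  # full feasible set reachable

    def test_disrupt_breaks_pairing(self, fixed_stem_records):
        rec = fixed_stem_records[1]
        mutant = mutate_stem_pairs(rec, 3, "disrupt", seed=5)
        changed = [
            (i, j)
            for i, j in rec.stem_pairs()
            if mutant[i] != rec.sequence[i]
        ]
        assert len(changed) == 3
        for i, j in changed:
            assert mutant[i] + mutant[j] not in _PAIRS
            assert mutant[i] != rec.sequence[i]
            assert mutant[j] != rec.sequence[j]

    def test_full_stem_mutation_leaves_rest(self, fixed_stem_records):
        rec = fixed_stem_records[2]
        pairs = rec.stem_pairs()
        mutant = mutate_stem_pairs(rec, len(pairs), "retain", seed=1)
        touched = {p for ij in pairs for p in ij}
        for pos in range(len(rec)):
            if pos not in touched:
                assert mutant[pos] == rec.sequence[pos]
            else:
                assert mutant[pos] != rec.sequence[pos]

    def test_k_too_large(self, fixed_stem_records):
        with pytest.raises(ValueError):
            mutate_stem_pairs(fixed_stem_records[0], 9, "retain", seed=0)


class TestSectionImpact:
    def test_indifferent_model_has_zero_impact(self, terminator_panel):
        result = section_impact(
            lambda seqs: np.ones(len(seqs)), terminator_panel[:10], seed=0
        )
        for section in SECTION_ORDER:
            assert result.impacts[section] == pytest.approx(0.0)

    def test_fraction_unmutated_model_closed_form(self, terminator_panel):
        """A model returning the unmutated fraction of the U-tail gives a
        U-tail impact of ~0.5 (half the section is mutated) and ~0 for
        other sections."""
        originals = {r.sequence: r for r in terminator_panel}
        panel = terminator_panel[:20]

        def scorer(seqs):
            out = []
            for s in seqs:
                ref = min(
                    panel, key=lambda r: _hamming(r.sequence, s)
                )
                lo, hi = ref.sections["u_tail"]
                matches = sum(
                    a == b for a, b in zip(s[lo:hi], ref.sequence[lo:hi])
                )
                out.append(matches / (hi - lo))
            return np.array(out)

        result = section_impact(scorer, panel, n_repeats=10, seed=1)
        assert result.impacts["u_tail"] == pytest.approx(0.5, abs=0.08)
        assert abs(result.impacts["loop"]) < 0.08
        del originals

    def test_default_repeats(self, terminator_panel):
        calls = []

        def scorer(seqs):
            calls.append(len(seqs))
            return np.full(len(seqs), 0.5)

        section_impact(scorer, terminator_panel[:4])
        assert calls[0] == 4  # originals
        assert all(c == 4 * 15 for c in calls[1:])  # 15 mutants per record

    def test_zero_baseline_errors(self, terminator_panel):
        with pytest.raises(ZeroDivisionError):
            section_impact(
                lambda seqs: np.zeros(len(seqs)), terminator_panel[:3]
            )


class TestStructureImpact:
    @staticmethod
    def _intact_fraction_scorer(records):
        by_len = {r.sequence: r for r in records}

        def scorer(seqs):
            out = []
            for s in seqs:
                ref = min(
                    records, key=lambda r: sum(a != b for a, b in zip(r.sequence, s))
                )
                pairs = ref.stem_pairs()
                intact = sum((s[i] + s[j]) in _PAIRS for i, j in pairs)
                out.append(intact / len(pairs))
            return np.array(out)

        del by_len
        return scorer

    def test_closed_form_impact(self, fixed_stem_records):
        """For the intact-stem-fraction model the disrupt impact at k is
        k/stem_length and it is non-decreasing in k."""
        scorer = self._intact_fraction_scorer(fixed_stem_records)
        result = structure_impact(
            scorer, fixed_stem_records, k_range=range(1, 9), n_repeats=10,
            seed=2,
        )
        prev = -1.0
        for k in range(1, 9):
            assert result.impacts[k] == pytest.approx(k / 8, abs=0.03)
            assert result.impacts[k] >= prev - 1e-9
            prev = result.impacts[k]

    def test_insensitive_model_zero_impact(self, fixed_stem_records):
        result = structure_impact(
            lambda seqs: np.full(len(seqs), 0.8),
            fixed_stem_records[:5],
            k_range=[1, 4],
            seed=0,
        )
        assert result.impacts[1] == pytest.approx(0.0)
        assert result.impacts[4] == pytest.approx(0.0)


class TestDetectionImpact:
    def test_always_detecting_detector(self, fixed_stem_records):
        out = detection_impact(
            lambda seqs: [1] * len(seqs),
            fixed_stem_records[:5],
            MutationSpec(mode="section", section="loop", seed=0),
        )
        assert out["impact"] == pytest.approx(0.0)

    def test_stem_threshold_detector(self, fixed_stem_records):
        """A detector requiring >= 6 intact pairs of 8 loses every sequence
        when 3 pairs are disrupted: impact 1."""
        records = fixed_stem_records[:10]

        def detector(seqs):
            hits = []
            for s in seqs:
                ref = min(
                    records,
                    key=lambda r: sum(a != b for a, b in zip(r.sequence, s)),
                )
                intact = sum(
                    (s[i] + s[j]) in _PAIRS for i, j in ref.stem_pairs()
                )
                hits.append(1 if intact >= 6 else 0)
            return hits

        out = detection_impact(
            detector, records, MutationSpec(mode="structure", k=3, seed=1)
        )
        assert out["rate_retain"] == 1.0
        assert out["rate_disrupt"] == 0.0
        assert out["impact"] == 1.0

    def test_empty_records_error(self):
        with pytest.raises(ValueError):
            detection_impact(lambda s: [], [], MutationSpec(seed=0))


def test_impacts_to_frame_shapes(fixed_stem_records):
    sec = section_impact(
        lambda s: np.full(len(s), 0.5), fixed_stem_records[:3], seed=0
    )
    frame = impacts_to_frame(sec, "toy")
    assert set(frame["unit"]) == set(SECTION_ORDER)
    struct = structure_impact(
        lambda s: np.full(len(s), 0.5), fixed_stem_records[:3],
        k_range=[1, 2], seed=0,
    )
    frame2 = impacts_to_frame(struct, "toy")
    assert list(frame2["unit"]) == [1, 2]
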