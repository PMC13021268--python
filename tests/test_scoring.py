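"""Match classification, gap, the six-graded map and the three-level collapse."""

import dataclasses
import itertools

import pandas as pd
import pytest

import fourps as fp
from fourps.instrument import ItemResponse, RespondentRecord
from fourps.scoring import (
    FAIR,
    INSUFFICIENT,
    LESS_THAN_PREFERRED,
    MATCH,
    MORE_THAN_PREFERRED,
    SUFFICIENT,
    ScoringMap,
)

ALL_PAIRS = list(itertools.product(range(1, 5), range(1, 5)))


class TestGapAndCategory:
    @pytest.mark.parametrize(
        "pref, exp, gap", [(4, 4, 0), (4, 1, -3), (1, 4, 3), (2, 3, 1), (3, 2, -1)]
    )
    def test_gap_is_experience_minus_preference(self, pref, exp, gap):
        assert fp.compute_gap(pref, exp) == gap

    @pytest.mark.parametrize("pref, exp", [(0, 2), (5, 2), (2, 0), (2, 5)])
    def test_out_of_range_codes_raise(self, pref, exp):
        with pytest.raises(ValueError):
            fp.compute_gap(pref, exp)

    def test_corresponding_alternatives_match(self):
        # 'unimportant'~'not at all' ... 'crucial'~'entirely'
        for code in range(1, 5):
            assert fp.classify_match(code, code) == MATCH

    def test_category_counts_over_grid(self):
        counts = {MATCH: 0, LESS_THAN_PREFERRED: 0, MORE_THAN_PREFERRED: 0}
        for p, e in ALL_PAIRS:
            counts[fp.classify_match(p, e)] += 1
        assert counts == {MATCH: 4, LESS_THAN_PREFERRED: 6, MORE_THAN_PREFERRED: 6}


class TestLevels:
    @pytest.mark.parametrize(
        "rank, level",
        [(0, INSUFFICIENT), (1, INSUFFICIENT), (2, FAIR), (3, FAIR), (4, SUFFICIENT), (5, SUFFICIENT)],
    )
    def test_boundaries(self, rank, level):
        assert fp.level_of(rank) == level

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            fp.level_of(6)


class TestDefaultMap:
    def test_passes_validation(self, default_map):
        assert fp.validate_scoring_map(default_map) == []

    def test_diagonal_ranks_five(self, default_map):
        for code in range(1, 5):
            assert default_map.rank(code, code) == 5

    @pytest.mark.parametrize(
        "pref, exp, rank",
        # gap-class order best->worst 0, +1, -1, +2, -2, +3, -3 -> 5,4,3,2,1,0,0
        [(3, 4, 4), (4, 3, 3), (1, 3, 2), (3, 1, 1), (1, 4, 0), (4, 1, 0)],
    )
    def test_gap_class_ranks(self, default_map, pref, exp, rank):
        assert default_map.rank(pref, exp) == rank

    def test_all_six_grades_emitted(self, default_map):
        assert set(default_map.cells.values()) == set(range(6))

    def test_json_round_trip(self, default_map):
        back = fp.scoring_map_from_json(fp.scoring_map_to_json(default_map))
        assert back.cells == default_map.cells and back.name == default_map.name


class TestValidateScoringMap:
    def _mutate(self, default_map, cell, rank):
        cells = dict(default_map.cells)
        cells[cell] = rank
        return ScoringMap(cells=cells, name="mutant")

    def test_diagonal_below_five_rejected(self, default_map):
        report = fp.validate_scoring_map(self._mutate(default_map, (2, 2), 4))
        assert any(v.field == "diagonal" for v in report)

    def test_direction_tiebreak_flip_rejected(self, default_map):
        # ranking gap -1 above gap +1 violates "more is better than less"
        flipped = dict(default_map.cells)
        for p, e in ALL_PAIRS:
            if e - p == 1:
                flipped[(p, e)] = 3
            elif e - p == -1:
                flipped[(p, e)] = 4
        report = fp.validate_scoring_map(ScoringMap(cells=flipped, name="flip"))
        assert any(v.field == "direction" for v in report)

    def test_monotonicity_violation_rejected(self, default_map):
        report = fp.validate_scoring_map(self._mutate(default_map, (1, 4), 5))
        assert any(v.field in ("monotonicity", "direction") for v in report)

    def test_missing_cell_rejected(self, default_map):
        cells = dict(default_map.cells)
        del cells[(1, 2)]
        report = fp.validate_scoring_map(ScoringMap(cells=cells))
        assert any("missing cell" in v.reason for v in report)

    def test_missing_grade_rejected(self, default_map):
        # push every rank-1 cell to 2: grade 1 never emitted
        cells = {k: (2 if r == 1 else r) for k, r in default_map.cells.items()}
        report = fp.validate_scoring_map(ScoringMap(cells=cells))
        assert any(v.field == "coverage" for v in report)


class TestScoreItem:
    def test_full_consistency_triangle_over_grid(self, default_map):
        """category/gap/rank/level are mutually consistent on all 16 cells."""
        seen_ranks = set()
        for p, e in ALL_PAIRS:
            sc = fp.score_item(p, e, default_map)
            assert sc.gap == e - p
            assert (sc.gap == 0) == (sc.category == MATCH)
            assert (sc.gap < 0) == (sc.category == LESS_THAN_PREFERRED)
            assert sc.rank == default_map.rank(p, e)
            assert sc.level == fp.level_of(sc.rank)
            seen_ranks.add(sc.rank)
        assert seen_ranks == set(range(6))

    def test_examples(self, default_map):
        assert dataclasses.astuple(fp.score_item(1, 1, default_map))[3:] == (MATCH, 0, 5, SUFFICIENT)
        sc = fp.score_item(4, 1, default_map)
        assert (sc.category, sc.gap, sc.level) == (LESS_THAN_PREFERRED, -3, INSUFFICIENT)
        sc = fp.score_item(1, 3, default_map)
        assert (sc.category, sc.gap, sc.level) == (MORE_THAN_PREFERRED, 2, FAIR)

    def test_missing_side_yields_no_score(self, default_map):
        assert fp.score_item(None, 3, default_map) is None
        assert fp.score_item(3, None, default_map) is None


def _cohort_of(rows, instrument):
    records = []
    for rid, responses in rows:
        records.append(
            RespondentRecord(
                respondent_id=rid,
                site_id="s1",
                arm="none",
                timepoint=0,
                covariates={},
                responses=tuple(responses),
            )
        )
    return fp.Cohort(records=tuple(records), instrument=instrument)


class TestScoreCohort:
    def test_row_count_complete(self, instrument, default_map):
        rows = [
            ("r1", [ItemResponse(i, 2, 2) for i in range(1, 13)]),
            ("r2", [ItemResponse(i, 3, 1) for i in range(1, 13)]),
        ]
        scored = fp.score_cohort(_cohort_of(rows, instrument), default_map)
        assert len(scored) == 24

    def test_missing_item_dropped_rowwise(self, instrument, default_map):
        responses = [ItemResponse(i, 2, 2) for i in range(1, 12)] + [ItemResponse(12, 2, None)]
        scored = fp.score_cohort(_cohort_of([("r1", responses)], instrument), default_map)
        assert len(scored) == 11
        assert 12 not in set(scored["item_id"])

    def test_all_diagonal_cohort(self, instrument, default_map):
        rows = [("r1", [ItemResponse(i, 3, 3) for i in range(1, 13)])]
        scored = fp.score_cohort(_cohort_of(rows, instrument), default_map)
        assert (scored["rank"] == 5).all() and (scored["level"] == SUFFICIENT).all()

    def test_equals_itemwise_scoring(self, effect_cohort, default_map):
        """No cross-item coupling: the cohort path equals item-by-item scoring."""
        cohort, _ = effect_cohort
        scored = fp.score_cohort(cohort, default_map)
        sub = scored.sample(n=150, random_state=0)
        for _, row in sub.iterrows():
            sc = fp.score_item(row["preference"], row["experience"], default_map)
            assert (sc.category, sc.gap, sc.rank, sc.level) == (
                row["category"],
                row["gap"],
                row["rank"],
                row["level"],
            )

    def test_invalid_map_rejected(self, effect_cohort, default_map):
        cohort, _ = effect_cohort
        bad = ScoringMap(cells={**default_map.cells, (2, 2): 0})
        with pytest.raises(ValueError, match="invalid scoring map"):
            fp.score_cohort(cohort, bad)


class TestDesignateItems:
    def test_primary_marked_rest_secondary(self, instrument):
        designated = fp.designate_items(instrument, {1})
        assert designated.item(1).designation == "primary"
        assert all(designated.item(i).designation == "secondary" for i in range(2, 13))

    def test_all_primary_clinical_mode(self, instrument):
        designated = fp.designate_items(instrument, set(range(1, 13)))
        assert len(designated.primary_items) == 12

    def test_unknown_item_raises(self, instrument):
        with pytest.raises(ValueError, match="13"):
            fp.designate_items(instrument, {13})
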