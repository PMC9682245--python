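"""Tokenizer: vocabulary filter, positions, cumulative features, transforms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ehrformer.tokenizer import (TOKEN_WIDTH, VALUE_COLUMNS, assign_positions,
                                 build_vocab, compute_cumulative_features,
                                 filter_stays, fit_transforms, process_static,
                                 tokenize_stay)


def frame(rows):
    return pd.DataFrame(rows, columns=["variable", "category", "time_hours", "value"])


class TestBuildVocab:
    def make_frames(self, n_stays, extra=()):
        frames = [frame([("hr", "vital", 0.5, 80.0)]) for _ in range(n_stays)]
        for stay_idx, rows in extra:
            frames[stay_idx] = pd.concat([frames[stay_idx], frame(rows)],
                                         ignore_index=True)
        return frames

    def test_prevalence_boundary_is_inclusive(self):
        # a lab in exactly 1 of 100 stays sits on the 1% boundary: retained
        frames = self.make_frames(100, [(0, [("lactate", "lab", 1.0, 2.0)])])
        vocab = build_vocab(frames, min_prevalence=0.01)
        assert "lactate" in vocab.name_to_id

    def test_below_boundary_lab_dropped_but_vital_kept(self):
        frames = self.make_frames(200, [(0, [("lactate", "lab", 1.0, 2.0),
                                             ("etco2", "vital", 1.0, 30.0)])])
        vocab = build_vocab(frames, min_prevalence=0.01)
        assert "lactate" not in vocab.name_to_id   # 0.5% < 1%
        assert "etco2" in vocab.name_to_id         # vitals exempt from filter

    def test_unseen_medication_absent(self):
        vocab = build_vocab(self.make_frames(10))
        assert all(cat != "medication" for cat in vocab.categories.values())

    def test_reserved_ids_disjoint_and_contiguous(self):
        vocab = build_vocab(self.make_frames(5, [(0, [("abx", "medication", 1.0, 1.0)])]))
        ids = sorted(vocab.name_to_id.values())
        assert ids[0] == vocab.first_variable_id
        assert ids == list(range(ids[0], ids[0] + len(ids)))
        assert set(vocab.task_ids) | {vocab.PAD, vocab.STATIC} == set(range(2 + vocab.n_tasks))

    def test_empty_training_set_errors(self):
        with pytest.raises(ValueError):
            build_vocab([])

    def test_json_round_trip(self, small_vocab):
        from ehrformer.tokenizer import VocabMap
        back = VocabMap.from_json(small_vocab.to_json())
        assert back.name_to_id == small_vocab.name_to_id
        assert back.size == small_vocab.size


class TestAssignPositions:
    @pytest.mark.parametrize("times,expected", [
        ([0.1, 0.2, 0.2, 0.3, 0.3], [0, 1, 1, 2, 2]),
        ([], []),
        ([5.0, 5.0, 5.0], [0, 0, 0]),
        ([1.0], [0]),
    ])
    def test_examples(self, times, expected):
        assert assign_positions(times).tolist() == expected

    def test_decreasing_input_errors(self):
        with pytest.raises(ValueError):
            assign_positions([1.0, 0.5])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=40))
    def test_dense_rank_properties(self, raw):
        times = np.sort(np.asarray(raw))
        pos = assign_positions(times)
        steps = np.diff(pos)
        assert ((steps == 0) | (steps == 1)).all()
        assert pos[0] == 0
        assert len(np.unique(pos)) == len(np.unique(times))
        # equal times share an index
        for i in range(1, len(times)):
            assert (pos[i] == pos[i - 1]) == (times[i] == times[i - 1])


class TestCumulativeFeatures:
    def test_singleton_conventions(self):
        feats = compute_cumulative_features([10.0], [0.5])
        assert feats.shape == (1, 9)
        value, mean, median, count, vmin, vmax, std, first, gap = feats[0]
        assert (value, mean, median, count, vmin, vmax, std, first, gap) == \
            (10, 10, 10, 1, 10, 10, 0, 10, 0)

    def test_two_event_worked_example(self):
        feats = compute_cumulative_features([10.0, 20.0], [1.0, 3.0])
        np.testing.assert_allclose(feats[1], [20, 15, 15, 2, 10, 20, 5, 10, 2.0])

    def test_unsorted_errors(self):
        with pytest.raises(ValueError):
            compute_cumulative_features([1.0, 2.0], [3.0, 1.0])

    def test_matches_prefix_recomputation(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(1, 50))
            t = np.sort(rng.uniform(0, 48, n))
            v = rng.normal(50, 10, n)
            feats = compute_cumulative_features(v, t)
            for i in range(n):
                prefix = v[: i + 1]
                expected = [v[i], prefix.mean(), np.median(prefix), i + 1,
                            prefix.min(), prefix.max(), prefix.std(), v[0],
                            0.0 if i == 0 else t[i] - t[i - 1]]
                np.testing.assert_allclose(feats[i], expected, atol=1e-10)


class TestFitAndStatic:
    def test_training_standardization_is_zero_mean_unit_variance(
            self, small_cohort, small_vocab, small_artifacts):
        per_var: dict[str, list] = {}
        for s in small_cohort:
            mat = tokenize_stay(s.events, small_vocab, small_artifacts)
            frame_sorted = s.events.sort_values(["time_hours", "variable"],
                                                kind="stable")
            names = [n for n in frame_sorted["variable"]
                     if n in small_vocab.name_to_id]
            for row, name in zip(mat, names):
                per_var.setdefault(name, []).append(row[3:])
        flagged = {z.split(":")[0] for z in small_artifacts.zero_variance}
        for name, rows in per_var.items():
            block = np.vstack(rows)
            for j, col in enumerate(VALUE_COLUMNS):
                if f"{name}:{col}" in small_artifacts.zero_variance:
                    continue
                assert abs(block[:, j].mean()) < 1e-9
                assert abs(block[:, j].var() - 1.0) < 1e-6

    def test_constant_column_guard(self):
        class Stay:
            def __init__(self, i):
                self.events = frame([("hr", "vital", float(i), 70.0)])
                self.static_record = {"age": 50.0}
        arts = fit_transforms([Stay(i) for i in range(4)], build_vocab(
            [Stay(i).events for i in range(4)]))
        assert "hr:value" in arts.zero_variance
        assert arts.value_stats["hr"][0, 1] == 1.0
        assert "static:age" in arts.zero_variance

    def test_median_imputation_and_mask(self, small_artifacts):
        record = {c: None for c in small_artifacts.static_numeric_columns}
        record.update({c: None for c in small_artifacts.static_categorical_levels})
        vec = process_static(record, small_artifacts)
        n_num = len(small_artifacts.static_numeric_columns)
        masks = vec[-n_num:]
        assert (masks == 1).all()
        # median-imputed then standardized: (median - mean)/scale, finite
        assert np.isfinite(vec).all()

    def test_one_hot_block(self, small_artifacts):
        col = sorted(small_artifacts.static_categorical_levels)[0]
        levels = small_artifacts.static_categorical_levels[col]
        record = {col: levels[1]}
        vec = process_static(record, small_artifacts)
        offset = sum(len(small_artifacts.static_categorical_levels[c])
                     for c in sorted(small_artifacts.static_categorical_levels)
                     if c < col)
        block = vec[offset: offset + len(levels)]
        assert block.tolist() == [1.0 if i == 1 else 0.0 for i in range(len(levels))]

    def test_unknown_column_errors(self, small_artifacts):
        with pytest.raises(KeyError):
            process_static({"not_a_column": 1.0}, small_artifacts)

    def test_constant_width_across_cohort(self, small_cohort, small_artifacts):
        widths = {process_static(s.static_record, small_artifacts).size
                  for s in small_cohort}
        assert len(widths) == 1
        assert widths.pop() == small_artifacts.static_width


class TestTokenizeStay:
    def test_width_is_twelve(self, small_cohort, small_vocab, small_artifacts):
        for s in small_cohort[:10]:
            mat = tokenize_stay(s.events, small_vocab, small_artifacts)
            assert mat.shape[1] == TOKEN_WIDTH == 12

    def test_interleaved_variables_keep_separate_histories(
            self, small_vocab, small_artifacts):
        ev = frame([("a", "vital", 1.0, 10.0), ("b", "vital", 2.0, 100.0),
                    ("a", "vital", 3.0, 20.0)])
        vocab = build_vocab([ev])
        arts = fit_transforms([type("S", (), {"events": ev, "static_record": {}})()],
                              vocab)
        raw = compute_cumulative_features([10.0, 20.0], [1.0, 3.0])
        mat = tokenize_stay(ev, vocab, arts)
        # third row is variable 'a' again: count 2, not 3 (b is excluded)
        count_col = VALUE_COLUMNS.index("count") + 3
        stats = arts.value_stats["a"]
        expected = (raw[1, 3] - stats[3, 0]) / stats[3, 1]
        assert mat[2, count_col] == pytest.approx(expected)

    def test_all_out_of_vocab_gives_empty_matrix(self, small_vocab, small_artifacts):
        ev = frame([("nonexistent", "lab", 1.0, 5.0)])
        with pytest.warns(UserWarning):
            mat = tokenize_stay(ev, small_vocab, small_artifacts)
        assert mat.shape == (0, TOKEN_WIDTH)

    def test_row_order_invariance(self, small_cohort, small_vocab, small_artifacts):
        s = small_cohort[0]
        shuffled = s.events.sample(frac=1.0, random_state=3)
        a = tokenize_stay(s.events, small_vocab, small_artifacts)
        b = tokenize_stay(shuffled, small_vocab, small_artifacts)
        np.testing.assert_array_equal(a, b)

    def test_position_column_counts_unique_times(self, small_cohort, small_vocab,
                                                 small_artifacts):
        s = small_cohort[1]
        mat = tokenize_stay(s.events, small_vocab, small_artifacts)
        kept = s.events[s.events["variable"].isin(small_vocab.name_to_id)]
        assert len(np.unique(mat[:, 0])) == kept["time_hours"].nunique()


class TestFilterStays:
    def make(self, los, n_tok):
        return type("S", (), {"stay_id": f"s-{los}-{n_tok}", "los_hours": los,
                              "n_tokens": n_tok})()

    def test_rules(self):
        stays = [self.make(0.5, 10), self.make(48.0, 500),
                 self.make(241.0, 10), self.make(48.0, 12_001)]
        kept, log = filter_stays(stays)
        assert [s.los_hours for s in kept] == [48.0]
        reasons = dict(log)
        assert reasons[stays[0].stay_id] == "los_too_short"
        assert reasons[stays[2].stay_id] == "los_too_long"
        assert reasons[stays[3].stay_id] == "too_many_tokens"

    def test_boundaries_inclusive(self):
        kept, _ = filter_stays([self.make(1.0, 12_000), self.make(240.0, 1)])
        assert len(kept) == 2
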