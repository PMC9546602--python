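"""Session data model, file round-trips, count tabulation, design checks."""

import random

import pytest

from quadbias.iat_data import (
    CELLS,
    DESIGN_SHORT_CRITICAL,
    DESIGN_STANDARD,
    BlockOrder,
    Pairing,
    SessionRecord,
    StatusRole,
    StimulusCategory,
    TrialRecord,
    ValidationError,
    read_sessions,
    tabulate_counts,
    validate_design,
    write_sessions,
)
from quadbias.synthetic_data import (
    FIXTURE_ERROR_TRIALS,
    PopulationConfig,
    generate_population,
)

IP, OP = Pairing.INGROUP_PLEASANT, Pairing.OUTGROUP_PLEASANT
CAT = StimulusCategory


def _trial(block, trial, cat=CAT.INGROUP_TARGET, pairing=IP, correct=True,
           latency=700.0):
    return TrialRecord(block, trial, cat, pairing, correct, latency)


def _session(pid="p1", trials=(), status=StatusRole.LOWER,
             order=BlockOrder.INGROUP_PLEASANT_FIRST, **kw):
    return SessionRecord(
        participant_id=pid,
        group_membership="g",
        status_role=status,
        iat_variant="race_bw",
        critical_block_order=order,
        trials=list(trials),
        **kw,
    )


class TestTrialRecord:
    def test_rejects_nonpositive_latency(self):
        with pytest.raises(ValidationError):
            _trial(3, 1, latency=-5.0)
        with pytest.raises(ValidationError):
            _trial(3, 1, latency=0.0)

    def test_pairing_only_on_critical_blocks(self):
        with pytest.raises(ValidationError):
            TrialRecord(3, 1, CAT.INGROUP_TARGET, None, True, 700.0)
        with pytest.raises(ValidationError):
            TrialRecord(1, 1, CAT.PLEASANT_WORD, IP, True, 700.0)
        # well-formed practice and critical trials
        TrialRecord(1, 1, CAT.PLEASANT_WORD, None, True, 700.0)
        _trial(7, 1, pairing=OP)


class TestReadWrite:
    def test_minimal_file(self, tmp_path):
        path = tmp_path / "trials.csv"
        path.write_text(
            "participant_id,block,trial,category,pairing,correct,latency_ms\n"
            "a,3,1,ingroup_target,ingroup_pleasant_shared,1,700\n"
            "a,3,2,pleasant_word,ingroup_pleasant_shared,0,850\n"
        )
        sessions = read_sessions(path)
        assert len(sessions) == 1 and len(sessions[0].trials) == 2
        assert sessions[0].trials[1].first_response_correct is False

    def test_negative_latency_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "participant_id,block,trial,category,pairing,correct,latency_ms\n"
            "a,3,1,ingroup_target,ingroup_pleasant_shared,1,-5\n"
        )
        with pytest.raises(ValidationError, match="row 2"):
            read_sessions(path)

    def test_unknown_category_token(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "participant_id,block,trial,category,pairing,correct,latency_ms\n"
            "a,3,1,mystery,ingroup_pleasant_shared,1,700\n"
        )
        with pytest.raises(ValidationError, match="mystery"):
            read_sessions(path)

    def test_missing_mandatory_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("participant_id,block,trial,category,pairing,correct\nx\n")
        from quadbias.iat_data import FormatError

        with pytest.raises(FormatError, match="latency_ms"):
            read_sessions(path)

    def test_interleaved_participants_partition(self, tmp_path):
        path = tmp_path / "trials.csv"
        rows = [
            "a,3,2,ingroup_target,ingroup_pleasant_shared,1,700",
            "b,3,1,pleasant_word,outgroup_pleasant_shared,1,650",
            "a,3,1,pleasant_word,ingroup_pleasant_shared,1,600",
            "b,3,2,ingroup_target,outgroup_pleasant_shared,0,800",
        ]
        path.write_text(
            "participant_id,block,trial,category,pairing,correct,latency_ms\n"
            + "\n".join(rows) + "\n"
        )
        sessions = {s.participant_id: s for s in read_sessions(path)}
        assert set(sessions) == {"a", "b"}
        # trials ordered by (block, trial) within each session
        assert [t.trial_index for t in sessions["a"].trials] == [1, 2]
        assert sessions["a"].trials[0].stimulus_category is CAT.PLEASANT_WORD
        assert sessions["b"].trials[1].first_response_correct is False

    def test_round_trip_preserves_sessions(self, tmp_path, fixture_sessions):
        path = tmp_path / "out.csv"
        write_sessions(fixture_sessions, path)
        back = read_sessions(path)
        by_id = {s.participant_id: s for s in back}
        for orig in fixture_sessions:
            got = by_id[orig.participant_id]
            assert got.status_role == orig.status_role
            assert got.critical_block_order == orig.critical_block_order
            assert got.thermometer_ingroup == orig.thermometer_ingroup
            assert got.trials == orig.trials


class TestTabulate:
    def test_all_correct_session(self):
        trials = []
        for block, pairing in ((3, IP), (6, OP)):
            for i, cat in enumerate(CAT):
                trials.append(_trial(block, i + 1, cat, pairing))
        table = tabulate_counts(_session(trials=trials))
        assert table.n_total == 8
        assert all(ni == 0 for _, ni in table.counts.values())

    def test_additivity_over_sessions(self, fixture_sessions):
        s1, s2 = fixture_sessions[0], fixture_sessions[1]
        combined = tabulate_counts([s1, s2])
        summed = tabulate_counts(s1) + tabulate_counts(s2)
        assert combined.counts == summed.counts

    def test_permutation_invariance(self, fixture_sessions):
        s = fixture_sessions[0]
        shuffled_trials = list(s.trials)
        random.Random(5).shuffle(shuffled_trials)
        shuffled = _session(pid=s.participant_id, trials=shuffled_trials,
                            status=s.status_role, order=s.critical_block_order)
        assert tabulate_counts(s).counts == tabulate_counts(shuffled).counts
        sessions = list(fixture_sessions)
        assert (
            tabulate_counts(sessions).counts
            == tabulate_counts(sessions[::-1]).counts
        )

    def test_fixture_hand_tally(self, fixture_sessions):
        """Participant f1: 15 trials/category/pairing, two deliberate errors.

        The category cycle places block-3 trial 1 on an ingroup face and
        trial 2 on a pleasant word; those are the only incorrect responses.
        """
        table = tabulate_counts(fixture_sessions[0])
        assert table.n_total == 120
        assert FIXTURE_ERROR_TRIALS == ((3, 1), (3, 2))
        expected = {}
        for cell in CELLS:
            expected[cell] = (15, 0)
        expected[(CAT.INGROUP_TARGET, IP)] = (14, 1)
        expected[(CAT.PLEASANT_WORD, IP)] = (14, 1)
        assert dict(table.counts) == expected

    def test_critical_only_total(self, fixture_sessions):
        s = fixture_sessions[0]
        n_critical = sum(1 for t in s.trials if t.is_critical)
        assert tabulate_counts(s).n_total == n_critical == 120


class TestValidateDesign:
    def test_canonical_session_passes(self, fixture_sessions):
        assert validate_design(fixture_sessions[0], DESIGN_STANDARD) == []

    def test_missing_block_named(self, fixture_sessions):
        s = fixture_sessions[0]
        truncated = _session(trials=[t for t in s.trials if t.block_index != 7])
        violations = validate_design(truncated, DESIGN_STANDARD)
        assert any("block 7" in v for v in violations)

    def test_short_critical_variant(self):
        config = PopulationConfig(
            n_participants=1, trial_design=DESIGN_SHORT_CRITICAL, seed=3
        )
        sessions, _ = generate_population(config)
        assert validate_design(sessions[0], DESIGN_SHORT_CRITICAL) == []
        assert validate_design(sessions[0], DESIGN_STANDARD) != []
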