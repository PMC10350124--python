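import numpy as np
import pytest

from vocsim import (
    ErrorModel,
    Stimulus,
    SynthSpec,
    build_condition_grid,
    mock_recognizer,
    run_experiment,
    save_results,
    summarize,
    synth_stimulus,
    total_presentations,
)
from vocsim.experiment import ExperimentResult
from vocsim.scoring import ScoreResult
from vocsim.vocoder import VocoderParams


@pytest.fixture(scope="module")
def stimuli():
    out = []
    for i in range(3):
        sig, _ = synth_stimulus(
            SynthSpec(f0=150.0 + 40.0 * i, am_rate=4.0 + i, duration=0.4, seed=i)
        )
        out.append(Stimulus(f"s{i}", sig, f"token number {i}"))
    return out


@pytest.fixture(scope="module")
def identity_recognizer(stimuli):
    return mock_recognizer({s.id: s.transcript for s in stimuli})


class TestConditionGrid:
    def test_cartesian_product_with_noise(self):
        grid = build_condition_grid(
            {"sweep": {"n_channels": [4, 6]}, "noise": {"snrs": ["quiet", 5]}}
        )
        assert len(grid) == 4
        assert len({c.label for c in grid}) == 4

    def test_unswept_parameters_take_defaults(self):
        grid = build_condition_grid({"sweep": {"n_channels": [4]}})
        p = grid[0].params
        assert p.env_cutoff == 100.0
        assert p.dynamic_range_db == "full"
        assert p.quant_steps == "infinite"
        assert p.edge_mode == "equal_octave"
        assert (p.f_low, p.f_high) == (200.0, 7900.0)

    def test_empty_config_rejected(self):
        with pytest.raises(ValueError):
            build_condition_grid({})
        with pytest.raises(ValueError):
            build_condition_grid({"sweep": {"n_channels": []}})

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            build_condition_grid({"sweep": {"bogus": [1]}})

    def test_out_of_range_warns_by_default(self, caplog):
        with caplog.at_level("WARNING"):
            build_condition_grid({"sweep": {"env_cutoff": [1000.0]}})
        assert any("outside" in r.message for r in caplog.records)

    def test_out_of_range_raises_in_strict_mode(self):
        with pytest.raises(ValueError, match="outside"):
            build_condition_grid({"sweep": {"env_cutoff": [1000.0]}, "strict": True})

    def test_deterministic_ordering(self):
        cfg = {"sweep": {"env_cutoff": [50, 100], "n_channels": [4, 8]}}
        labels = [c.label for c in build_condition_grid(cfg)]
        assert labels == [c.label for c in build_condition_grid(cfg)]
        assert labels[0].startswith("n_channels=4")


class TestRunExperiment:
    def test_identity_pipeline_scores_100(self, stimuli, identity_recognizer):
        grid = build_condition_grid({"sweep": {"n_channels": [8]}})
        res = run_experiment(stimuli, grid, identity_recognizer, reps=2, base_seed=1)
        assert all(s.percent == 100.0 for s in res.scores[grid[0].label])

    def test_reps_stored_per_condition(self, stimuli, identity_recognizer):
        grid = build_condition_grid({"sweep": {"n_channels": [4, 8]}})
        res = run_experiment(stimuli, grid, identity_recognizer, reps=5, base_seed=1)
        assert all(len(v) == 5 for v in res.scores.values())

    def test_rerun_is_deterministic(self, stimuli, identity_recognizer):
        grid = build_condition_grid(
            {"sweep": {"n_channels": [4]}, "noise": {"snrs": [5]}}
        )
        a = run_experiment(stimuli, grid, identity_recognizer, reps=2, base_seed=3)
        b = run_experiment(stimuli, grid, identity_recognizer, reps=2, base_seed=3)
        assert summarize(a).equals(summarize(b))

    def test_total_deletion_error_model_scores_zero(self, stimuli):
        rec = mock_recognizer(
            {s.id: s.transcript for s in stimuli}, ErrorModel(p_del=1.0)
        )
        grid = build_condition_grid({"sweep": {"n_channels": [8]}})
        res = run_experiment(stimuli, grid, rec, reps=1, base_seed=0)
        assert res.scores[grid[0].label][0].percent == 0.0

    def test_failing_recognizer_scored_as_empty(self, stimuli):
        class Crashing:
            name = "crash"
            stochastic = False

            def transcribe(self, audio, stimulus_id=None):
                raise RuntimeError("boom")

        grid = build_condition_grid({"sweep": {"n_channels": [8]}})
        res = run_experiment(stimuli, grid, Crashing(), reps=1, base_seed=0)
        assert res.scores[grid[0].label][0].percent == 0.0

    def test_word_list_material(self, stimuli, identity_recognizer):
        grid = build_condition_grid(
            {"sweep": {"n_channels": [8]}, "material": "word_lists"}
        )
        res = run_experiment(stimuli, grid, identity_recognizer, reps=1, base_seed=0)
        assert res.scores[grid[0].label][0].percent == 100.0

    def test_invalid_args_rejected(self, stimuli, identity_recognizer):
        grid = build_condition_grid({"sweep": {"n_channels": [8]}})
        with pytest.raises(ValueError):
            run_experiment(stimuli, grid, identity_recognizer, reps=0)
        with pytest.raises(ValueError):
            run_experiment([], grid, identity_recognizer, reps=1)


class TestSummarize:
    def _result(self, percents_by_label):
        from vocsim.experiment import Condition

        conds = [
            Condition(params=VocoderParams(n_channels=8), label=label)
            for label in percents_by_label
        ]
        scores = {
            label: [ScoreResult(int(p), 100) for p in percents]
            for label, percents in percents_by_label.items()
        }
        return ExperimentResult(conditions=conds, scores=scores)

    def test_mean_and_sample_sd(self):
        df = summarize(self._result({"c": [80, 90]}))
        assert df.loc[0, "mean_percent"] == pytest.approx(85.0)
        assert df.loc[0, "sd_percent"] == pytest.approx(7.0710678, rel=1e-6)
        assert df.loc[0, "sem_percent"] == pytest.approx(5.0)

    def test_single_rep_sd_zero(self):
        df = summarize(self._result({"c": [80]}))
        assert df.loc[0, "sd_percent"] == 0.0

    def test_row_per_condition(self):
        df = summarize(self._result({"a": [10], "b": [20], "c": [30], "d": [40]}))
        assert len(df) == 4

    def test_aggregation_invariant_to_repetition_order(self):
        fwd = summarize(self._result({"c": [60, 70, 80]}))
        rev = summarize(self._result({"c": [80, 70, 60]}))
        assert fwd.loc[0, "mean_percent"] == rev.loc[0, "mean_percent"]
        assert fwd.loc[0, "sd_percent"] == rev.loc[0, "sd_percent"]

    def test_empty_result_rejected(self):
        with pytest.raises(ValueError):
            summarize(ExperimentResult(conditions=[], scores={}))

    def test_save_results_files(self, tmp_path):
        res = self._result({"c": [80, 90]})
        csv, js = tmp_path / "r.csv", tmp_path / "r.json"
        save_results(res, csv, js)
        assert csv.exists() and js.exists()
        assert "n_correct" in js.read_text()


class TestScaleArithmetic:
    def test_presentation_counts(self):
        assert total_presentations(60, 5, 900) == 270_000
        assert total_presentations(200, 5, 900) == 900_000
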