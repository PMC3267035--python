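import json

import numpy as np
import pandas as pd
import pytest

from dualroute.model_selection import EvidenceMatrix, rfx_bms
from dualroute.sweep_pipeline import (
    SweepConfig,
    SweepResult,
    report,
    run_model_space_validation,
    run_sweep,
    summarize_epochs,
    window_grid,
)
from dualroute.synthetic_data import generate_dataset


class TestWindowGrid:
    def test_default_grid(self):
        grid = window_grid()
        assert grid == tuple(range(50, 251, 10))
        assert len(grid) == 21

    def test_degenerate_grid(self):
        assert window_grid(50, 50, 10) == (50,)

    @pytest.mark.parametrize("args", [(50, 255, 10), (100, 50, 10), (50, 250, 7)])
    def test_non_conforming_grids_rejected(self, args):
        with pytest.raises(ValueError):
            window_grid(*args)


def fabricated_sweep(probs_by_window, windows, condition="deviant_fearful"):
    """SweepResult with hand-set CS probabilities (C gets the complement)."""
    rfx = {}
    for T, p in zip(windows, probs_by_window):
        rfx[(condition, T)] = type(
            "FakeRFX",
            (),
            {
                "model_ids": ("CS", "C"),
                "prob": lambda self, mid, kind="exceedance", p=p: (
                    p if mid == "CS" else 1 - p
                ),
            },
        )()
    return SweepResult(
        conditions=(condition,),
        windows=tuple(windows),
        model_ids=("CS", "C"),
        evidence={},
        rfx=rfx,
        accuracy={},
        failures=[],
        incomplete_windows=[],
    )


class TestEpochSummaries:
    def test_median_of_constant_epochs(self):
        windows = tuple(range(50, 251, 10))
        probs = [0.9 if T < 200 else 0.5 for T in windows]
        sweep = fabricated_sweep(probs, windows)
        table = summarize_epochs(sweep, 200)
        cs = table[table.model == "CS"].set_index("epoch").median_probability
        # T == 200 (0.5 in this construction) belongs to neither epoch
        assert cs["early"] == pytest.approx(0.9)
        assert cs["late"] == pytest.approx(0.5)

    def test_uniform_probability_gives_same_epochs(self):
        windows = tuple(range(50, 251, 10))
        sweep = fabricated_sweep([0.7] * 21, windows)
        table = summarize_epochs(sweep, 200)
        assert np.allclose(
            table[table.model == "CS"].median_probability, 0.7
        )

    def test_split_window_excluded_from_both_epochs(self):
        windows = tuple(range(50, 251, 10))
        sweep = fabricated_sweep([0.5] * 21, windows)
        table = summarize_epochs(sweep, 200)
        assert set(table.n_windows) == {15, 5}  # 50..190 and 210..250

    def test_constructed_evidence_dissociation(self):
        """Evidence dominated by CS early (5 nats/subject) and tied late
        produces the early/late probability dissociation downstream."""
        subjects = tuple(f"s{i}" for i in range(12))
        probs = []
        windows = (50, 100, 150, 210, 250)
        for T in windows:
            margin = 5.0 if T < 200 else 0.0
            L = np.zeros((12, 2))
            L[:, 0] = margin
            res = rfx_bms(
                EvidenceMatrix(subjects, ("CS", "C"), L), seed=T
            )
            probs.append(res.prob("CS"))
        sweep = fabricated_sweep(probs, windows)
        table = summarize_epochs(sweep, 200)
        cs = table[table.model == "CS"].set_index("epoch").median_probability
        assert cs["early"] >= 0.9
        assert cs["late"] == pytest.approx(0.5, abs=0.02)

    def test_empty_epoch_rejected(self):
        sweep = fabricated_sweep([0.9, 0.8], (50, 60))
        with pytest.raises(ValueError, match="late"):
            summarize_epochs(sweep, 200)


@pytest.fixture(scope="module")
def tiny_dataset():
    """2 subjects are enough to exercise the full sweep machinery."""
    ds, _ = generate_dataset("CS", n_subjects=2, seed=31)
    return ds


@pytest.fixture(scope="module")
def tiny_sweep(tiny_dataset, tmp_path_factory):
    out = tmp_path_factory.mktemp("sweep")
    cfg = SweepConfig(
        model_ids=("CS", "C"),
        windows=(50, 150),
        conditions=("deviant_fearful", "standard_neutral"),
        out_dir=str(out),
        master_seed=31,
        n_mc_samples=20_000,
    )
    return cfg, run_sweep(cfg, dataset=tiny_dataset), out


class TestRunSweep:
    def test_structure_complete(self, tiny_sweep):
        cfg, sweep, _ = tiny_sweep
        assert set(sweep.rfx) == {
            (c, T) for c in sweep.conditions for T in (50, 150)
        }
        assert sweep.failures == [] and sweep.incomplete_windows == []
        for rf in sweep.rfx.values():
            assert rf.expected_prob.sum() == pytest.approx(1.0)
            assert abs(rf.exceedance_prob.sum() - 1.0) < 0.01

    def test_outputs_written_and_parseable(self, tiny_sweep):
        _, sweep, out = tiny_sweep
        assert (out / "bms_by_window.tsv").exists()
        ev = EvidenceMatrix.from_tsv(out / "evidence_deviant_fearful_T050.tsv")
        assert np.allclose(
            ev.log_evidence,
            sweep.evidence[("deviant_fearful", 50)].log_evidence,
        )
        meta = json.loads((out / "sweep.json").read_text())
        assert meta["provenance"]["master_seed"] == 31

    def test_rerun_hits_cache_and_is_identical(self, tiny_dataset, tiny_sweep):
        cfg, sweep, out = tiny_sweep
        n_cache = len(list((out / "cache").glob("*.json")))
        assert n_cache == 2 * 2 * 2 * 2  # subjects x models x windows x conds
        again = run_sweep(cfg, dataset=tiny_dataset)
        for key in sweep.evidence:
            assert np.array_equal(
                sweep.evidence[key].log_evidence,
                again.evidence[key].log_evidence,
            )
            assert np.array_equal(
                sweep.rfx[key].exceedance_prob, again.rfx[key].exceedance_prob
            )
        assert len(list((out / "cache").glob("*.json"))) == n_cache

    def test_per_condition_independence(self, tiny_dataset, tiny_sweep):
        """Analysing a condition alone reproduces its joint-run results."""
        cfg, sweep, out = tiny_sweep
        solo_cfg = SweepConfig(
            model_ids=cfg.model_ids,
            windows=cfg.windows,
            conditions=("deviant_fearful",),
            out_dir=cfg.out_dir,  # same cache
            master_seed=cfg.master_seed,
            n_mc_samples=cfg.n_mc_samples,
        )
        solo = run_sweep(solo_cfg, dataset=tiny_dataset)
        for T in cfg.windows:
            key = ("deviant_fearful", T)
            assert np.array_equal(
                solo.evidence[key].log_evidence,
                sweep.evidence[key].log_evidence,
            )
            assert np.array_equal(
                solo.rfx[key].exceedance_prob,
                sweep.rfx[key].exceedance_prob,
            )

    def test_unknown_condition_rejected(self, tiny_dataset):
        cfg = SweepConfig(conditions=("deviant_sad",), windows=(50,))
        with pytest.raises(ValueError, match="deviant_sad"):
            run_sweep(cfg, dataset=tiny_dataset)


class TestReport:
    def test_probability_plots_and_tables(self, tiny_sweep, tmp_path):
        _, sweep, _ = tiny_sweep
        written = report(sweep, tmp_path)
        names = {p.name for p in written}
        assert "probability_vs_window_deviant_fearful.png" in names
        assert "epoch_summary.tsv" not in names  # split=200 has no windows
        # with a fabricated full grid the epoch table is written too
        full = fabricated_sweep([0.8] * 21, tuple(range(50, 251, 10)))
        written = report(full, tmp_path / "full")
        table = pd.read_csv(tmp_path / "full" / "epoch_summary.tsv", sep="\t")
        assert len(table) == 4  # 2 models x 2 epochs

    def test_empty_condition_filter_rejected(self, tiny_sweep, tmp_path):
        _, sweep, _ = tiny_sweep
        with pytest.raises(ValueError):
            report(sweep, tmp_path, conditions=())
        with pytest.raises(ValueError, match="not in sweep"):
            report(sweep, tmp_path, conditions=("deviant_happy",))


def test_model_space_validation_ranks_true_architecture_first(tmp_path):
    """With data generated from the amygdala (CS) truth, the amygdala model
    outranks deep-source substitutes (hippocampus, inferior colliculus)."""
    ds, _ = generate_dataset("CS", n_subjects=2, seed=41)
    cfg = SweepConfig(
        conditions=("deviant_fearful",),
        master_seed=41,
        n_mc_samples=20_000,
        out_dir=str(tmp_path),
    )
    table = run_model_space_validation(
        cfg, dataset=ds, model_ids=("CS", "HIPP", "IC"), window_ms=250
    )
    best = table[table["rank"] == 1]
    assert list(best.model) == ["CS"]
    second = table[table["rank"] == 2].iloc[0]
    assert second.ln_gbf_best_vs_this > 0
    assert second.evidence_vs_best in (
        "weak", "positive", "strong", "very strong"
    )
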