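import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner
from dataclasses import replace

from survinterim.cli import main as cli_main
from survinterim.study_design import StudyDesign
from survinterim.synthetic_cohort import (
    CorrelationModel,
    EffectModel,
    SurvivalModel,
)
from survinterim.trial_engine import (
    AlignmentError,
    SimulationConfig,
    config_from_dict,
    config_to_dict,
    load_config,
    profile_config,
    results_frame,
    run_monte_carlo,
    run_on_data,
    run_study,
    scaled,
)


def small_config(**overrides):
    base = dict(
        design=StudyDesign(n_patients=50, l1_intended=60.0, l2=60.0, m1=2, m2=2),
        survival_model=SurvivalModel.exponential(60.0),
        effect_model=EffectModel(tau=0.5),
        correlation=CorrelationModel(),
        d=300,
        n_runs=5,
        base_seed=99,
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestRunStudy:
    def test_determinism(self):
        config = small_config()
        a = run_study(config, 3)
        b = run_study(config, 3)
        for ra, rb in zip(a.results, b.results):
            assert ra.r == rb.r
            assert ra.time == rb.time
            assert ra.decision.fdp == rb.decision.fdp
            for v in config.variants:
                assert ra.apr[v].apr_hat == rb.apr[v].apr_hat
        assert a.first_stop == b.first_stop

    def test_null_run_has_zero_true_apr(self):
        config = small_config(effect_model=EffectModel(tau=0.0))
        study = run_study(config, 0)
        for res in study.results:
            assert res.decision.apr_true == 0.0

    def test_counts_non_decreasing(self):
        study = run_study(small_config(), 1)
        n = [res.n_included for res in study.results]
        events = [res.n_events for res in study.results]
        assert n == sorted(n)
        assert events == sorted(events)
        assert n[-1] == 50

    def test_all_looks_computed_even_after_stop(self):
        config = small_config(
            design=StudyDesign(
                n_patients=50, l1_intended=60.0, l2=60.0, m1=2, m2=2,
                apr_threshold=0.01,
            )
        )
        study = run_study(config, 0)
        assert len(study.results) == 4

    def test_stop_flag_consistent_with_estimate(self):
        study = run_study(small_config(), 2)
        thr = 0.8
        for res in study.results:
            for v, est in res.apr.items():
                assert res.stop[v] == (est.apr_hat >= thr)

    def test_true_apr_increases_over_recruitment(self):
        # With accumulating samples and strong effects, power at the end of
        # recruitment exceeds power at the first look in nearly every run.
        config = small_config(d=2000, effect_model=EffectModel(tau=0.5, sd=1.6))
        wins = 0
        for r in range(20):
            study = run_study(config, r)
            apr = [res.decision.apr_true for res in study.results]
            wins += apr[1] >= apr[0]
        assert wins >= 19


class TestRunMonteCarlo:
    def test_single_run_summary(self):
        config = small_config(n_runs=1)
        summary = run_monte_carlo(config)
        study = run_study(config, 0)
        assert np.allclose(summary.r[0], [res.r for res in study.results])
        frame = summary.to_frame()
        assert np.all(frame["found_sd"] == 0.0)

    def test_stop_fractions_partition(self):
        config = small_config(n_runs=8, d=500)
        summary = run_monte_carlo(config)
        for v in config.variants:
            total = summary.stop_fractions(v).sum() + summary.never_stopped_fraction(v)
            assert total == pytest.approx(1.0)

    def test_mean_true_apr_non_decreasing(self):
        config = small_config(d=800, n_runs=10)
        summary = run_monte_carlo(config)
        apr = summary.apr_true.mean(axis=0)
        assert apr[-1] >= apr[0]
        assert np.all(np.diff(apr) >= -0.02)  # within MC noise

    def test_summary_frame_columns(self):
        summary = run_monte_carlo(small_config(n_runs=2, d=100))
        frame = summary.to_frame()
        for col in ("analysis", "found_mean", "fdp_mean", "apr_true_mean",
                    "apr_hat_fixed_theta_mean", "stop_fraction_fixed_theta"):
            assert col in frame.columns
        runs = summary.runs_frame()
        assert len(runs) == 2 * 4


class TestRunOnData:
    def _fixture(self, rng, n=10, d=20):
        expr = pd.DataFrame(
            rng.normal(0, 1, (d, n)),
            index=[f"g{i}" for i in range(d)],
            columns=[f"s{j}" for j in range(n)],
        )
        patients = pd.DataFrame(
            {
                "patient_id": [f"s{j}" for j in range(n)],
                "arrival_month": rng.uniform(0, 20, n),
                "survival_month": rng.exponential(30, n),
                "event": 1,
            }
        )
        design = StudyDesign(n_patients=n, l1_intended=20.0, l2=40.0, m1=2, m2=2)
        return expr, patients, design

    def test_smoke_end_to_end(self, rng):
        expr, patients, design = self._fixture(rng)
        results = run_on_data(expr, patients, design)
        assert len(results) == 4
        assert all(res.decision is None for res in results)
        frame = results_frame(results)
        assert len(frame) == 4
        assert "apr_hat_fixed_theta" in frame.columns

    def test_duplicated_gene_identical_pvalues(self, rng):
        expr, patients, design = self._fixture(rng)
        expr.loc["g0_copy"] = expr.loc["g0"]
        results = run_on_data(expr, patients, design)
        assert len(results) == 4  # smoke: pipeline tolerates duplicate rows

        # p-values equal per look for the duplicated rows
        from survinterim.cox_screen import screen_genes
        from survinterim.study_design import PatientCohort, take_snapshot

        cohort = PatientCohort(
            arrivals=patients["arrival_month"].to_numpy(),
            survival=patients["survival_month"].to_numpy(),
        )
        snap = take_snapshot(cohort, 60.0)
        p = screen_genes(snap, expr.to_numpy())
        assert p[0] == p[-1]

    def test_misaligned_ids_error_names_samples(self, rng):
        expr, patients, design = self._fixture(rng)
        patients.loc[0, "patient_id"] = "mystery"
        with pytest.raises(AlignmentError, match="mystery"):
            run_on_data(expr, patients, design)

    def test_missing_arrivals_drawn_reproducibly(self, rng):
        expr, patients, design = self._fixture(rng)
        patients = patients.drop(columns=["arrival_month"])
        a = results_frame(run_on_data(expr, patients, design, arrival_seed=5))
        b = results_frame(run_on_data(expr, patients, design, arrival_seed=5))
        pd.testing.assert_frame_equal(a, b)

    def test_pure_noise_rarely_rejects(self, rng):
        hits = 0
        for seed in range(5):
            local = np.random.default_rng(seed)
            expr, patients, design = self._fixture(local, n=20, d=50)
            results = run_on_data(expr, patients, design)
            hits += sum(res.r for res in results)
        assert hits <= 2


class TestConfig:
    def test_round_trip(self):
        config = small_config()
        back = config_from_dict(config_to_dict(config))
        assert back == config

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown config keys"):
            config_from_dict({"n_patients": 50, "bogus": 1})

    def test_load_yaml(self, tmp_path):
        path = tmp_path / "config.yaml"
        path.write_text("n_patients: 10\nm1: 2\nm2: 2\nd: 50\nn_runs: 2\n")
        config = load_config(str(path))
        assert config.design.n_patients == 10
        assert config.d == 50

    def test_profiles_instantiate(self):
        for name in ("m4-tau50", "m10-tau50", "m10-tau50-small", "m10-tau5", "breast"):
            config = profile_config(name)
            assert config.n_runs == 1000
        breast = profile_config("breast")
        assert breast.d == 24496
        assert breast.effect_model.mode == "table"
        assert breast.survival_model.family == "lognormal"
        assert breast.correlation.sigma2 == pytest.approx(0.1)

    def test_unknown_profile(self):
        with pytest.raises(KeyError):
            profile_config("nope")

    def test_scaled(self):
        config = scaled(profile_config("m4-tau50"), d=100, n_runs=3)
        assert config.d == 100
        assert config.n_runs == 3


class TestCli:
    def test_simulate_with_profile(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "out"
        result = runner.invoke(
            cli_main,
            ["simulate", "--profile", "m4-tau50", "--out", str(out),
             "--runs", "2", "--genes", "100", "--seed", "1"],
        )
        assert result.exit_code == 0, result.output
        summary = pd.read_csv(out / "summary.csv")
        assert len(summary) == 4
        echoed = yaml.safe_load((out / "config.yaml").read_text())
        assert echoed["n_runs"] == 2
        assert echoed["d"] == 100

    def test_simulate_requires_one_source(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(cli_main, ["simulate", "--out", str(tmp_path)])
        assert result.exit_code != 0

    def test_analyze_command(self, tmp_path, rng):
        expr = pd.DataFrame(
            rng.normal(0, 1, (15, 8)),
            index=[f"g{i}" for i in range(15)],
            columns=[f"s{j}" for j in range(8)],
        )
        expr.index.name = "gene_id"
        expr_path = tmp_path / "expr.csv"
        expr.to_csv(expr_path)
        patients = pd.DataFrame(
            {
                "patient_id": [f"s{j}" for j in range(8)],
                "arrival_month": rng.uniform(0, 10, 8),
                "survival_month": rng.exponential(20, 8),
                "event": 1,
            }
        )
        pat_path = tmp_path / "patients.csv"
        patients.to_csv(pat_path, index=False)
        config_path = tmp_path / "config.yaml"
        config_path.write_text("n_patients: 8\nl1: 10\nl2: 20\nm1: 2\nm2: 2\nd: 15\n")
        out = tmp_path / "out"
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            ["analyze", "--expr", str(expr_path), "--patients", str(pat_path),
             "--config", str(config_path), "--out", str(out)],
        )
        assert result.exit_code == 0, result.output
        frame = pd.read_csv(out / "analyses.csv")
        assert len(frame) == 4
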