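import warnings
from collections import Counter

import pytest
from click.testing import CliRunner

from endovalid.analysis_reports import (
    DEFAULT_FN_VOCAB,
    SmallSampleWarning,
    error_analysis_fn,
    error_analysis_fp,
    run_pipeline,
    subgroup_report,
)
from endovalid.claims_processing import filter_claims_window, test_labels as derive_test_labels
from endovalid.cli import cli
from endovalid.cohort_io import (
    RunConfig,
    read_claims_table,
    read_surgical_table,
    write_claims_table,
    write_surgical_table,
)
from endovalid.diagnostic_accuracy import build_contingency
from endovalid.surgical_typology import reference_labels
from endovalid.synthetic_cohort import (
    FIXTURE_EXPECTED,
    GeneratorSpec,
    generate_cohort,
    generate_fixture_small,
)


@pytest.fixture()
def fixture_run(tmp_path, config):
    records, claims = generate_fixture_small()
    surgical = tmp_path / "surgical.csv"
    claims_path = tmp_path / "claims.csv"
    write_surgical_table(records, surgical)
    write_claims_table(claims, claims_path)
    cfg = RunConfig(rng_seed=13, bootstrap_reps=200)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SmallSampleWarning)
        bundle = run_pipeline(surgical, claims_path, cfg, tmp_path / "out")
    return bundle, tmp_path / "out"


class TestErrorAnalysisFN:
    def test_fixture_hand_tally(self, fixture_cohort, config):
        records, claims = fixture_cohort
        dates = {r.participant_id: r.surgery_date for r in records}
        retained = filter_claims_window(claims, dates, config)
        counts = error_analysis_fn(
            FIXTURE_EXPECTED["fn_participants"], retained, DEFAULT_FN_VOCAB
        )
        assert counts == Counter(FIXTURE_EXPECTED["fn_code_categories"])

    def test_no_fn_participants_empty(self, fixture_cohort, config):
        records, claims = fixture_cohort
        dates = {r.participant_id: r.surgery_date for r in records}
        retained = filter_claims_window(claims, dates, config)
        assert error_analysis_fn([], retained, DEFAULT_FN_VOCAB) == Counter()

    def test_unmatched_code_falls_into_other(self, fixture_cohort, config):
        records, claims = fixture_cohort
        dates = {r.participant_id: r.surgery_date for r in records}
        retained = filter_claims_window(claims, dates, config)
        counts = error_analysis_fn(["p07", "p10"], retained, {})
        assert counts == Counter({"other": 2})

    def test_participant_counted_once_per_category(self, fixture_cohort, config):
        records, claims = fixture_cohort
        dates = {r.participant_id: r.surgery_date for r in records}
        retained = filter_claims_window(claims, dates, config)
        doubled = retained + retained
        counts = error_analysis_fn(["p07"], doubled, DEFAULT_FN_VOCAB)
        assert counts == Counter({"pain": 1})


class TestErrorAnalysisFP:
    def test_fixture_fp_subtype_tally(self, fixture_labels):
        _, tst = fixture_labels
        counts = error_analysis_fp(FIXTURE_EXPECTED["fp_participants"], tst)
        assert counts == Counter(FIXTURE_EXPECTED["fp_subtypes"])

    def test_no_fps_empty(self, fixture_labels):
        _, tst = fixture_labels
        assert error_analysis_fp([], tst) == Counter()

    def test_nos_only_fp_counted_as_nos(self):
        tst = {"x": {"overall": True, "SE": False, "OE": False, "DE": False}}
        assert error_analysis_fp(["x"], tst) == Counter({"NOS": 1})

    def test_perfect_specificity_cohort_has_empty_tally(self):
        spec = GeneratorSpec(
            n_participants=200, coding_specificity=1.0, rng_seed=31
        )
        records, claims = generate_cohort(spec)
        cfg = RunConfig(rng_seed=31)
        ref = reference_labels(records)
        dates = {r.participant_id: r.surgery_date for r in records}
        tst = derive_test_labels(claims, dates, cfg)
        fp_ids = [
            pid for pid in ref if not ref[pid]["overall"] and tst[pid]["overall"]
        ]
        assert error_analysis_fp(fp_ids, tst) == Counter()


class TestSubgroupReport:
    def test_fixture_strata_counts_and_small_sample_flags(self, fixture_labels, fixture_cohort):
        records, _ = fixture_cohort
        ref, tst = fixture_labels
        cfg = RunConfig(rng_seed=3, bootstrap_reps=200)
        with pytest.warns(SmallSampleWarning):
            report = subgroup_report(ref, tst, records, cfg)
        # woc pools woc + unknown race by default: p03, p09, p10
        assert report["woc"]["n"] == 3 and report["woc"]["small_sample"]
        assert report["white"]["n"] == 7
        assert report["hispanic"]["n"] == 3   # p04, p06, p10
        assert report["non_hispanic"]["n"] == 6  # p09 (missing) excluded

    def test_unknown_race_exclusion_switch(self, fixture_labels, fixture_cohort):
        records, _ = fixture_cohort
        ref, tst = fixture_labels
        cfg = RunConfig(
            rng_seed=3, bootstrap_reps=200, include_unknown_race_in_woc=False
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SmallSampleWarning)
            report = subgroup_report(ref, tst, records, cfg)
        assert report["woc"]["n"] == 2  # p03, p10 only

    def test_fixture_point_estimates_match_hand_tables(self, fixture_labels, fixture_cohort):
        records, _ = fixture_cohort
        ref, tst = fixture_labels
        cfg = RunConfig(rng_seed=3, bootstrap_reps=200)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SmallSampleWarning)
            report = subgroup_report(ref, tst, records, cfg)
        # white stratum by hand: p01 TP, p02 TP, p04 TP, p05 TP, p06 FP,
        # p07 FN, p08 TN -> agreement 5/7
        assert report["white"]["metrics"]["percent_agreement"].point == pytest.approx(5 / 7)

    def test_smaller_stratum_has_wider_ci(self):
        # stratified cohort shaped like the published one (49 vs 363):
        # with demographic-independent errors the small stratum's kappa CI
        # must be wider
        spec = GeneratorSpec(rng_seed=29)
        records, claims = generate_cohort(spec)
        cfg = RunConfig(rng_seed=29)
        ref = reference_labels(records)
        dates = {r.participant_id: r.surgery_date for r in records}
        tst = derive_test_labels(claims, dates, cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SmallSampleWarning)
            report = subgroup_report(ref, tst, records, cfg)
        assert report["woc"]["n"] < report["white"]["n"]
        woc = report["woc"]["metrics"]["kappa"]
        white = report["white"]["metrics"]["kappa"]
        assert (woc.upper - woc.lower) > (white.upper - white.lower)
        # exchangeability: each stratum's point inside the other's CI
        assert white.lower <= woc.point <= white.upper or \
            woc.lower <= white.point <= woc.upper


class TestRunPipeline:
    def test_fixture_run_outputs_and_counts(self, fixture_run):
        bundle, out = fixture_run
        for name in (
            "accuracy_table.csv",
            "accuracy_table.txt",
            "subgroup_table.csv",
            "error_fn.csv",
            "error_fp.csv",
            "run_log.txt",
        ):
            assert (out / name).exists(), name
        counts = bundle["stage_counts"]
        assert counts["participants"] == 10
        assert counts["cases"] == 7
        assert counts["claims_read"] == 11
        assert counts["claims_removed_window"] == FIXTURE_EXPECTED["window_removed_claims"]
        assert counts["claims_read"] == (
            counts["claims_retained"] + counts["claims_removed_window"]
        )
        assert counts["false_negatives"] == bundle["overall_table"].fn == 2
        assert counts["false_positives"] == bundle["overall_table"].fp == 1
        assert bundle["fn_participants"] == FIXTURE_EXPECTED["fn_participants"]
        assert bundle["fp_participants"] == FIXTURE_EXPECTED["fp_participants"]
        assert bundle["fn_counts"] == Counter(FIXTURE_EXPECTED["fn_code_categories"])
        assert bundle["fp_counts"] == Counter(FIXTURE_EXPECTED["fp_subtypes"])

    def test_error_counts_match_overall_table(self, fixture_run):
        bundle, _ = fixture_run
        assert len(bundle["fn_participants"]) == bundle["overall_table"].fn
        assert len(bundle["fp_participants"]) == bundle["overall_table"].fp

    def test_empty_claims_file(self, tmp_path):
        records, _ = generate_fixture_small()
        surgical = tmp_path / "s.csv"
        claims = tmp_path / "c.csv"
        write_surgical_table(records, surgical)
        write_claims_table([], claims)
        cfg = RunConfig(rng_seed=2, bootstrap_reps=100)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SmallSampleWarning)
            bundle = run_pipeline(surgical, claims, cfg, tmp_path / "out")
        t = bundle["overall_table"]
        assert t.tp == 0 and t.fp == 0
        assert bundle["report"].comparisons["overall"]["specificity"].point == 1.0
        assert bundle["report"].comparisons["overall"]["sensitivity"].point == 0.0

    def test_unknown_claim_participant_attributes_stage(self, tmp_path):
        records, claims = generate_fixture_small()
        ghost = claims[0].__class__(
            "ghost", claims[0].code_system, "617.1",
            claims[0].service_date, claims[0].source,
        )
        surgical = tmp_path / "s.csv"
        claims_path = tmp_path / "c.csv"
        write_surgical_table(records, surgical)
        write_claims_table(claims + [ghost], claims_path)
        with pytest.raises(RuntimeError, match="window_filter"):
            run_pipeline(
                surgical, claims_path, RunConfig(rng_seed=1), tmp_path / "out"
            )

    def test_noise_free_synthetic_run_is_perfect(self, tmp_path):
        records, claims = generate_cohort(GeneratorSpec.noise_free(rng_seed=8))
        surgical = tmp_path / "s.csv"
        claims_path = tmp_path / "c.csv"
        write_surgical_table(records, surgical)
        write_claims_table(claims, claims_path)
        cfg = RunConfig(rng_seed=8, bootstrap_reps=100)
        bundle = run_pipeline(surgical, claims_path, cfg, tmp_path / "out")
        for comp, metrics in bundle["report"].comparisons.items():
            for name, est in metrics.items():
                assert est.point == 1.0, (comp, name)
        assert bundle["fn_counts"] == Counter()
        assert bundle["fp_counts"] == Counter()


class TestCLI:
    def test_synth_then_run(self, tmp_path):
        runner = CliRunner()
        data_dir = tmp_path / "data"
        result = runner.invoke(
            cli, ["synth", "--out-dir", str(data_dir), "--seed", "6"]
        )
        assert result.exit_code == 0, result.output
        assert (data_dir / "surgical.csv").exists()
        assert (data_dir / "claims.csv").exists()

        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text("bootstrap_reps: 100\nrng_seed: 6\n")
        result = runner.invoke(
            cli,
            [
                "run",
                "--surgical", str(data_dir / "surgical.csv"),
                "--claims", str(data_dir / "claims.csv"),
                "--config", str(cfg_path),
                "--out", str(tmp_path / "out"),
            ],
        )
        assert result.exit_code == 0, result.output
        assert (tmp_path / "out" / "accuracy_table.csv").exists()

    def test_synth_spec_file(self, tmp_path):
        runner = CliRunner()
        spec_path = tmp_path / "spec.yaml"
        spec_path.write_text("n_participants: 25\nrng_seed: 3\n")
        result = runner.invoke(
            cli, ["synth", "--spec", str(spec_path), "--out-dir", str(tmp_path / "d")]
        )
        assert result.exit_code == 0, result.output
        records = read_surgical_table(tmp_path / "d" / "surgical.csv")
        assert len(records) == 25

    def test_synth_rejects_unknown_spec_key(self, tmp_path):
        runner = CliRunner()
        spec_path = tmp_path / "spec.yaml"
        spec_path.write_text("n_participantz: 25\n")
        result = runner.invoke(
            cli, ["synth", "--spec", str(spec_path), "--out-dir", str(tmp_path / "d")]
        )
        assert result.exit_code != 0
        assert "n_participantz" in result.output
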