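"""Validation statistics (RSD, IS recovery, linearity) and species
authentication calls."""

import numpy as np
import pytest

from seedmark import (
    AuthThresholds,
    FixtureSpec,
    MarkerCandidate,
    PeakAreaRecord,
    Uniqueness,
    authenticate,
    authenticate_table,
    is_recovery,
    linearity,
    normalize_area,
    read_peak_table,
    records_to_frame,
    repeatability_reproducibility,
    rsd,
    simulate_dilution_series,
    simulate_peak_areas,
    validation_report,
)


def rec(peptide="WVQQAK", day=1, replicate=1, raw=1000.0, flour=1.0, **kw):
    return PeakAreaRecord(
        sample_id=kw.pop("sample_id", "S1"),
        species_label=kw.pop("species_label", "flaxseed"),
        peptide=peptide,
        replicate=replicate,
        day=day,
        raw_area=raw,
        flour_mg=flour,
        **kw,
    )


class TestNormalization:
    def test_area_per_mg_flour(self):
        assert normalize_area(rec(raw=1_000_000.0, flour=0.5)) == 2_000_000.0

    def test_zero_area_stays_zero(self):
        assert normalize_area(rec(raw=0.0)) == 0.0

    def test_zero_flour_rejected(self):
        blank = rec(raw=10.0, record_class="blank", flour=0.0)
        with pytest.raises(ValueError, match="flour_mg"):
            normalize_area(blank)

    def test_sample_record_requires_positive_flour(self):
        with pytest.raises(ValueError, match="flour_mg"):
            rec(flour=0.0)

    def test_normalization_is_linear_in_raw_area(self):
        a = normalize_area(rec(raw=123.0, flour=0.7))
        b = normalize_area(rec(raw=3 * 123.0, flour=0.7))
        assert b == pytest.approx(3 * a)


class TestRsd:
    def test_textbook_example(self):
        assert rsd([90.0, 100.0, 110.0]) == pytest.approx(10.0)

    def test_constant_values_zero(self):
        assert rsd([7.0, 7.0, 7.0]) == 0.0

    def test_scale_invariance(self):
        values = [90.0, 100.0, 110.0]
        assert rsd([5.5 * v for v in values]) == pytest.approx(rsd(values))

    @pytest.mark.parametrize("values", [[1.0], [], [-1.0, 1.0]])
    def test_degenerate_inputs_error(self, values):
        with pytest.raises(ValueError):
            rsd(values)


class TestPrecision:
    def test_constant_areas_give_zero_rsds(self):
        records = [
            rec(day=d, replicate=r, raw=500.0) for d in (1, 2) for r in (1, 2, 3)
        ]
        est = repeatability_reproducibility(records)
        assert est.intra_day_rsd == pytest.approx(0.0)
        assert est.inter_day_rsd == pytest.approx(0.0)

    def test_day_shift_shows_only_in_reproducibility(self):
        # day means 100 and 110, constant within day:
        # sd(100, 110) = 7.0711, mean 105 -> inter-day RSD 6.7344 %
        records = [
            rec(day=1, replicate=r, raw=100.0) for r in (1, 2, 3)
        ] + [rec(day=2, replicate=r, raw=110.0) for r in (1, 2, 3)]
        est = repeatability_reproducibility(records)
        assert est.intra_day_rsd == pytest.approx(0.0)
        assert est.inter_day_rsd == pytest.approx(6.7344, abs=1e-3)

    def test_single_day_reports_reason_not_crash(self):
        records = [rec(day=1, replicate=r, raw=100.0 + r) for r in (1, 2, 3)]
        est = repeatability_reproducibility(records)
        assert est.intra_day_rsd is not None
        assert est.inter_day_rsd is None
        assert "day" in est.inter_reason

    def test_multiple_peptides_rejected(self):
        with pytest.raises(ValueError, match="per peptide"):
            repeatability_reproducibility([rec(peptide="AAAAK"), rec(peptide="CCCCR")])

    def test_recovers_simulated_cvs(self):
        """Simulated 5 % intra-day / 3 % inter-day CV design (20 days x 10
        replicates) is recovered within the sampling band."""
        spec = FixtureSpec(
            rng_seed=7, intra_day_cv=0.05, inter_day_cv=0.03, n_days=20, n_reps=10
        )
        df = simulate_peak_areas(spec, {"WVQQAK": "flaxseed"})
        est = repeatability_reproducibility(df)
        assert 4.0 <= est.intra_day_rsd <= 6.0
        assert 2.0 <= est.inter_day_rsd <= 4.5


class TestIsRecovery:
    def test_ninety_percent_recovery(self):
        mean, _ = is_recovery([450.0], [500.0])
        assert mean == pytest.approx(90.0)

    def test_identical_signals_full_recovery(self):
        mean, sd = is_recovery([500.0, 500.0], [500.0, 500.0])
        assert mean == pytest.approx(100.0)
        assert sd == pytest.approx(0.0)

    def test_sd_propagated_from_spiked_replicates(self):
        mean, sd = is_recovery([90.0, 100.0, 110.0], [100.0])
        assert mean == pytest.approx(100.0)
        assert sd == pytest.approx(10.0)

    def test_missing_reference_errors(self):
        with pytest.raises(ValueError):
            is_recovery([450.0], [])

    def test_zero_reference_mean_errors(self):
        with pytest.raises(ValueError, match="zero"):
            is_recovery([450.0], [0.0])


class TestLinearity:
    def test_exact_line_through_origin(self):
        fit = linearity([(1, 10), (2, 20), (4, 40)])
        assert fit.slope == pytest.approx(10.0)
        assert fit.intercept == pytest.approx(0.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_flat_response_zero_slope_zero_r2(self):
        fit = linearity([(1, 5.0), (2, 5.0), (4, 5.0)])
        assert fit.slope == 0.0
        assert fit.r2 == 0.0

    def test_too_few_levels_error(self):
        with pytest.raises(ValueError, match="3 distinct"):
            linearity([(1, 10), (2, 20), (2, 21)])

    def test_noiseless_simulated_series_is_perfect(self):
        df = simulate_dilution_series(true_slope=2500.0, levels=[1, 2, 4, 8, 16], noise_sd=0.0)
        fit = linearity(list(zip(df["dilution_level"], df["normalized_area"])))
        assert fit.r2 == pytest.approx(1.0)
        assert fit.slope == pytest.approx(2500.0)


PANEL = [
    MarkerCandidate(
        sequence="WVQQAK",
        species_tag="flaxseed",
        parent_accessions=frozenset(["Q8LPD3"]),
        uniqueness=Uniqueness("unique", frozenset(["flaxseed"])),
        role="quantifier",
    ),
    MarkerCandidate(
        sequence="DLPGQCGTQPSR",
        species_tag="flaxseed",
        parent_accessions=frozenset(["Q8LPD3"]),
        uniqueness=Uniqueness("unique", frozenset(["flaxseed"])),
        role="qualifier",
    ),
    MarkerCandidate(
        sequence="LVYIER",
        species_tag="sesame",
        parent_accessions=frozenset(["Q9XHP0"]),
        uniqueness=Uniqueness("unique", frozenset(["sesame"])),
        role="quantifier",
    ),
    MarkerCandidate(
        sequence="VHVVDR",
        species_tag="sesame",
        parent_accessions=frozenset(["Q9XHP0"]),
        uniqueness=Uniqueness("unique", frozenset(["sesame"])),
        role="qualifier",
    ),
]


class TestAuthenticate:
    def test_quantifier_plus_qualifier_is_positive(self):
        records = [
            rec(peptide="WVQQAK", raw=1_500_000.0),
            rec(peptide="DLPGQCGTQPSR", raw=400_000.0),
        ]
        call = authenticate(records, PANEL)
        assert call.species_called == {"flaxseed"}
        assert call.evidence["flaxseed"].status == "positive"
        assert call.evidence["sesame"].status == "negative"

    def test_blank_sample_all_negative(self):
        records = [
            rec(peptide=p, raw=0.0, record_class="blank", sample_id="blank1")
            for p in ("WVQQAK", "DLPGQCGTQPSR", "LVYIER", "VHVVDR")
        ]
        call = authenticate(records, PANEL)
        assert call.species_called == frozenset()
        assert all(ev.status == "negative" for ev in call.evidence.values())

    def test_quantifier_without_qualifier_is_inconclusive(self):
        records = [rec(peptide="WVQQAK", raw=1_500_000.0)]
        call = authenticate(records, PANEL)
        assert call.evidence["flaxseed"].status == "inconclusive"
        assert "flaxseed" not in call.species_called

    def test_missing_quantifier_in_panel_errors(self):
        qualifier_only = [c for c in PANEL if c.role == "qualifier"]
        with pytest.raises(ValueError, match="no quantifier"):
            authenticate([rec()], qualifier_only, species=["flaxseed"])

    def test_multiple_samples_rejected(self):
        records = [rec(sample_id="a"), rec(sample_id="b")]
        with pytest.raises(ValueError, match="one sample"):
            authenticate(records, PANEL)

    def test_authenticate_table_calls_each_sample(self):
        records = [
            rec(peptide="WVQQAK", raw=1_500_000.0, sample_id="s_flax"),
            rec(peptide="DLPGQCGTQPSR", raw=400_000.0, sample_id="s_flax"),
            rec(peptide="LVYIER", raw=11_000_000.0, sample_id="s_sesame"),
            rec(peptide="VHVVDR", raw=4_000_000.0, sample_id="s_sesame"),
        ]
        calls = authenticate_table(records_to_frame(records), PANEL)
        by_sample = {c.sample_id: c.species_called for c in calls}
        assert by_sample == {"s_flax": {"flaxseed"}, "s_sesame": {"sesame"}}


class TestTableIO:
    def test_read_peak_table_round_trip(self, tmp_path):
        df = records_to_frame([rec(raw=100.0, flour=0.5)])
        path = tmp_path / "areas.csv"
        df.drop(columns=["normalized_area"]).to_csv(path, index=False)
        loaded = read_peak_table(path)
        assert loaded["normalized_area"].iloc[0] == pytest.approx(200.0)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sample_id,peptide\nS1,WVQQAK\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_peak_table(path)

    def test_validation_report_covers_each_peptide(self):
        spec = FixtureSpec(rng_seed=3, n_days=3, n_reps=3)
        frames = [
            simulate_peak_areas(spec, {"WVQQAK": "flaxseed", "LVYIER": "sesame"}),
            simulate_dilution_series(1000.0, [1, 2, 4, 8], 0.0, peptide="WVQQAK"),
            records_to_frame(
                [
                    rec(peptide="GWGG", raw=450.0, record_class="is_spike", flour=1.0),
                    rec(peptide="GWGG", raw=500.0, record_class="is_reference", flour=1.0),
                ]
            ),
        ]
        import pandas as pd

        report = validation_report(pd.concat(frames, ignore_index=True))
        report = report.set_index("peptide")
        assert set(report.index) == {"WVQQAK", "LVYIER"}
        assert report.loc["WVQQAK", "linearity_r2"] == pytest.approx(1.0)
        assert np.isnan(report.loc["LVYIER", "linearity_r2"])
        assert report.loc["WVQQAK", "is_recovery_pct"] == pytest.approx(90.0)
        assert report.loc["WVQQAK", "repeatability_rsd_pct"] > 0
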