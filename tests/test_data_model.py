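import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fedsurv.data_model import (
    CentreDataset,
    compute_eqd2,
    default_model_config,
    derive_outcome,
    encode_covariates,
    impute_gtv_median_of_means,
    read_centre_csv,
    reference_covariates,
    write_centre_csv,
)
from fedsurv.errors import (
    DataConsistencyError,
    EncodingError,
    ImputationError,
    InvalidInputError,
)


class TestEqd2:
    @pytest.mark.parametrize(
        "dose,per_fraction,ab,expected",
        [
            (50.0, 2.0, 10.0, 50.0),  # 2 Gy/fraction identity
            (54.0, 1.8, 10.0, 54.0 * 11.8 / 12.0),  # = 53.1
            (0.0, 2.0, 10.0, 0.0),
        ],
    )
    def test_known_values(self, dose, per_fraction, ab, expected):
        assert compute_eqd2(dose, per_fraction, ab) == pytest.approx(expected)

    def test_printed_value(self):
        assert compute_eqd2(54.0, 1.8, 10.0) == pytest.approx(53.1, abs=0.05)

    @pytest.mark.parametrize("bad", [(-1.0, 2.0, 10.0), (50.0, 0.0, 10.0), (50.0, 2.0, -1.0)])
    def test_invalid_inputs(self, bad):
        with pytest.raises(InvalidInputError):
            compute_eqd2(*bad)

    @given(
        dose=st.floats(0.1, 80.0),
        scale=st.floats(0.1, 5.0),
        d=st.floats(0.5, 8.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_linear_in_total_dose(self, dose, scale, d):
        a = compute_eqd2(dose, d, 10.0)
        b = compute_eqd2(scale * dose, d, 10.0)
        assert b == pytest.approx(scale * a, rel=1e-12)

    @given(d1=st.floats(0.5, 8.0), d2=st.floats(0.5, 8.0))
    @settings(max_examples=50, derandomize=True)
    def test_monotone_in_fraction_dose(self, d1, d2):
        lo, hi = sorted([d1, d2])
        assert compute_eqd2(50.0, lo, 10.0) <= compute_eqd2(50.0, hi, 10.0)


class TestDeriveOutcome:
    def test_os_death_is_event(self, make_record):
        rec = make_record(death_months=30.0, followup_months=30.0)
        out = derive_outcome(rec, "OS")
        assert (out.time_months, out.event) == (30.0, 1)

    def test_os_censored_at_followup(self, make_record):
        out = derive_outcome(make_record(), "OS")
        assert (out.time_months, out.event) == (48.0, 0)

    def test_lrc_censored_at_distant_metastasis(self, make_record):
        rec = make_record(dm_months=12.0, death_months=40.0, followup_months=40.0)
        out = derive_outcome(rec, "LRC")
        assert (out.time_months, out.event) == (12.0, 0)

    def test_lrc_event_at_locoregional_failure(self, make_record):
        rec = make_record(lrf_months=9.0)
        out = derive_outcome(rec, "LRC")
        assert (out.time_months, out.event) == (9.0, 1)

    def test_lrc_earlier_censor_takes_precedence(self, make_record):
        # distant metastasis before the locoregional failure: the
        # patient leaves LRC observation at the metastasis
        rec = make_record(dm_months=5.0, lrf_months=8.0)
        out = derive_outcome(rec, "LRC")
        assert (out.time_months, out.event) == (5.0, 0)

    def test_lrc_censored_at_apr(self, make_record):
        rec = make_record(apr_nondisease_months=20.0)
        out = derive_outcome(rec, "LRC")
        assert (out.time_months, out.event) == (20.0, 0)

    def test_ffdm_censored_at_local_recurrence(self, make_record):
        rec = make_record(lrf_months=8.0)
        out = derive_outcome(rec, "FFDM")
        assert (out.time_months, out.event) == (8.0, 0)

    def test_ffdm_event(self, make_record):
        rec = make_record(dm_months=14.0)
        out = derive_outcome(rec, "FFDM")
        assert (out.time_months, out.event) == (14.0, 1)

    def test_event_after_followup_rejected(self, make_record):
        rec = make_record(death_months=60.0, followup_months=48.0)
        with pytest.raises(DataConsistencyError):
            derive_outcome(rec, "OS")

    def test_times_never_exceed_os_time(self, small_cohort):
        for node in small_cohort:
            for rec in node.records:
                t_os = derive_outcome(rec, "OS").time_months
                assert derive_outcome(rec, "LRC").time_months <= t_os + 1e-9
                assert derive_outcome(rec, "FFDM").time_months <= t_os + 1e-9


class TestEncoding:
    def test_reference_patient(self, make_record):
        rec = make_record(
            sex="male", t_stage="T1-2", n_stage="N0", histology="SCC",
            rt_technique="3D-CRT", chemo="none", age_years=35.0,
            gtv_cm3=1.1, total_dose_gy=40.0, dose_per_fraction_gy=2.0,
        )
        config = default_model_config("OS")
        x = encode_covariates(rec, config)
        expected = {
            "age_per_decade": 3.5,
            "log10_gtv": math.log10(1.1),
            "eqd2_per_10gy": 4.0,
        }
        for term, value in zip(config.covariates, x):
            assert value == pytest.approx(expected.get(term, 0.0))

    def test_full_example(self, make_record):
        rec = make_record(
            sex="female", t_stage="T3-4", n_stage="N+", age_years=62.0,
            gtv_cm3=41.5, total_dose_gy=53.2 * 12.0 / 11.8,
            dose_per_fraction_gy=1.8, histology="SCC",
            rt_technique="IMRT/VMAT", chemo="mitomycin",
        )
        config = default_model_config("OS")
        x = dict(zip(config.covariates, encode_covariates(rec, config)))
        assert x["sex_female"] == 1.0
        assert x["t_stage_t34"] == 1.0
        assert x["n_stage_npos"] == 1.0
        assert x["age_per_decade"] == pytest.approx(6.2)
        assert x["log10_gtv"] == pytest.approx(math.log10(41.5))
        assert x["eqd2_per_10gy"] == pytest.approx(5.32)
        assert x["histology_basaloid"] == 0.0
        assert x["rt_imrt_vmat"] == 1.0
        assert (x["chemo_mitomycin"], x["chemo_cisplatin"], x["chemo_other"]) == (1, 0, 0)

    def test_unknown_level_names_field(self, make_record):
        rec = make_record(sex="unknown")
        with pytest.raises(EncodingError, match="sex"):
            encode_covariates(rec, default_model_config("OS"))

    def test_missing_gtv_rejected(self, make_record):
        rec = make_record(gtv_cm3=None)
        with pytest.raises(EncodingError, match="gtv"):
            encode_covariates(rec, default_model_config("OS"))

    def test_categorical_encoding_injective(self, make_record):
        config = default_model_config("OS")
        base = encode_covariates(make_record(), config)
        for field, other in [
            ("sex", "female"), ("t_stage", "T3-4"), ("n_stage", "N+"),
            ("histology", "basaloid-SCC"), ("rt_technique", "3D-CRT"),
            ("chemo", "cisplatin"),
        ]:
            x = encode_covariates(make_record(**{field: other}), config)
            assert not np.array_equal(x, base)

    def test_ffdm_config_drops_rt_technique(self):
        config = default_model_config("FFDM")
        assert "rt_imrt_vmat" not in config.covariates
        assert config.exclude_m1

    def test_reference_vector_terms(self):
        config = default_model_config("OS")
        ref = dict(zip(config.covariates, reference_covariates(config)))
        assert ref["age_per_decade"] == 3.5
        assert ref["log10_gtv"] == 0.02572
        assert ref["eqd2_per_10gy"] == 4.0
        assert all(
            v == 0.0
            for k, v in ref.items()
            if k not in ("age_per_decade", "log10_gtv", "eqd2_per_10gy")
        )


class TestGtvImputation:
    def _node(self, make_record, cid, gtvs):
        records = tuple(
            make_record(patient_id=f"{cid}-{i}", gtv_cm3=g)
            for i, g in enumerate(gtvs)
        )
        return CentreDataset(centre_id=cid, records=records)

    def test_median_of_other_centre_means(self, make_record):
        nodes = [
            self._node(make_record, "A", [20.0, 20.0]),
            self._node(make_record, "B", [50.0]),
            self._node(make_record, "C", [120.0]),
            self._node(make_record, "D", [None, 33.0]),
        ]
        out = impute_gtv_median_of_means(nodes)
        # donor means are 20, 50, 120 and D's own observed value is excluded
        # from other centres' means; D's missing entry gets median 50
        assert out[3].records[0].gtv_cm3 == pytest.approx(50.0)
        assert out[3].records[1].gtv_cm3 == pytest.approx(33.0)

    def test_no_missing_is_identity(self, make_record):
        nodes = [self._node(make_record, "A", [20.0]), self._node(make_record, "B", [30.0])]
        out = impute_gtv_median_of_means(nodes)
        assert out == nodes

    def test_single_donor(self, make_record):
        nodes = [
            self._node(make_record, "A", [70.6]),
            self._node(make_record, "B", [None]),
        ]
        out = impute_gtv_median_of_means(nodes)
        assert out[1].records[0].gtv_cm3 == pytest.approx(70.6)

    def test_all_missing_raises(self, make_record):
        nodes = [self._node(make_record, "A", [None, None])]
        with pytest.raises(ImputationError):
            impute_gtv_median_of_means(nodes)

    def test_order_invariant_and_observed_unchanged(self, make_record):
        nodes = [
            self._node(make_record, "A", [20.0]),
            self._node(make_record, "B", [50.0, None]),
            self._node(make_record, "C", [120.0]),
        ]
        fwd = impute_gtv_median_of_means(nodes)
        rev = impute_gtv_median_of_means(nodes[::-1])
        filled_fwd = next(n for n in fwd if n.centre_id == "B")
        filled_rev = next(n for n in rev if n.centre_id == "B")
        assert filled_fwd.records[1].gtv_cm3 == filled_rev.records[1].gtv_cm3
        assert filled_fwd.records[0].gtv_cm3 == 50.0  # observed untouched


class TestCsvRoundtrip:
    def test_roundtrip_preserves_records(self, small_cohort, tmp_path):
        node = small_cohort[0]
        path = tmp_path / "centre.csv"
        write_centre_csv(node, path)
        back = read_centre_csv(path, node.centre_id, node.role)
        assert back.n == node.n
        for a, b in zip(node.records, back.records):
            assert a.patient_id == b.patient_id
            assert a.sex == b.sex
            assert a.gtv_cm3 == pytest.approx(b.gtv_cm3)
            assert a.followup_months == pytest.approx(b.followup_months)
            assert (a.death_months is None) == (b.death_months is None)

    def test_missing_fields_roundtrip(self, make_record, tmp_path):
        node = CentreDataset(
            "X", (make_record(gtv_cm3=None, death_months=None),)
        )
        path = tmp_path / "x.csv"
        write_centre_csv(node, path)
        back = read_centre_csv(path, "X")
        assert back.records[0].gtv_cm3 is None
        assert back.records[0].death_months is None
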