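"""Item coding, two-wave aggregation, severity count, covariate design."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wheezesev.items import (
    EHAAS_ITEMS,
    ISAAC_ITEMS,
    MISSING,
    ItemResponseTable,
    OrdinalItemSpec,
    discrete_severity_count,
    encode_covariates,
    load_coded_table,
    load_item_table,
    recode_ehaas_two_wave,
    write_item_table,
)

SPEC = {s.name: s for s in ISAAC_ITEMS}


def _table(codes: dict, covariates=None, n=None):
    n = n if n is not None else len(next(iter(codes.values())))
    return ItemResponseTable(
        ids=np.array([f"c{i}" for i in range(n)]),
        specs=SPEC,
        codes={k: np.asarray(v, dtype=np.int64) for k, v in codes.items()},
        covariates=covariates,
    )


class TestLoadItemTable:
    def test_labels_map_to_ascending_codes(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text(
            "child_id,episodes,sleep,speech,exercise\n"
            "a,Never,Never,Absent,Absent\n"
            "b,1 to 3,< 1 night/week,Present,Absent\n"
            "c,13+,1+ nights/week,Absent,Present\n"
        )
        t = load_item_table(p)
        assert t.codes["episodes"].tolist() == [0, 1, 3]
        assert t.codes["sleep"].tolist() == [0, 1, 2]
        assert t.codes["speech"].tolist() == [0, 1, 0]

    def test_missing_token_becomes_missing_marker(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("episodes,sleep,speech,exercise\nNA,Never,Absent,Absent\n")
        t = load_item_table(p)
        assert t.codes["episodes"][0] == MISSING
        assert t.n == 1

    def test_unknown_label_raises_with_location(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("episodes,sleep,speech,exercise\nWeekly,Never,Absent,Absent\n")
        with pytest.raises(ValueError, match="episodes"):
            load_item_table(p)

    def test_duplicate_child_id_rejected(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text(
            "child_id,episodes,sleep,speech,exercise\n"
            "a,Never,Never,Absent,Absent\na,Never,Never,Absent,Absent\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            load_item_table(p)

    def test_round_trip_preserves_category_counts(self, tmp_path, rng):
        # marginal counts shaped like the infant-cohort descriptive table
        n = 657
        codes = {
            "episodes": rng.permuted(np.repeat([0, 1, 2, 3, MISSING], [205, 328, 73, 28, 23])),
            "sleep": rng.permuted(np.repeat([0, 1, 2, MISSING], [455, 83, 96, 23])),
            "speech": rng.permuted(np.repeat([0, 1, MISSING], [517, 116, 24])),
            "exercise": rng.permuted(np.repeat([0, 1, MISSING], [576, 67, 14])),
        }
        t = _table(codes, n=n)
        write_item_table(t, tmp_path / "t.csv")
        back = load_coded_table(tmp_path / "t.csv")
        for v in codes:
            np.testing.assert_array_equal(back.category_counts(v), t.category_counts(v))
            assert (back.codes[v] == MISSING).sum() == (t.codes[v] == MISSING).sum()


class TestTwoWaveRecode:
    def _waves(self, ep, sl, sp, ex):
        specs = {s.name: s for s in ISAAC_ITEMS}

        def one(vals):
            return ItemResponseTable(
                ids=np.array([f"c{i}" for i in range(len(vals["episodes"]))]),
                specs=specs,
                codes={k: np.asarray(v, dtype=np.int64) for k, v in vals.items()},
            )

        w60 = one({"episodes": [p[0] for p in ep], "sleep": [p[0] for p in sl],
                   "speech": [p[0] for p in sp], "exercise": [p[0] for p in ex]})
        w72 = one({"episodes": [p[1] for p in ep], "sleep": [p[1] for p in sl],
                   "speech": [p[1] for p in sp], "exercise": [p[1] for p in ex]})
        return w60, w72

    def test_published_rule_examples(self):
        ep = [(0, 1), (2, 3), (0, 0), (1, 1)]
        sl = [(0, 0), (0, 1), (2, 2), (1, 0)]
        sp = [(0, 1), (0, 0), (1, 1), (1, 0)]
        ex = [(0, 0), (1, 1), (0, 1), (0, 0)]
        out = recode_ehaas_two_wave(*self._waves(ep, sl, sp, ex))
        assert out.codes["episodes"].tolist() == [0, 3, MISSING, 1]
        assert out.codes["sleep"].tolist() == [0, 1, 2, 1]
        assert out.codes["speech"].tolist() == [1, 0, 1, 1]
        assert out.specs["episodes"].n_categories == 4
        assert out.specs["sleep"].n_categories == 3

    def test_rule_set_is_total_on_covered_domain(self):
        # every wave-pair maps to exactly one level or is flagged missing
        ep_pairs = [(a, b) for a in range(4) for b in range(4)]
        sl_pairs = [(a, b) for a in range(3) for b in range(3)]
        m = max(len(ep_pairs), len(sl_pairs))
        ep = ep_pairs + [(0, 1)] * (m - len(ep_pairs))
        sl = sl_pairs + [(0, 0)] * (m - len(sl_pairs))
        sp = [(0, 0)] * m
        ex = [(0, 0)] * m
        out = recode_ehaas_two_wave(*self._waves(ep, sl, sp, ex))
        ep_out = out.codes["episodes"][: len(ep_pairs)]
        uncovered = {(0, 0), (1, 3), (3, 1)}
        for pair, code in zip(ep_pairs, ep_out):
            if pair in uncovered:
                assert code == MISSING
            else:
                assert 0 <= code <= 3
        assert (out.codes["sleep"][: len(sl_pairs)] != MISSING).all()
        assert out.meta["uncovered_pairs"]["episodes"] == 3

    def test_binary_items_present_if_endorsed_either_wave(self):
        ep = [(0, 1)] * 3
        sl = [(0, 0)] * 3
        sp = [(0, 0), (1, MISSING), (MISSING, 0)]
        ex = [(MISSING, 1), (0, 0), (1, 1)]
        out = recode_ehaas_two_wave(*self._waves(ep, sl, sp, ex))
        assert out.codes["speech"].tolist() == [0, 1, MISSING]
        assert out.codes["exercise"].tolist() == [1, 0, 1]


class TestDiscreteSeverity:
    @pytest.mark.parametrize(
        "row,expected",
        [((0, 0, 0, 0), 0), ((2, 1, 1, 1), 4), ((1, 0, 0, MISSING), MISSING),
         ((3, 2, 0, 0), 2)],
    )
    def test_endorsement_count_examples(self, row, expected):
        assert discrete_severity_count(np.array([row]))[0] == expected

    def test_count_observed_mode(self):
        out = discrete_severity_count(
            np.array([[1, 0, 0, MISSING]]), require_complete=False
        )
        assert out[0] == 1

    @given(
        st.lists(st.tuples(st.integers(0, 3), st.integers(0, 2),
                           st.integers(0, 1), st.integers(0, 1)),
                 min_size=1, max_size=20),
        st.integers(0, 3),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_additional_endorsement(self, rows, which):
        Y = np.array(rows, dtype=np.int64)
        base = discrete_severity_count(Y)
        bumped = Y.copy()
        bumped[:, which] = np.maximum(bumped[:, which], 1)
        assert (discrete_severity_count(bumped) >= base).all()


class TestDesignMatrix:
    def _cov_table(self, n=6):
        cov = pd.DataFrame({
            "maternal_asthma": [0, 1] * (n // 2),
            "prenatal_smoking": [0] * n,
            "single_mother": [0, 0, 1] * (n // 3),
            "medicaid": [1] * n,
            "cesarean": [0] * n,
            "female": [0, 1] * (n // 2),
            "race_black": [0] * n,
            "race_other": [0] * n,
            "race_nonwhite": [0, 1] * (n // 2),
        })
        codes = {s.name: np.zeros(n, dtype=np.int64) for s in ISAAC_ITEMS}
        return _table(codes, covariates=cov, n=n)

    def test_scheme_arities(self):
        t = self._cov_table()
        assert encode_covariates(t, "cohort1_full").q == 8
        assert encode_covariates(t, "cohort1_nosex").q == 7
        assert encode_covariates(t, "cohort3").q == 2
        assert encode_covariates(t, ["medicaid"]).q == 1

    def test_white_reference_rows_are_zero_dummies(self):
        t = self._cov_table()
        X = encode_covariates(t, "cohort1_full")
        i_b = X.names.index("race_black")
        i_o = X.names.index("race_other")
        assert (X.X[:, [i_b, i_o]] == 0).all()

    def test_missing_column_and_bad_level_raise(self):
        t = self._cov_table()
        with pytest.raises(KeyError):
            encode_covariates(t, ["not_a_column"])
        t.covariates["maternal_asthma"] = 2
        with pytest.raises(ValueError, match="non-binary"):
            encode_covariates(t, "cohort1_full")
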