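"""Table IO, mass-fraction normalization and evolved-strain measures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protalloc.expression import (
    AbundanceTable,
    ParseError,
    evolved_turnover_change,
    read_abundance_table,
    read_transcriptome_table,
    to_mass_fractions,
    transcriptome_fractions,
    utilized_transcriptome_change,
    write_abundance_table,
    write_transcriptome_table,
)
from protalloc.expression import TranscriptomeTable
from protalloc.solver import DemandProfile


def _write(tmp_path, text, name="table.tsv"):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestAbundanceIO:
    def test_basic_parse(self, tmp_path):
        path = _write(
            tmp_path,
            "protein\tmw\tglc\tgal\nA\t10.0\t2\t1\nB\t20.0\t1\t4\n",
        )
        rates = _write(tmp_path, "glc\tgal\n0.9\t0.5\n", "rates.tsv")
        table = read_abundance_table(path, rates)
        assert table.copies.shape == (2, 2)
        assert table.growth_rates["gal"] == pytest.approx(0.5)

    def test_duplicate_id_rejected(self, tmp_path):
        path = _write(tmp_path, "protein\tmw\tglc\nA\t10\t2\nA\t10\t3\n")
        with pytest.raises(ParseError, match="A"):
            read_abundance_table(path)

    def test_negative_value_line_number(self, tmp_path):
        path = _write(tmp_path, "protein\tmw\tglc\nA\t10\t2\nB\t10\t-3\n")
        with pytest.raises(ParseError, match="line 3"):
            read_abundance_table(path)

    def test_missing_mw_column(self, tmp_path):
        path = _write(tmp_path, "protein\tglc\nA\t2\n")
        with pytest.raises(ParseError, match="mw"):
            read_abundance_table(path)

    def test_round_trip(self, tmp_path):
        data = pd.DataFrame(
            {"mw": [10.0, 20.0], "glc": [2.0, 1.0], "gal": [0.0, 5.0]},
            index=pd.Index(["A", "B"], name="protein"),
        )
        table = AbundanceTable(data, pd.Series({"glc": 0.9, "gal": 0.4}))
        write_abundance_table(table, tmp_path / "a.tsv", tmp_path / "r.tsv")
        back = read_abundance_table(tmp_path / "a.tsv", tmp_path / "r.tsv")
        pd.testing.assert_frame_equal(back.data, table.data)
        write_abundance_table(back, tmp_path / "b.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()


class TestMassFractions:
    def test_symmetric_masses(self):
        data = pd.DataFrame(
            {"mw": [10.0, 20.0], "c": [2.0, 1.0]},
            index=pd.Index(["A", "B"], name="protein"),
        )
        frac = to_mass_fractions(AbundanceTable(data, pd.Series({"c": 1.0})))
        assert frac["c"].to_dict() == pytest.approx({"A": 0.5, "B": 0.5})

    def test_single_protein(self):
        data = pd.DataFrame(
            {"mw": [5.0], "c": [7.0]}, index=pd.Index(["A"], name="protein")
        )
        frac = to_mass_fractions(AbundanceTable(data, pd.Series({"c": 1.0})))
        assert frac.loc["A", "c"] == pytest.approx(1.0)

    def test_equal_weights(self):
        data = pd.DataFrame(
            {"mw": [10.0, 10.0], "c": [3.0, 1.0]},
            index=pd.Index(["A", "B"], name="protein"),
        )
        frac = to_mass_fractions(AbundanceTable(data, pd.Series({"c": 1.0})))
        assert frac["c"].to_dict() == pytest.approx({"A": 0.75, "B": 0.25})

    def test_zero_column_rejected(self):
        data = pd.DataFrame(
            {"mw": [10.0], "c": [0.0]}, index=pd.Index(["A"], name="protein")
        )
        with pytest.raises(ParseError):
            to_mass_fractions(AbundanceTable(data, pd.Series({"c": 1.0})))

    @settings(max_examples=25, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.floats(0.1, 1e4),  # mw
                st.floats(0.0, 1e6),  # copies
            ),
            min_size=1,
            max_size=8,
        ).filter(lambda rows: sum(mw * c for mw, c in rows) > 0)
    )
    def test_columns_sum_to_one(self, rows):
        data = pd.DataFrame(
            {
                "mw": [mw for mw, _ in rows],
                "c": [c for _, c in rows],
            },
            index=pd.Index([f"p{i}" for i in range(len(rows))], name="protein"),
        )
        frac = to_mass_fractions(AbundanceTable(data, pd.Series({"c": 1.0})))
        assert frac["c"].sum() == pytest.approx(1.0, abs=1e-9)


class TestTranscriptome:
    def test_equal_products(self):
        data = pd.DataFrame(
            {"length": [100.0, 200.0], "wt": [10.0, 5.0]},
            index=pd.Index(["g1", "g2"], name="gene"),
        )
        frac = transcriptome_fractions(TranscriptomeTable(data))
        assert frac["wt"].to_dict() == pytest.approx({"g1": 0.5, "g2": 0.5})

    def test_hand_computed(self):
        data = pd.DataFrame(
            {"length": [100.0, 200.0], "wt": [4.0, 1.0]},
            index=pd.Index(["g1", "g2"], name="gene"),
        )
        frac = transcriptome_fractions(TranscriptomeTable(data))
        assert frac["wt"].to_dict() == pytest.approx({"g1": 2 / 3, "g2": 1 / 3})

    def test_single_expressed_gene(self):
        data = pd.DataFrame(
            {"length": [100.0, 200.0], "wt": [4.0, 0.0]},
            index=pd.Index(["g1", "g2"], name="gene"),
        )
        frac = transcriptome_fractions(TranscriptomeTable(data))
        assert frac.loc["g1", "wt"] == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        data = pd.DataFrame(
            {"length": [100.0], "wt": [0.0]}, index=pd.Index(["g1"], name="gene")
        )
        with pytest.raises(ParseError):
            transcriptome_fractions(TranscriptomeTable(data))

    def test_io_round_trip(self, tmp_path):
        data = pd.DataFrame(
            {"length": [90.0, 150.0], "wt": [4.0, 1.0], "ev1": [2.0, 3.0]},
            index=pd.Index(["g1", "g2"], name="gene"),
        )
        table = TranscriptomeTable(data, pd.Series({"wt": 0.7, "ev1": 1.0}))
        write_transcriptome_table(table, tmp_path / "t.tsv", tmp_path / "r.tsv")
        back = read_transcriptome_table(tmp_path / "t.tsv", tmp_path / "r.tsv")
        pd.testing.assert_frame_equal(back.data, table.data)


class TestUtilizedTranscriptomeChange:
    wt = pd.Series({"g1": 0.5, "g2": 0.3, "g3": 0.2})

    def test_hand_case(self):
        ev = pd.Series({"g1": 0.7, "g2": 0.2, "g3": 0.1})
        deltas = utilized_transcriptome_change(self.wt, ev, [frozenset({"g1"})])
        assert deltas[0] == pytest.approx(0.2)

    def test_no_change(self):
        deltas = utilized_transcriptome_change(
            self.wt, self.wt.copy(), [frozenset({"g1", "g2"})]
        )
        assert np.allclose(deltas, 0.0)

    def test_boundary_all_mass_into_set(self):
        ev = pd.Series({"g1": 1.0, "g2": 0.0, "g3": 0.0})
        deltas = utilized_transcriptome_change(self.wt, ev, [frozenset({"g1"})])
        assert deltas[0] == pytest.approx(1 - 0.5)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3))
    def test_antisymmetry(self, vals):
        ev = pd.Series(dict(zip(["g1", "g2", "g3"], vals)))
        ev = ev / ev.sum()
        sets = [frozenset({"g1"}), frozenset({"g2", "g3"})]
        fwd = utilized_transcriptome_change(self.wt, ev, sets)
        rev = utilized_transcriptome_change(ev, self.wt, sets)
        assert np.allclose(fwd, -rev)


def test_evolved_turnover_change_null():
    """Identical strains at the same growth rate show zero turnover change."""
    fractions = pd.DataFrame(
        {"wt": {"A": 0.6, "B": 0.4}, "ev1": {"A": 0.6, "B": 0.4}}
    )
    profile = DemandProfile(0.5, {"A": 0.3, "B": 0.1}, 0.6)
    change, medians, _ = evolved_turnover_change(
        fractions, {"wt": profile, "ev1": profile}
    )
    assert np.allclose(change["ev1"].to_numpy(), 0.0)
    assert medians["ev1"] == pytest.approx(0.0)


def test_evolved_turnover_change_halved_expression():
    """Halving a demand-constant protein's expression raises its turnover."""
    fractions = pd.DataFrame(
        {"wt": {"A": 0.6, "B": 0.4}, "ev1": {"A": 0.3, "B": 0.7}}
    )
    profile = DemandProfile(0.5, {"A": 0.3, "B": 0.1}, 0.6)
    change, _, table = evolved_turnover_change(
        fractions, {"wt": profile, "ev1": profile}
    )
    # A's ratio doubles -> wt relative becomes 0.5, evolved 1.0
    assert table.relative.loc["A", "wt"] == pytest.approx(0.5)
    assert change.loc["A", "ev1"] == pytest.approx(0.5)
    assert change.loc["B", "ev1"] < 0
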