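"""Wiring-table parsing, the polarity/weight rules and synthetic connectomes."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nemasim.connectome import (
    UNKNOWN,
    CellClass,
    ChemicalConnection,
    ConnectomeFormatError,
    ElectricalConnection,
    Polarity,
    RowError,
    UnknownCellError,
    classify_polarity,
    connection_weight,
    generate_synthetic_connectome,
    read_connectome_table,
    subset_connectome,
    write_connectome_csv,
)

WORMWIRING_HEADER = "Origin,Target,Type,Number of Connections,Neurotransmitter\n"


class TestReader:
    def test_three_row_wormwiring_table(self):
        csv = (WORMWIRING_HEADER
               + "AVBL,DB1,GapJunction,2,\n"
               + "DB1,MDL08,Send,5,Acetylcholine\n"
               + "DD1,MDL08,Send,3,GABA\n")
        c = read_connectome_table(csv, "wormwiring")
        assert len(c.chemical) == 2
        assert len(c.electrical) == 1
        assert set(c.cells) == {"AVBL", "DB1", "MDL08", "DD1"}
        assert c.cells["MDL08"].cell_class is CellClass.MUSCLE
        (gap,) = c.electrical
        assert {gap.cell_a, gap.cell_b} == {"AVBL", "DB1"} and gap.n_contacts == 2
        by_pre = {x.pre: x for x in c.chemical}
        assert by_pre["DB1"].n_contacts == 5
        assert by_pre["DD1"].neurotransmitter == "GABA"

    def test_header_only_gives_empty_connectome(self):
        c = read_connectome_table(WORMWIRING_HEADER, "wormwiring")
        assert not c.cells and not c.chemical and not c.electrical

    def test_zero_contact_count_is_row_error_with_line(self):
        csv = WORMWIRING_HEADER + "A,B,Send,0,\n"
        with pytest.raises(RowError, match="line 2"):
            read_connectome_table(csv, "wormwiring")

    def test_non_integer_count_is_row_error(self):
        csv = WORMWIRING_HEADER + "A,B,Send,two,\n"
        with pytest.raises(RowError, match="not an integer"):
            read_connectome_table(csv, "wormwiring")

    def test_missing_column_names_the_column(self):
        with pytest.raises(ConnectomeFormatError, match="number of connections"):
            read_connectome_table("Origin,Target,Type\n", "wormwiring")

    def test_varshney_dialect_codes(self):
        csv = ("Neuron 1,Neuron 2,Type,Nbr\n"
               "AVAL,AVBL,S,3\n"       # chemical
               "AVBL,AVAL,R,3\n"       # mirrored duplicate, skipped
               "AVAL,AVBR,Sp,2\n"
               "AVAL,AVBL,EJ,4\n"      # gap junction
               "DB1,MDL08,NMJ,6\n")    # neuromuscular, chemical
        c = read_connectome_table(csv, "varshney")
        assert len(c.chemical) == 3
        assert len(c.electrical) == 1
        assert all(x.neurotransmitter == UNKNOWN for x in c.chemical)

    def test_blank_neurotransmitter_reads_as_unknown(self):
        c = read_connectome_table(WORMWIRING_HEADER + "A,B,Send,1,\n", "wormwiring")
        assert c.chemical[0].neurotransmitter == UNKNOWN

    def test_self_connection_dropped_with_warning(self, caplog):
        csv = WORMWIRING_HEADER + "A,A,Send,2,\nA,B,Send,1,\n"
        with caplog.at_level("WARNING"):
            c = read_connectome_table(csv, "wormwiring")
        assert len(c.chemical) == 1
        assert "self-connection" in caplog.text

    def test_duplicate_ordered_pairs_summed(self):
        csv = (WORMWIRING_HEADER + "A,B,Send,2,GABA\n" + "A,B,Send,3,GABA\n"
               + "A,B,GapJunction,1,\n" + "B,A,GapJunction,2,\n")
        c = read_connectome_table(csv, "wormwiring")
        assert len(c.chemical) == 1 and c.chemical[0].n_contacts == 5
        assert len(c.electrical) == 1 and c.electrical[0].n_contacts == 3

    def test_round_trip_through_csv(self):
        src = generate_synthetic_connectome(15, 4, chem_density=0.2,
                                            gap_density=0.1, seed=7)
        connected = sorted(
            {x.pre for x in src.chemical} | {x.post for x in src.chemical}
            | {x.cell_a for x in src.electrical} | {x.cell_b for x in src.electrical})
        src = subset_connectome(src, connected)
        buf = io.StringIO()
        write_connectome_csv(src, buf)
        buf.seek(0)
        annotations = {n: (ci.cell_class, ci.neurotransmitter)
                       for n, ci in src.cells.items()}
        back = read_connectome_table(buf, "wormwiring", cell_annotations=annotations)
        assert back.cells == src.cells
        assert sorted(back.chemical, key=lambda x: (x.pre, x.post)) == \
               sorted(src.chemical, key=lambda x: (x.pre, x.post))
        assert sorted(back.electrical, key=lambda x: (x.cell_a, x.cell_b)) == \
               sorted(src.electrical, key=lambda x: (x.cell_a, x.cell_b))


class TestPolarityRule:
    @pytest.mark.parametrize("nt,expected", [
        ("GABA", Polarity.INHIBITORY),
        ("gaba", Polarity.INHIBITORY),
        (" Gaba ", Polarity.INHIBITORY),
        ("Acetylcholine", Polarity.EXCITATORY),
        ("Glutamate", Polarity.EXCITATORY),
        (UNKNOWN, Polarity.EXCITATORY),
        ("", Polarity.EXCITATORY),
    ])
    def test_gaba_and_only_gaba_inhibits(self, nt, expected):
        assert classify_polarity(nt) is expected

    @given(st.text(min_size=0, max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_partition_into_exactly_two_classes(self, nt):
        pol = classify_polarity(nt)
        assert pol in (Polarity.EXCITATORY, Polarity.INHIBITORY)
        assert (pol is Polarity.INHIBITORY) == (nt.strip().upper() == "GABA")


class TestWeightRule:
    def test_figure_worked_examples(self):
        assert connection_weight(13, 0.01) == pytest.approx(0.13)
        assert connection_weight(1, 0.01) == pytest.approx(0.01)
        assert connection_weight(7, 0.0) == 0.0

    @pytest.mark.parametrize("n", [1, 2, 5, 13, 40])
    @pytest.mark.parametrize("base", [0.0, 0.005, 0.01, 0.2])
    def test_linear_in_both_arguments(self, n, base):
        assert connection_weight(n, base) == pytest.approx(n * base)
        assert connection_weight(n, 2 * base) == pytest.approx(2 * connection_weight(n, base))

    def test_negative_baseline_rejected(self):
        with pytest.raises(ValueError):
            connection_weight(3, -0.01)


class TestSubset:
    def test_both_endpoints_of_one_connection(self):
        c = read_connectome_table(
            WORMWIRING_HEADER + "A,B,Send,2,\nB,C,Send,1,\n", "wormwiring")
        sub = subset_connectome(c, ["A", "B"])
        assert set(sub.cells) == {"A", "B"}
        assert len(sub.chemical) == 1

    def test_single_cell_keeps_no_edges(self):
        c = read_connectome_table(WORMWIRING_HEADER + "A,B,Send,2,\n", "wormwiring")
        sub = subset_connectome(c, ["A"])
        assert set(sub.cells) == {"A"} and not sub.chemical

    def test_unknown_names_listed_in_error(self):
        c = read_connectome_table(WORMWIRING_HEADER + "A,B,Send,2,\n", "wormwiring")
        with pytest.raises(UnknownCellError, match="NOPE1, NOPE2"):
            subset_connectome(c, ["A", "NOPE2", "NOPE1"])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_edge_filter(self, seed):
        c = generate_synthetic_connectome(50, 0, chem_density=0.08,
                                          gap_density=0.04, seed=seed)
        rng = np.random.default_rng(seed)
        names = sorted(rng.choice(sorted(c.cells), size=10, replace=False).tolist())
        sub = subset_connectome(c, names)
        wanted = set(names)
        expect_chem = [x for x in c.chemical if x.pre in wanted and x.post in wanted]
        expect_elec = [x for x in c.electrical
                       if x.cell_a in wanted and x.cell_b in wanted]
        assert sorted(sub.chemical, key=lambda x: (x.pre, x.post)) == \
               sorted(expect_chem, key=lambda x: (x.pre, x.post))
        assert len(sub.electrical) == len(expect_elec)


class TestSyntheticGenerator:
    def test_same_seed_identical(self):
        a = generate_synthetic_connectome(30, 8, seed=42)
        b = generate_synthetic_connectome(30, 8, seed=42)
        assert a.cells == b.cells
        assert a.chemical == b.chemical
        assert a.electrical == b.electrical

    def test_zero_density_zero_edges(self):
        c = generate_synthetic_connectome(20, 5, chem_density=0.0,
                                          gap_density=0.0, seed=0)
        assert not c.chemical and not c.electrical

    def test_edge_count_within_three_sigma_of_binomial(self):
        n, p = 50, 0.1
        c = generate_synthetic_connectome(n, 0, chem_density=p, gap_density=0.0,
                                          seed=1)
        trials = n * (n - 1)
        mean, sigma = trials * p, np.sqrt(trials * p * (1 - p))
        assert abs(len(c.chemical) - mean) < 3 * sigma

    def test_muscles_never_presynaptic(self):
        c = generate_synthetic_connectome(20, 10, chem_density=0.3, seed=3)
        muscle_names = {n for n, ci in c.cells.items()
                        if ci.cell_class is CellClass.MUSCLE}
        assert not any(x.pre in muscle_names for x in c.chemical)

    def test_gaba_fraction_applied(self):
        c = generate_synthetic_connectome(40, 0, gaba_fraction=0.25, seed=5)
        n_gaba = sum(ci.neurotransmitter == "GABA" for ci in c.cells.values())
        assert n_gaba == 10

    def test_contact_counts_at_least_one(self):
        c = generate_synthetic_connectome(30, 5, chem_density=0.2,
                                          gap_density=0.1, seed=9)
        assert all(x.n_contacts >= 1 for x in c.chemical + c.electrical)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            generate_synthetic_connectome(0, 0)
        with pytest.raises(ValueError):
            generate_synthetic_connectome(5, 0, chem_density=1.5)


class TestInvariants:
    def test_connection_validation_catches_dangling_edges(self):
        from nemasim.connectome import Connectome, CellIdentity

        c = Connectome(cells={"A": CellIdentity("A")},
                       chemical=[ChemicalConnection("A", "GHOST", 1)])
        with pytest.raises(UnknownCellError):
            c.validate()

    def test_contact_count_invariants_enforced(self):
        with pytest.raises(ValueError):
            ChemicalConnection("A", "B", 0)
        with pytest.raises(ValueError):
            ElectricalConnection("A", "B", -1)

    def test_electrical_pair_is_unordered(self):
        assert ElectricalConnection("B", "A", 2) == ElectricalConnection("A", "B", 2)
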