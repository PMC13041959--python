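"""PDB, crosslink-table, chain-map and restraint I/O."""

import numpy as np
import pytest

from xlstruct import (ChainMap, CSMRecord, UniqueXL, map_crosslink, read_pdb,
                      write_pdb)
from xlstruct.xl_io import (CANONICAL_DIALECT, Restraint, RestraintSet,
                            TableDialect, format_restraints, read_chain_map,
                            read_crosslink_table, write_chain_map,
                            write_crosslink_table, write_restraints)


class TestReadPdb:
    def test_minimal_two_residue_chain(self, minimal_pdb):
        m = read_pdb(minimal_pdb)
        assert m.chains == ["A"]
        assert m.residues("A") == [1, 2]
        assert m.chain_sequences == {"A": "AK"}
        np.testing.assert_allclose(m.ca("A", 2), [3.988, 2.839, 0.0])

    def test_trimer_has_three_chain_sequences(self, trimer_pdb):
        m = read_pdb(trimer_pdb)
        assert sorted(m.chain_sequences) == ["A", "B", "C"]

    def test_altloc_keeps_single_record(self, altloc_pdb):
        m = read_pdb(altloc_pdb)
        # two altlocs in the file collapse to one alpha-carbon for residue 1
        assert m.residues("A") == [1, 2]
        np.testing.assert_allclose(m.ca("A", 1), [0.0, 0.0, 0.0])

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_pdb(tmp_path / "absent.pdb")

    def test_no_alpha_carbons_rejected(self, tmp_path):
        p = tmp_path / "noca.pdb"
        p.write_text("ATOM      1  N   ALA A   1       0.000   0.000   0.000"
                     "  1.00  0.00           N\nEND\n")
        with pytest.raises(ValueError):
            read_pdb(p)

    def test_round_trip_preserves_geometry(self, trimer, tmp_path):
        p = tmp_path / "rt.pdb"
        write_pdb(trimer, p)
        back = read_pdb(p)
        assert back.chains == trimer.chains
        for c in trimer.chains:
            assert back.residues(c) == trimer.residues(c)
            # PDB stores 3 decimals
            np.testing.assert_allclose(back.ca_coords(c), trimer.ca_coords(c),
                                       atol=5e-4)


class TestCrosslinkTable:
    def _write(self, tmp_path, rows, header="csm_id\treplicate\tprotein_a\t"
               "position_a\tprotein_b\tposition_b\tscore\tpasses_fdr"):
        p = tmp_path / "xl.tsv"
        p.write_text(header + "\n" + "\n".join(rows) + "\n")
        return p

    def test_five_row_toy_table(self, tmp_path):
        rows = [f"c{i}\trep1\tP1\t{10+i}\tP2\t5\t50.0\tTrue" for i in range(5)]
        recs = read_crosslink_table(self._write(tmp_path, rows))
        assert len(recs) == 5
        assert recs[0].protein_a == "P1" and recs[0].position_b == 5

    def test_malformed_position_names_row(self, tmp_path):
        rows = ["c1\trep1\tP1\t10\tP2\t5\t\tTrue",
                "c2\trep1\tP1\tBAD\tP2\t5\t\tTrue"]
        with pytest.raises(ValueError, match="row 2"):
            read_crosslink_table(self._write(tmp_path, rows))

    def test_unknown_columns_for_dialect(self, tmp_path):
        p = tmp_path / "other.csv"
        p.write_text("ProtA,PosA\nP1,3\n")
        with pytest.raises(ValueError, match="expects columns"):
            read_crosslink_table(p, CANONICAL_DIALECT)

    def test_custom_dialect(self, tmp_path):
        p = tmp_path / "vendor.csv"
        p.write_text("Accession A,Site A,Accession B,Site B\nP1,12,P2,9\n")
        dia = TableDialect(name="vendor", protein_a="Accession A",
                           position_a="Site A", protein_b="Accession B",
                           position_b="Site B", delimiter=",")
        recs = read_crosslink_table(p, dia)
        assert [(recs[0].protein_a, recs[0].position_a)] == [("P1", 12)]
        assert recs[0].passes_fdr  # absent column defaults to passing

    def test_failing_fdr_rows_retained_but_flagged(self, tmp_path):
        rows = ["c1\trep1\tP1\t10\tP2\t5\t\tTrue",
                "c2\trep1\tP1\t10\tP2\t5\t\tFalse"]
        recs = read_crosslink_table(self._write(tmp_path, rows))
        assert [r.passes_fdr for r in recs] == [True, False]

    def test_write_read_round_trip(self, tmp_path, planted):
        csms, _ = planted
        p = tmp_path / "rt.tsv"
        write_crosslink_table(csms, p)
        back = read_crosslink_table(p)
        assert [(r.protein_a, r.position_a, r.protein_b, r.position_b)
                for r in back] == \
               [(r.protein_a, r.position_a, r.protein_b, r.position_b)
                for r in csms]


class TestMapCrosslink:
    def test_mapped_pair(self, trimer):
        cmap = ChainMap({"P1": [("A", 0)]})
        xl = UniqueXL(("P1", 7), ("P1", 21))
        m = map_crosslink(xl, cmap, trimer)
        assert m.mapped and m.candidates == ((("A", 7), ("A", 21)),)
        assert not m.non_lysine

    def test_accession_absent_from_chain_map(self, trimer):
        xl = UniqueXL(("P1", 7), ("QX", 7))
        m = map_crosslink(xl, ChainMap({"P1": [("A", 0)]}), trimer)
        assert not m.mapped and m.reason == "no-chain"

    def test_position_beyond_chain_length(self, trimer):
        xl = UniqueXL(("P1", 7), ("P1", 9999))
        m = map_crosslink(xl, ChainMap({"P1": [("A", 0)]}), trimer)
        assert not m.mapped and m.reason == "no-residue"

    def test_non_lysine_warns_but_keeps(self, trimer):
        xl = UniqueXL(("P1", 7), ("P1", 8))  # residue 8 is ALA
        with pytest.warns(UserWarning, match="non-lysine"):
            m = map_crosslink(xl, ChainMap({"P1": [("A", 0)]}), trimer)
        assert m.mapped and m.non_lysine

    def test_homo_oligomer_yields_all_candidates(self, trimer):
        cmap = ChainMap({"P1": [("A", 0), ("B", 0)]})
        xl = UniqueXL(("P1", 7), ("P1", 14))
        m = map_crosslink(xl, cmap, trimer)
        assert len(m.candidates) == 4  # 2 chains x 2 chains

    def test_total_over_planted_dataset(self, mapped, planted):
        _, truth = planted
        assert len(mapped) == len(truth)
        assert all(m.mapped or m.reason in ("no-chain", "no-residue")
                   for m in mapped)

    def test_offset_bridges_numbering(self, trimer):
        # sequence position 2 + offset 5 -> model residue 7 (a lysine)
        cmap = ChainMap({"P1": [("A", 5)]})
        m = map_crosslink(UniqueXL(("P1", 2), ("P1", 9)), cmap, trimer)
        assert m.mapped and m.candidates[0] == (("A", 7), ("A", 14))


class TestRestraints:
    def _rs(self, order=(0, 1, 2)):
        rows = [Restraint("A", 10, "CA", "B", 20, "CA", 18.5, 18.5, 18.5),
                Restraint("A", 5, "CA", "C", 8, "CA", 18.5, 18.5, 18.5),
                Restraint("B", 2, "CA", "A", 30, "CA", 18.5, 18.5, 18.5)]
        return RestraintSet([rows[i] for i in order])

    def test_assign_line_band_is_zero_to_37(self):
        text = format_restraints(RestraintSet(
            [Restraint("A", 10, "CA", "B", 20, "CA", 18.5, 18.5, 18.5)]))
        assert text == ("assign (segid A and resid 10 and name CA) "
                        "(segid B and resid 20 and name CA) 18.5 18.5 18.5\n")
        target, lo, hi = 18.5, 18.5, 18.5
        assert (target - lo, target + hi) == (0.0, 37.0)

    def test_refinement_list_layout(self):
        rs = RestraintSet([Restraint("B", 20, "CA", "A", 10, "CA", 18.5, 18.5, 18.5)],
                          dialect="refinement-list")
        assert format_restraints(rs) == "10 A 20 B 18.5\n"  # canonicalized order

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            format_restraints(RestraintSet([]))

    @pytest.mark.parametrize("order", [(0, 1, 2), (2, 0, 1), (1, 2, 0)])
    def test_byte_stable_under_permutation(self, order):
        assert format_restraints(self._rs(order)) == format_restraints(self._rs())

    def test_unresolvable_selector(self, trimer, tmp_path):
        rs = RestraintSet([Restraint("Z", 1, "CA", "A", 7, "CA", 18.5, 18.5, 18.5)])
        with pytest.raises(ValueError, match="selector"):
            write_restraints(rs, tmp_path / "r.tbl", model=trimer)


def test_chain_map_yaml_round_trip(tmp_path):
    cmap = ChainMap({"P1": [("A", 0)], "P2": [("B", 0), ("C", -3)]})
    p = tmp_path / "cm.yaml"
    write_chain_map(cmap, p)
    assert read_chain_map(p).entries == cmap.entries
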