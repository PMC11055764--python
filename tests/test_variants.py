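"""Stop-codon context extraction, classification and insert design."""

import numpy as np
import pytest

from trquant.errors import BoundsError, ContextError
from trquant.variants import (
    SCCRecord,
    VariantTable,
    class_counts,
    classify_stop,
    design_reporter_insert,
    extract_scc,
    read_variant_table,
    reverse_complement,
    write_variant_table,
)

BASES = "ACGT"


class TestExtractScc:
    def test_toy_sequence(self):
        # 9 codons of padding, then TGA at codon 10 flanked by known bases
        cds = "A" * 27 + "TGA" + "C" * 30
        rec = extract_scc(cds, 10, "toy")
        assert rec.upstream == "A" * 10
        assert rec.stop_codon == "TGA"
        assert rec.downstream == "C" * 10
        assert rec.plus_four == "C"
        assert len(rec.insert_core) == 23

    def test_non_stop_codon_rejected(self):
        cds = "A" * 27 + "AAA" + "C" * 30
        with pytest.raises(ContextError):
            extract_scc(cds, 10)

    def test_window_out_of_bounds(self):
        with pytest.raises(BoundsError):
            extract_scc("ATG" + "TGA" + "C" * 30, 2)  # only 3 nt upstream
        with pytest.raises(BoundsError):
            extract_scc("A" * 27 + "TGA" + "CC", 10)  # short downstream

    @pytest.mark.parametrize("stop", ["TAA", "TAG", "TGA"])
    def test_round_trip_against_slicing_oracle(self, stop, rng):
        # plant a stop in random flanks; the record must equal direct slices
        for _ in range(100):
            up = "".join(rng.choice(list(BASES), 30))
            down = "".join(rng.choice(list(BASES), 30))
            cds = up + stop + down
            rec = extract_scc(cds, 11)
            assert rec.upstream == cds[20:30]
            assert rec.stop_codon == stop
            assert rec.downstream == cds[33:43]


class TestClassifyStop:
    @pytest.mark.parametrize(
        "codon", ["TGA", "tga", "UGA", "uga", "UgA"]
    )
    def test_alphabet_and_case_invariance(self, codon):
        rec = SCCRecord(variant_name="x", stop_codon=codon)
        assert classify_stop(rec) == "UGA"

    def test_packaged_contexts(self, packaged_table):
        r198 = packaged_table["R198X"]
        assert classify_stop(r198) == "UGA" and r198.plus_four_rna == "C"
        y141 = packaged_table["Y141X"]
        assert classify_stop(y141) == "UAG" and y141.plus_four_rna == "U"
        s68 = packaged_table["S68X"]
        assert classify_stop(s68) == "UGA" and s68.plus_four_rna == "G"


class TestClassCounts:
    def test_packaged_partition(self, packaged_table):
        assert class_counts(packaged_table) == {"UAA": 2, "UAG": 6, "UGA": 6}

    def test_empty_table(self):
        assert class_counts(VariantTable([])) == {"UAA": 0, "UAG": 0, "UGA": 0}

    def test_counts_conserve_record_count(self, packaged_table):
        assert sum(class_counts(packaged_table).values()) == len(packaged_table)


class TestPackagedTable:
    def test_fourteen_unique_variants(self, packaged_table):
        assert len(packaged_table) == 14
        names = [r.variant_name for r in packaged_table]
        assert len(set(names)) == 14

    def test_undetermined_class_is_flagged(self, packaged_table):
        rec = packaged_table["R294X"]
        assert rec.flags["stop_class_provenance"] == "inferred-by-count"

    def test_csv_round_trip(self, packaged_table, tmp_path):
        path = tmp_path / "variants.csv"
        write_variant_table(packaged_table, path)
        reread = read_variant_table(path)
        assert [r.variant_name for r in reread] == [
            r.variant_name for r in packaged_table
        ]
        assert class_counts(reread) == class_counts(packaged_table)


class TestReporterInsert:
    @pytest.fixture
    def scc(self, rng):
        cds = "".join(rng.choice(list(BASES), 30)) + "TAG" + "".join(
            rng.choice(list(BASES), 30)
        )
        return extract_scc(cds, 11, "toy")

    def test_core_identity(self, scc):
        pair = design_reporter_insert(scc)
        assert scc.insert_core in pair.sense
        assert pair.sense == "CCGGA" + scc.insert_core + "G"

    def test_duplex_complementarity(self, scc):
        pair = design_reporter_insert(scc)
        assert reverse_complement(pair.duplex_antisense) == pair.duplex_sense

    @pytest.mark.parametrize("n", list("ACGT"))
    def test_ligation_reconstitutes_both_enzyme_sites(self, scc, n):
        # oracle: BspEI recognizes TCCGGA (cut T^CCGGA), BstEII GGTNACC
        # (cut G^GTNACC); ligating the insert into a cut vector must
        # rebuild both sites around the core.
        pair = design_reporter_insert(scc, bstEII_n=n)
        vector_up_top = "GGT"  # ends with the T of the BspEI site
        vector_down_top = "GT" + n + "ACC"
        ligated_top = vector_up_top + pair.sense + vector_down_top
        assert "TCCGGA" in ligated_top
        assert "GGT" + n + "ACC" in ligated_top
        # overhang geometry: 4-nt BspEI overhang, 5-nt BstEII overhang
        assert pair.sense[: pair.sense_overhang_len] == "CCGG"
        assert pair.antisense[: pair.antisense_overhang_len] == (
            "GT" + reverse_complement(n) + "AC"
        )
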