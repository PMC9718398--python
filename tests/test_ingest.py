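import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proximap.ingest import (
    DEFAULT_CONTAMINANTS,
    ContaminantList,
    PreyRecord,
    PreyTableWarning,
    build_interactome,
    filter_preys,
    normalize_symbol,
    read_prey_table,
    write_prey_table,
)
from proximap.synthetic import GeneratorConfig, generate_bioid

from conftest import make_record


class TestReadPreyTable:
    def test_well_formed_rows_become_records(self, tmp_path):
        records = [
            make_record(prey="CHEK1"),
            make_record(prey="PLK1", avg_spec=3.5),
            make_record(prey="POLA1", bait="XRCC3"),
        ]
        path = tmp_path / "t.tsv"
        write_prey_table(records, path)
        assert read_prey_table(path) == records

    def test_out_of_range_probability_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "t.tsv"
        write_prey_table([make_record(), make_record(prey="PLK1")], path)
        text = path.read_text().replace("0.99", "1.2", 1)
        path.write_text(text)
        with pytest.warns(PreyTableWarning, match="line 2"):
            records = read_prey_table(path)
        assert [r.prey for r in records] == ["PLK1"]

    def test_non_numeric_avg_spec_is_row_level_error(self, tmp_path):
        path = tmp_path / "t.tsv"
        write_prey_table([make_record()], path)
        path.write_text(path.read_text().replace("5.0", "many", 1))
        with pytest.warns(PreyTableWarning, match="line 2"):
            assert read_prey_table(path) == []

    def test_missing_column_is_hard_error_naming_it(self, tmp_path):
        path = tmp_path / "t.tsv"
        write_prey_table([make_record()], path)
        lines = path.read_text().splitlines()
        cut = ["\t".join(l.split("\t")[1:]) for l in lines]  # drop Bait column
        path.write_text("\n".join(cut))
        with pytest.raises(ValueError, match="Bait"):
            read_prey_table(path)

    def test_symbols_uppercased_and_stripped(self, tmp_path):
        path = tmp_path / "t.tsv"
        write_prey_table([make_record()], path)
        path.write_text(path.read_text().replace("CHEK1", "  chek1 "))
        (rec,) = read_prey_table(path)
        assert rec.prey == "CHEK1"

    def test_synthetic_table_round_trips_field_for_field(self, tmp_path):
        config = GeneratorConfig(
            seed=5, n_all_common=10, n_bcdx2_exclusive=3, n_cx3_exclusive=2,
            n_bait_specific=2, n_background=5, n_hu_modulated=2,
        )
        records, _ = generate_bioid(config)
        path = tmp_path / "synth.tsv"
        write_prey_table(records, path)
        assert read_prey_table(path) == records


class TestNormalizeSymbol:
    @pytest.mark.parametrize(
        "raw,expected",
        [(" brca2 ", "BRCA2"), ("RAD51C-201", "RAD51C"), ("XRCC3", "XRCC3")],
    )
    def test_namespace_mapping(self, raw, expected):
        assert normalize_symbol(raw, isoform_delim="-") == expected


class TestFilterPreys:
    def test_boundary_record_kept_inclusively(self):
        rec = make_record(iprophet_prob=0.9, unique_peptides=1)
        kept, _ = filter_preys([rec])
        assert kept == [rec]

    @pytest.mark.parametrize("contaminant", ["PRKDC", "AHNAK", "KRT18", "RPL11"])
    def test_contaminants_removed(self, contaminant):
        kept, report = filter_preys([make_record(prey=contaminant)])
        assert kept == [] and report.removed_contaminant == 1

    def test_planted_pass_fail_labels_recovered(self):
        import numpy as np

        rng = np.random.default_rng(3)
        records, should_pass = [], []
        for i in range(100):
            passing = bool(rng.random() < 0.5)
            if passing:
                rec = make_record(
                    prey=f"OK{i}", iprophet_prob=float(rng.uniform(0.9, 1.0)),
                    unique_peptides=int(rng.integers(1, 5)),
                )
            else:
                mode = rng.integers(3)
                rec = make_record(
                    prey="PRKDC" if mode == 0 else f"BAD{i}",
                    iprophet_prob=float(rng.uniform(0, 0.89)) if mode == 1 else 0.99,
                    unique_peptides=0 if mode == 2 else 2,
                )
            records.append(rec)
            if passing:
                should_pass.append(rec)
        kept, report = filter_preys(records)
        assert kept == should_pass
        assert report.n_removed == 100 - len(should_pass)

    def test_filtering_is_idempotent(self):
        records = [make_record(prey=f"G{i}", iprophet_prob=0.85 + i * 0.01)
                   for i in range(10)]
        once, _ = filter_preys(records)
        twice, _ = filter_preys(once)
        assert once == twice

    @settings(derandomize=True, max_examples=30)
    @given(
        probs=st.lists(st.floats(0, 1), min_size=1, max_size=20),
        lo=st.floats(0, 1),
        hi=st.floats(0, 1),
    )
    def test_raising_min_prob_never_adds_preys(self, probs, lo, hi):
        lo, hi = min(lo, hi), max(lo, hi)
        records = [make_record(prey=f"G{i}", iprophet_prob=p)
                   for i, p in enumerate(probs)]
        strict, _ = filter_preys(records, min_prob=hi)
        lax, _ = filter_preys(records, min_prob=lo)
        assert set(r.prey for r in strict) <= set(r.prey for r in lax)

    def test_contaminant_and_confidence_filters_commute(self):
        records = [
            make_record(prey="PRKDC"),
            make_record(prey="GOOD1"),
            make_record(prey="LOWP", iprophet_prob=0.5),
            make_record(prey="KRT7", iprophet_prob=0.5),
        ]
        nothing = ContaminantList(symbols=frozenset({"__NONE__"}))
        conf_first, _ = filter_preys(
            filter_preys(records, contaminants=nothing)[0],
            min_prob=0.0, min_unique=0,
        )
        cont_first, _ = filter_preys(
            filter_preys(records, min_prob=0.0, min_unique=0)[0],
        )
        assert conf_first == cont_first

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            filter_preys([], min_prob=1.5)
        with pytest.raises(ValueError):
            filter_preys([], min_unique=-1)


class TestContaminantList:
    def test_from_file_supports_prefix_entries(self, tmp_path):
        path = tmp_path / "cont.txt"
        path.write_text("# comment\nAHNAK\nKRT*\n")
        cl = ContaminantList.from_file(path)
        assert "AHNAK" in cl and "KRT14" in cl and "BRCA2" not in cl


class TestPreyRecordInvariants:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("iprophet_prob", 1.2),
            ("iprophet_prob", -0.1),
            ("avg_spec", -1.0),
            ("protein_length_aa", 0),
            ("unique_peptides", -1),
            ("condition", "mock"),
        ],
    )
    def test_invalid_fields_raise(self, field, value):
        with pytest.raises(ValueError):
            make_record(**{field: value})


class TestBuildInteractome:
    def test_partition_by_bait(self):
        records = [
            make_record(bait="RAD51B", prey="A"),
            make_record(bait="RAD51B", prey="B"),
            make_record(bait="XRCC3", prey="C"),
        ]
        inter = build_interactome(records, "RAD51B", "untreated")
        assert set(inter.preys) == {"A", "B"}

    def test_absent_bait_errors_naming_available(self):
        records = [make_record(bait="RAD51B")]
        with pytest.raises(ValueError, match="RAD51B"):
            build_interactome(records, "XRCC2", "untreated")

    def test_avg_spec_copied_unchanged(self):
        rec = make_record(avg_spec=7.5)
        inter = build_interactome([rec], rec.bait, rec.condition)
        assert inter.preys[rec.prey] == 7.5
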