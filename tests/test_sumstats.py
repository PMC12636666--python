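"""Summary-statistics ingestion, QC cascade and panel harmonization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ctfm.sumstats import (
    ReferencePanel,
    align_to_reference,
    apply_qc_filters,
    effective_sample_size,
    read_sumstats,
)
from conftest import make_record


def _write(tmp_path, df, name="ss.tsv", sep="\t"):
    path = tmp_path / name
    df.to_csv(path, sep=sep, index=False)
    return path


class TestReadSumstats:
    def test_identity_parse(self, tmp_path):
        df = pd.DataFrame([make_record(f"rs{i}", position=1000 + i) for i in range(5)])
        out = read_sumstats(_write(tmp_path, df))
        assert len(out) == 5
        assert list(out["variant_id"]) == [f"rs{i}" for i in range(5)]
        assert out.attrs["n_unparseable"] == 0

    def test_unparseable_row_dropped_and_counted(self, tmp_path):
        df = pd.DataFrame([make_record("rs0"), make_record("rs1", position=2000)]).astype(
            {"pvalue": object}
        )
        df.loc[1, "pvalue"] = "NA"
        with pytest.warns(UserWarning, match="unparseable"):
            out = read_sumstats(_write(tmp_path, df))
        assert len(out) == 1
        assert out.attrs["n_unparseable"] == 1

    def test_dialect_maps_alternative_headers(self, tmp_path):
        df = pd.DataFrame([make_record(f"rs{i}", position=1000 + i) for i in range(3)])
        canonical = read_sumstats(_write(tmp_path, df))
        renamed = df.rename(columns={"chromosome": "CHR", "position": "BP", "pvalue": "P"})
        mapped = read_sumstats(
            _write(tmp_path, renamed, "alt.tsv"),
            dialect={"CHR": "chromosome", "BP": "position", "P": "pvalue"},
        )
        pd.testing.assert_frame_equal(canonical, mapped)

    def test_missing_mandatory_column_is_config_error(self, tmp_path):
        df = pd.DataFrame([make_record()]).drop(columns=["se"])
        with pytest.raises(ValueError, match="se"):
            read_sumstats(_write(tmp_path, df))

    def test_missing_info_column_becomes_nan(self, tmp_path):
        df = pd.DataFrame([make_record()]).drop(columns=["info"])
        out = read_sumstats(_write(tmp_path, df))
        assert np.isnan(out["info"].iloc[0])

    def test_empty_file_errors(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(ValueError, match="empty"):
            read_sumstats(path)

    def test_comma_separator_sniffed(self, tmp_path):
        df = pd.DataFrame([make_record()])
        out = read_sumstats(_write(tmp_path, df, "ss.csv", sep=","))
        assert len(out) == 1


class TestQCFilters:
    def test_fixture_survivors_and_attribution(self, qc_fixture):
        out, report = apply_qc_filters(qc_fixture)
        assert sorted(out["variant_id"]) == ["clean1", "clean2", "clean3"]
        assert report.counts_removed == {
            "non_autosomal": 1,
            "multi_allelic": 2,
            "strand_ambiguous": 1,
            "low_info": 1,
            "low_maf": 1,
            "extreme_beta": 1,
            "invalid_pvalue": 0,
            "duplicate_position": 0,
        }

    def test_info_threshold(self):
        df = pd.DataFrame([make_record(info=0.85)])
        out, report = apply_qc_filters(df)
        assert len(out) == 0 and report.counts_removed["low_info"] == 1

    def test_missing_info_passes(self):
        df = pd.DataFrame([make_record(info=np.nan)])
        out, report = apply_qc_filters(df)
        assert len(out) == 1
        assert report.notes["missing_info"] == 1

    def test_ambiguous_pairs_removed(self):
        df = pd.DataFrame(
            [
                make_record("at", effect_allele="A", other_allele="T"),
                make_record("cg", position=2000, effect_allele="C", other_allele="G"),
                make_record("gc", position=3000, effect_allele="G", other_allele="C"),
            ]
        )
        _, report = apply_qc_filters(df)
        assert report.counts_removed["strand_ambiguous"] == 3

    def test_invalid_pvalue_and_duplicates(self):
        df = pd.DataFrame(
            [
                make_record("bad", pvalue=1.2),
                make_record("d1", position=5000),
                make_record("d2", position=5000, effect_allele="A", other_allele="C"),
            ]
        )
        out, report = apply_qc_filters(df)
        # d1/d2 share a position under two ids -> multi-allelic, not residual dup
        assert report.counts_removed["invalid_pvalue"] == 1
        assert report.counts_removed["multi_allelic"] == 2
        assert len(out) == 0

    def test_chr_prefix_normalized(self):
        df = pd.DataFrame([make_record(chromosome="chr1")])
        out, _ = apply_qc_filters(df)
        assert len(out) == 1

    def test_idempotence_and_accounting(self, qc_fixture):
        out1, report1 = apply_qc_filters(qc_fixture)
        assert report1.n_input == report1.n_output + report1.total_removed()
        out2, report2 = apply_qc_filters(out1)
        assert report2.total_removed() == 0
        pd.testing.assert_frame_equal(out1, out2)


def _panel_for(records: pd.DataFrame) -> ReferencePanel:
    """Panel matching the records' positions with allele_b = effect allele."""
    rng = np.random.default_rng(0)
    variants = pd.DataFrame(
        dict(
            variant_id=records["variant_id"],
            chromosome=records["chromosome"].astype(str),
            position=records["position"],
            allele_a=records["other_allele"],
            allele_b=records["effect_allele"],
        )
    ).sort_values(["chromosome", "position"]).reset_index(drop=True)
    dosages = rng.integers(0, 3, size=(len(variants), 50)).astype(float)
    eaf = records.set_index("variant_id")["eaf"].reindex(variants["variant_id"]).to_numpy()
    variants["panel_maf"] = np.minimum(eaf, 1 - eaf)
    return ReferencePanel(variants=variants, dosages=dosages)


class TestAlignment:
    def test_swapped_orientation_flips_beta_and_eaf(self):
        rec = pd.DataFrame([make_record(beta=0.1, eaf=0.3)])
        panel = _panel_for(rec)
        # swap panel orientation so the GWAS effect allele is allele_a
        panel.variants[["allele_a", "allele_b"]] = panel.variants[["allele_b", "allele_a"]].to_numpy()
        out, _ = align_to_reference(rec, panel)
        assert out["beta"].iloc[0] == pytest.approx(-0.1)
        assert out["eaf"].iloc[0] == pytest.approx(0.7)

    def test_absent_from_panel_counted(self):
        rec = pd.DataFrame([make_record(), make_record("rs2", position=99999)])
        panel = _panel_for(rec.iloc[:1])
        out, report = align_to_reference(rec, panel)
        assert len(out) == 1
        assert report.counts_removed["absent_from_panel"] == 1

    def test_maf_discrepancy_removed(self):
        rec = pd.DataFrame([make_record(eaf=0.30)])
        panel = _panel_for(rec)
        panel.variants.loc[0, "panel_maf"] = 0.05  # |0.30 - 0.05| = 0.25 > 0.2
        out, report = align_to_reference(rec, panel)
        assert len(out) == 0 and report.counts_removed["maf_discrepancy"] == 1

    def test_panel_low_maf_removed(self):
        rec = pd.DataFrame([make_record(eaf=0.006)])
        panel = _panel_for(rec)
        panel.variants.loc[0, "panel_maf"] = 0.001
        out, report = align_to_reference(rec, panel)
        assert len(out) == 0 and report.counts_removed["panel_low_maf"] == 1

    def test_unsorted_panel_errors(self):
        rec = pd.DataFrame([make_record(), make_record("rs2", position=500)])
        panel = _panel_for(rec)
        panel.variants["position"] = [2000, 1000]
        with pytest.raises(ValueError, match="unsorted"):
            align_to_reference(rec, panel)

    def test_alignment_involution(self):
        """Flipping orientation and re-aligning returns the original values."""
        rec = pd.DataFrame([make_record(beta=0.17, eaf=0.22)])
        panel = _panel_for(rec)
        flipped = rec.copy()
        flipped[["effect_allele", "other_allele"]] = flipped[
            ["other_allele", "effect_allele"]
        ].to_numpy()
        flipped["beta"] = -flipped["beta"]
        flipped["eaf"] = 1 - flipped["eaf"]
        out, _ = align_to_reference(flipped, panel)
        assert out["beta"].iloc[0] == pytest.approx(0.17, abs=1e-15)
        assert out["eaf"].iloc[0] == pytest.approx(0.22, abs=1e-15)


class TestEffectiveSampleSize:
    @pytest.mark.parametrize(
        "n_case,n_control,convention,expected",
        [
            (100, 100, "finemap", 200.0),
            (100, 100, "ldsc", 50.0),
            # large case-control GWAS, evaluated directly from the formula
            (122188, 604640, "finemap", 4.0 / (1.0 / 122188 + 1.0 / 604640)),
        ],
    )
    def test_values(self, n_case, n_control, convention, expected):
        assert effective_sample_size(n_case, n_control, convention) == pytest.approx(expected)

    def test_nonpositive_count_errors(self):
        with pytest.raises(ValueError):
            effective_sample_size(0, 100, "ldsc")

    @settings(deadline=None, derandomize=True)
    @given(st.integers(1, 10**7), st.integers(1, 10**7))
    def test_finemap_is_four_times_ldsc(self, a, b):
        assert effective_sample_size(a, b, "finemap") == pytest.approx(
            4 * effective_sample_size(a, b, "ldsc")
        )


def test_panel_roundtrip(tmp_path, small_sim):
    panel = small_sim["panel"]
    panel.save(tmp_path / "panel")
    loaded = ReferencePanel.load(tmp_path / "panel")
    pd.testing.assert_frame_equal(
        panel.variants.reset_index(drop=True), loaded.variants, check_dtype=False
    )
    np.testing.assert_allclose(panel.dosages, loaded.dosages, atol=1e-5)
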