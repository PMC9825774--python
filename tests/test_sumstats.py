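"""Column detection, Z-score computation, P clamping, allele alignment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from locuskit import sumstats
from locuskit.sumstats import (
    MIN_P,
    AlignmentError,
    AmbiguousColumnError,
    MungeConfig,
    NoUsableRecordsError,
    SchemaError,
    align_to_reference,
    clamp_p,
    compute_z,
    detect_columns,
    harmonize,
    load_cache,
    save_cache,
)


class TestDetectColumns:
    def test_metal_style_headers_resolve_fully(self):
        schema = detect_columns(
            ["MarkerName", "CHR", "BP", "Allele1", "Allele2", "Effect", "StdErr", "P-value"]
        )
        assert schema.mapping == {
            "snp_id": "MarkerName", "chrom": "CHR", "pos": "BP",
            "allele_effect": "Allele1", "allele_other": "Allele2",
            "beta": "Effect", "se": "StdErr", "p": "P-value",
        }

    def test_canonical_headers_map_to_themselves(self):
        headers = ["snp_id", "chrom", "pos", "allele_effect", "allele_other", "z", "p"]
        schema = detect_columns(headers)
        assert schema.mapping == {h: h for h in headers}

    def test_missing_position_column_is_an_error(self):
        with pytest.raises(SchemaError, match="snp_id"):
            detect_columns(["CHR", "A1", "A2", "P"])

    def test_missing_statistic_is_an_error(self):
        with pytest.raises(SchemaError, match="statistic"):
            detect_columns(["SNP", "CHR", "BP", "A1", "A2"])

    def test_two_headers_for_one_field_is_ambiguous(self):
        with pytest.raises(AmbiguousColumnError, match="rsid"):
            detect_columns(["SNP", "rsid", "CHR", "BP", "P"])

    def test_matching_is_case_insensitive(self):
        schema = detect_columns(["snp", "chr", "bp", "PVAL"])
        assert set(schema.mapping) == {"snp_id", "chrom", "pos", "p"}

    def test_synonyms_extendable_via_config(self):
        schema = detect_columns(["SNP", "mychrom", "BP", "P"],
                                extra_synonyms={"mychrom": "chrom"})
        assert schema.source("chrom") == "mychrom"


class TestComputeZ:
    def test_source_priority_and_arithmetic(self):
        df = pd.DataFrame(
            {
                "z": [np.nan, np.nan, np.nan, 3.5],
                "beta": [0.1, np.nan, -1.0, 0.1],
                "odds_ratio": [np.nan, 1.0, np.nan, np.nan],
                "se": [0.05, 0.1, np.nan, 0.05],
                "p": [np.nan, np.nan, 0.05, np.nan],
            }
        )
        z, valid = compute_z(df)
        assert valid.all()
        assert z[0] == pytest.approx(2.0)          # beta/se
        assert z[1] == pytest.approx(0.0)          # ln(1)/se
        # inverse-normal from p with a negative sign source
        assert z[2] == pytest.approx(-1.9599639845400545, abs=1e-9)
        assert z[3] == 3.5                         # provided z wins over beta/se

    def test_nonpositive_se_flags_record_invalid(self):
        df = pd.DataFrame({"beta": [0.1, 0.2], "se": [0.0, -1.0]})
        _, valid = compute_z(df)
        assert not valid.any()

    def test_p_outside_unit_interval_flags_record_invalid(self):
        df = pd.DataFrame({"beta": [1.0, 1.0], "p": [0.0, 1.5]})
        _, valid = compute_z(df)
        assert not valid.any()

    def test_p_roundtrip_recovers_p_to_1e10_relative(self):
        # z from (p, sign), then back through the two-sided normal formula
        p = 10.0 ** np.linspace(-300, 0, 80)[:-1]
        df = pd.DataFrame({"p": p, "beta": np.ones_like(p)})
        z, valid = compute_z(df)
        assert valid.all()
        p_back = 2 * stats.norm.sf(np.abs(z))
        np.testing.assert_allclose(p_back, p, rtol=1e-10)


class TestClampP:
    def test_simple_values(self):
        p_out, nl = clamp_p(p=np.array([1.0, 0.01]))
        assert nl[0] == 0.0
        assert nl[1] == pytest.approx(2.0)
        np.testing.assert_array_equal(p_out, [1.0, 0.01])

    def test_zero_p_clamps_to_smallest_subnormal(self):
        p_out, nl = clamp_p(p=np.array([0.0]))
        assert p_out[0] == MIN_P == 5e-324
        assert nl[0] == pytest.approx(323.3062153431158)

    def test_neglog10p_monotone_in_z_beyond_underflow(self):
        z = np.arange(1, 61, dtype=float)
        _, nl = clamp_p(p=2 * stats.norm.sf(z), z=z)
        assert np.all(np.isfinite(nl))
        assert np.all(np.diff(nl) > 0), "no plateau allowed across the underflow point"

    def test_clamp_constant_configurable(self):
        p_out, nl = clamp_p(p=np.array([0.0]), clamp_value=1e-100)
        assert p_out[0] == 1e-100
        assert nl[0] == pytest.approx(100.0)


class TestHarmonize:
    def _raw(self, **overrides):
        base = {
            "SNP": ["rs1", "rs2", "rs3"],
            "CHR": ["chr1", "1", "chr2"],
            "BP": [100, 200, 300],
            "A1": ["a", "T", "G"],
            "A2": ["t", "c", "A"],
            "BETA": [0.1, -0.2, 0.3],
            "SE": [0.1, 0.1, 0.1],
            "P": [0.3, 0.04, 0.002],
        }
        base.update(overrides)
        return pd.DataFrame(base)

    def test_alleles_uppercased_and_chr_prefix_stripped(self):
        out = harmonize(self._raw())
        assert out["allele_effect"].tolist() == ["A", "T", "G"]
        assert set(out["chrom"]) == {"1", "2"}

    def test_numeric_sex_chromosome_aliases(self):
        out = harmonize(self._raw(CHR=["23", "24", "26"]))
        assert out["chrom"].tolist() == ["X", "Y", "MT"]

    def test_duplicates_keep_first_and_sorted_by_position(self):
        raw = self._raw(CHR=["1", "1", "1"], BP=[200, 100, 100],
                        A1=["A", "G", "G"], A2=["G", "A", "A"])
        out = harmonize(raw)
        # rs2/rs3 share a variant key (order-insensitive allele pair)
        assert len(out) == 2
        assert out["pos"].tolist() == [100, 200]
        assert out.loc[out["pos"] == 100, "snp_id"].item() == "rs2"

    def test_duplicate_policy_keep_min_p(self):
        raw = self._raw(CHR=["1", "1", "1"], BP=[100, 100, 100],
                        A1=["A", "A", "A"], A2=["G", "G", "G"],
                        P=[0.5, 0.001, 0.1], BETA=[0.1, 0.33, 0.16])
        out = harmonize(raw, config=MungeConfig(duplicate_policy="keep_min_p"))
        assert len(out) == 1
        assert out["snp_id"].item() == "rs2"

    def test_no_usable_records_raises(self):
        raw = self._raw(SE=[0.0, 0.0, 0.0], P=[np.nan] * 3)
        with pytest.raises(NoUsableRecordsError):
            harmonize(raw)

    def test_z_sign_matches_beta_and_p_never_zero(self):
        out = harmonize(self._raw(P=[0.0, 0.04, 0.002]))
        assert (out["p"] > 0).all()
        assert np.isfinite(out["neglog10p"]).all()
        present = out["beta"].notna()
        assert (np.sign(out.loc[present, "z"]) == np.sign(out.loc[present, "beta"])).all()


class TestAlignToReference:
    PANEL = pd.DataFrame(
        {
            "chrom": ["1", "1", "1", "1"],
            "pos": [100, 200, 300, 400],
            "allele_1": ["G", "T", "A", "A"],
            "allele_2": ["A", "C", "T", "C"],
        }
    )

    def _ss(self, pos, ea, oa, z=2.0, eaf=0.2):
        return pd.DataFrame(
            {
                "snp_id": [f"1:{p}" for p in pos], "chrom": "1", "pos": pos,
                "allele_effect": ea, "allele_other": oa,
                "z": z, "p": 0.05, "neglog10p": 1.3, "eaf": eaf, "trait": "t",
            }
        )

    def test_swapped_alleles_flip_z_and_eaf(self):
        out = align_to_reference(self._ss([100], ["A"], ["G"], z=2.0, eaf=0.2), self.PANEL)
        assert out["z"].item() == -2.0
        assert out["eaf"].item() == pytest.approx(0.8)
        assert (out["allele_effect"].item(), out["allele_other"].item()) == ("G", "A")

    def test_strand_complement_match_keeps_z(self):
        # sumstats (A, G) vs panel (T, C): complement, not swapped
        out = align_to_reference(self._ss([200], ["A"], ["G"], z=2.0), self.PANEL)
        assert out["z"].item() == 2.0
        assert (out["allele_effect"].item(), out["allele_other"].item()) == ("T", "C")

    def test_complement_plus_swap_flips_z(self):
        # sumstats (G, A) vs panel (T, C): complement of (C, T) i.e. swapped
        out = align_to_reference(self._ss([200], ["G"], ["A"], z=2.0, eaf=0.3), self.PANEL)
        assert out["z"].item() == -2.0
        assert out["eaf"].item() == pytest.approx(0.7)

    def test_palindromic_ambiguous_dropped_by_default(self):
        ss = pd.concat(
            [self._ss([300], ["A"], ["T"], eaf=0.5), self._ss([100], ["G"], ["A"])],
            ignore_index=True,
        )
        out = align_to_reference(ss, self.PANEL)
        assert out["pos"].tolist() == [100]

    def test_palindromic_kept_when_eaf_informative(self):
        out = align_to_reference(self._ss([300], ["A"], ["T"], eaf=0.9), self.PANEL)
        assert out["pos"].tolist() == [300]

    def test_palindromic_policies(self):
        ss = self._ss([300], ["A"], ["T"], eaf=0.9)
        assert len(align_to_reference(ss, self.PANEL,
                                      MungeConfig(palindromic_policy="keep_all"))) == 1
        with pytest.raises(NoUsableRecordsError):
            align_to_reference(ss, self.PANEL, MungeConfig(palindromic_policy="drop_all"))

    def test_unmatched_position_dropped(self):
        ss = pd.concat(
            [self._ss([100], ["G"], ["A"]), self._ss([999], ["A"], ["C"])],
            ignore_index=True,
        )
        assert align_to_reference(ss, self.PANEL)["pos"].tolist() == [100]

    def test_zero_matches_suggests_build_mismatch(self):
        with pytest.raises(AlignmentError, match="build"):
            align_to_reference(self._ss([999], ["A"], ["C"]), self.PANEL)

    def test_idempotent(self):
        ss = pd.concat(
            [
                self._ss([100], ["A"], ["G"], z=2.0, eaf=0.2),
                self._ss([200], ["A"], ["G"], z=-1.0, eaf=0.7),
                self._ss([400], ["A"], ["C"], z=0.5, eaf=0.1),
            ],
            ignore_index=True,
        )
        once = align_to_reference(ss, self.PANEL)
        twice = align_to_reference(once, self.PANEL)
        pd.testing.assert_frame_equal(once, twice)


class TestCache:
    def test_round_trip_is_lossless(self, tmp_path, harmonized):
        path = tmp_path / "cache.feather"
        save_cache(harmonized, path)
        pd.testing.assert_frame_equal(load_cache(path), harmonized)

    def test_empty_table_round_trips(self, tmp_path, harmonized):
        path = tmp_path / "empty.feather"
        save_cache(harmonized.iloc[:0], path)
        assert load_cache(path).empty

    def test_unwritable_path_raises_oserror(self, harmonized):
        with pytest.raises(OSError):
            save_cache(harmonized, "/nonexistent-dir/cache.feather")


def test_read_sumstats_detects_delimiters(tmp_path):
    df = pd.DataFrame({"SNP": ["rs1"], "CHR": [1], "BP": [100], "P": [0.5]})
    for name, sep in [("a.tsv", "\t"), ("b.csv", ","), ("c.txt", " ")]:
        df.to_csv(tmp_path / name, sep=sep, index=False)
        out = sumstats.read_sumstats(tmp_path / name)
        assert out.columns.tolist() == ["SNP", "CHR", "BP", "P"]
    gz = tmp_path / "d.tsv.gz"
    df.to_csv(gz, sep="\t", index=False, compression="gzip")
    assert sumstats.read_sumstats(gz)["BP"].item() == 100


def test_munge_config_from_yaml(tmp_path):
    path = tmp_path / "munge.yaml"
    path.write_text(
        "palindromic_policy: keep_all\npalindromic_band: [0.35, 0.65]\n"
        "extra_synonyms:\n  mychrom: chrom\n"
    )
    cfg = MungeConfig.from_file(path)
    assert cfg.palindromic_policy == "keep_all"
    assert cfg.palindromic_band == (0.35, 0.65)
    assert cfg.extra_synonyms == {"mychrom": "chrom"}
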