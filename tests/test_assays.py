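"""Assay registry: channel→allele semantics and the homozygous-mother model."""

import io

import pytest

from ddfetal.assays import (
    AssayConfigError,
    AssumptionViolationError,
    Channel,
    MaternalContext,
    builtin_registry,
    fetus_specific_channel,
    load_assays,
    maternal_channel,
    parse_genotype,
)


class TestBuiltinRegistry:
    def test_contains_four_assays(self, registry):
        assert set(registry) == {"RHD_ex7", "RHCE_rs609320", "RHCE_rs676785", "KEL_rs8176058"}

    def test_rhd_channels(self, registry):
        rhd = registry["RHD_ex7"]
        assert rhd.fam_allele == "RHD+"
        assert rhd.hex_allele == "beta-globin"
        assert rhd.reference_channel_is_total_dna
        assert rhd.null_allele == "RHD-"

    def test_kel_channels(self, registry):
        kel = registry["KEL_rs8176058"]
        assert kel.fam_allele == "KEL1" and kel.hex_allele == "KEL2"
        assert not kel.reference_channel_is_total_dna

    def test_snp_assay_alleles(self, registry):
        assert registry["RHCE_rs676785"].genotype_alleles == ("c", "C")
        assert registry["RHCE_rs609320"].genotype_alleles == ("e", "E")


class TestLoadAssays:
    CONFIG = """
assays:
  - name: FY_rs2814778
    gene: ACKR1
    snp_id: rs2814778
    fam_allele: FY*A
    hex_allele: FY*B
    amplicon_length_bp: 80
"""

    def test_none_gives_builtins(self, registry):
        assert load_assays(None).keys() == registry.keys()

    def test_yaml_stream_extends_builtins(self):
        reg = load_assays(io.StringIO(self.CONFIG))
        assert "FY_rs2814778" in reg and "RHD_ex7" in reg

    def test_yaml_file(self, tmp_path):
        path = tmp_path / "assays.yaml"
        path.write_text(self.CONFIG)
        assert "FY_rs2814778" in load_assays(path)

    def test_duplicate_name_rejected(self):
        bad = self.CONFIG + self.CONFIG.replace("assays:\n", "")
        with pytest.raises(AssayConfigError, match="duplicate"):
            load_assays(io.StringIO(bad))

    def test_builtin_name_collision_rejected(self):
        cfg = self.CONFIG.replace("FY_rs2814778", "RHD_ex7")
        with pytest.raises(AssayConfigError, match="duplicate"):
            load_assays(io.StringIO(cfg))

    def test_missing_field_named(self):
        cfg = self.CONFIG.replace("    hex_allele: FY*B\n", "")
        with pytest.raises(AssayConfigError, match="hex_allele"):
            load_assays(io.StringIO(cfg))

    def test_identical_channel_alleles_rejected(self):
        cfg = self.CONFIG.replace("FY*B", "FY*A")
        with pytest.raises(AssayConfigError, match="must differ"):
            load_assays(io.StringIO(cfg))


class TestParseGenotype:
    @pytest.mark.parametrize(
        "assay_name, text, expected",
        [
            ("RHCE_rs676785", "c/c", ("c", "c")),
            ("RHCE_rs676785", "cc", ("c", "c")),
            ("RHCE_rs676785", "Cc", ("C", "c")),
            ("RHCE_rs609320", "Ee", ("E", "e")),
            ("KEL_rs8176058", "KEL1/KEL2", ("KEL1", "KEL2")),
            ("RHD_ex7", "RHD-/RHD-", ("RHD-", "RHD-")),
            ("RHD_ex7", "RHD−/RHD−", ("RHD-", "RHD-")),  # unicode minus
        ],
    )
    def test_forms(self, registry, assay_name, text, expected):
        assert parse_genotype(registry[assay_name], text) == expected

    def test_unknown_allele(self, registry):
        with pytest.raises(AssumptionViolationError, match="not valid"):
            parse_genotype(registry["KEL_rs8176058"], "KEL1/KEL3")


class TestMaternalContext:
    def test_heterozygous_mother_rejected(self, registry):
        with pytest.raises(AssumptionViolationError, match="heterozygous"):
            MaternalContext(registry["RHCE_rs676785"], "Cc")

    def test_rhd_positive_mother_rejected(self, registry):
        with pytest.raises(AssumptionViolationError, match="maternal background"):
            MaternalContext(registry["RHD_ex7"], "RHD+/RHD+")

    def test_control_locus_not_a_genotype(self, registry):
        with pytest.raises(AssumptionViolationError):
            MaternalContext(registry["RHD_ex7"], "beta-globin/beta-globin")


class TestFetusSpecificChannel:
    @pytest.mark.parametrize(
        "assay_name, maternal, channel, allele",
        [
            ("RHCE_rs676785", "cc", Channel.HEX, "C"),
            ("RHCE_rs676785", "CC", Channel.FAM, "c"),
            ("RHCE_rs609320", "ee", Channel.HEX, "E"),
            ("RHCE_rs609320", "EE", Channel.FAM, "e"),
            ("KEL_rs8176058", "KEL2/KEL2", Channel.FAM, "KEL1"),
            ("KEL_rs8176058", "KEL1/KEL1", Channel.HEX, "KEL2"),
            ("RHD_ex7", "RHD-/RHD-", Channel.FAM, "RHD+"),
        ],
    )
    def test_designation(self, registry, assay_name, maternal, channel, allele):
        ctx = MaternalContext(registry[assay_name], maternal)
        assert fetus_specific_channel(ctx) == (channel, allele)
        assert maternal_channel(ctx) is channel.other()

    def test_two_homozygotes_get_opposite_channels(self, registry):
        """For every SNP assay the two possible homozygous mothers resolve
        to complementary fetus-specific channels."""
        for assay in registry.values():
            if assay.reference_channel_is_total_dna:
                continue
            ch_a, _ = fetus_specific_channel(MaternalContext(assay, (assay.fam_allele,) * 2))
            ch_b, _ = fetus_specific_channel(MaternalContext(assay, (assay.hex_allele,) * 2))
            assert {ch_a, ch_b} == {Channel.FAM, Channel.HEX}
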