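"""Panel/outcome I/O, allele harmonization, and OR/CI conversion."""

import math

import pytest
from hypothesis import given, strategies as st

from scoremr import (
    ConfigError,
    DomainError,
    OutcomeAssociation,
    ParseError,
    SimConfig,
    SnpRecord,
    harmonize,
    log_to_or_ci,
    or_ci_to_log,
    read_panel,
    simulate_panel,
    write_panel,
)
from scoremr.sumstats import (
    DROPPED_MISMATCH,
    DROPPED_PALINDROMIC,
    SIGN_FLIPPED,
    UNCHANGED,
)


def _outcome(rsid="rs1", ea="A", oa="G", eaf=0.3, beta=-0.05, se=0.02):
    return OutcomeAssociation(rsid, ea, oa, eaf, beta, se, 0.5)


def _snp(rsid="rs1", ea="A", oa="G", eaf=0.3, beta=0.1):
    return SnpRecord(rsid, ea, oa, eaf, beta, 0.01, 1e-9)


class TestPanelIO:
    def test_simulated_panel_roundtrips_exactly(self, tmp_path):
        panel = simulate_panel(SimConfig(seed=7))
        path = tmp_path / "panel.tsv"
        write_panel(panel, path)
        back = read_panel(path)
        assert len(back) == 84
        for a, b in zip(panel, back):
            assert a == b  # repr-based serialization is lossless

    def test_header_only_file_gives_empty_panel(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("rsid\teffect_allele\tother_allele\teaf\tbeta\tse\tp\n")
        assert read_panel(path) == []

    def test_missing_column_is_config_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("rsid\teffect_allele\tother_allele\teaf\tbeta\tse\n")
        with pytest.raises(ConfigError, match="p"):
            read_panel(path)

    def test_malformed_numeric_names_rsid_and_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "rsid\teffect_allele\tother_allele\teaf\tbeta\tse\tp\n"
            "rs42\tA\tG\t0.3\toops\t0.01\t0.5\n"
        )
        with pytest.raises(ParseError, match=r"line 2.*rs42.*beta"):
            read_panel(path)

    def test_duplicate_rsid_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        row = "rs1\tA\tG\t0.3\t0.1\t0.01\t0.5\n"
        path.write_text("rsid\teffect_allele\tother_allele\teaf\tbeta\tse\tp\n" + row + row)
        with pytest.raises(ParseError, match="duplicate"):
            read_panel(path)

    def test_dialect_remaps_column_names(self, tmp_path):
        path = tmp_path / "giant.tsv"
        path.write_text("SNP\tA1\tA2\tFreq\tb\tSE\tP\nrs1\tA\tG\t0.3\t0.1\t0.01\t0.5\n")
        dialect = {
            "rsid": "SNP", "effect_allele": "A1", "other_allele": "A2",
            "eaf": "Freq", "beta": "b", "se": "SE", "p": "P",
        }
        (rec,) = read_panel(path, dialect=dialect)
        assert rec.rsid == "rs1" and rec.beta_exposure == 0.1


class TestHarmonize:
    # (outcome ea, outcome oa) against panel A/G, expected action
    TRUTH_TABLE = [
        ("A", "G", UNCHANGED),  # identical
        ("G", "A", SIGN_FLIPPED),  # swapped
        ("T", "C", UNCHANGED),  # strand complement
        ("C", "T", SIGN_FLIPPED),  # complement + swapped
        ("A", "C", DROPPED_MISMATCH),  # incompatible pair
        ("C", "G", DROPPED_MISMATCH),  # different variant class
    ]

    @pytest.mark.parametrize("ea,oa,expected", TRUTH_TABLE)
    def test_allele_configuration_truth_table(self, ea, oa, expected):
        snp = _snp()
        out = _outcome(ea=ea, oa=oa)
        (pair,) = harmonize([snp], [out]).pairs
        assert pair.action == expected
        if expected == UNCHANGED:
            assert pair.outcome.beta_outcome == out.beta_outcome
            assert pair.outcome.eaf == out.eaf
        if expected == SIGN_FLIPPED:
            assert pair.outcome.beta_outcome == -out.beta_outcome
            assert pair.outcome.eaf == pytest.approx(1.0 - out.eaf)
            assert pair.outcome.effect_allele == snp.effect_allele

    @pytest.mark.parametrize(
        "panel_eaf,out_eaf,policy,expected",
        [
            (0.50, 0.50, "drop", DROPPED_PALINDROMIC),  # uninformative frequency
            (0.20, 0.21, "drop", UNCHANGED),  # same minor side
            (0.20, 0.80, "drop", SIGN_FLIPPED),  # opposite sides
            (0.20, 0.21, "drop-all", DROPPED_PALINDROMIC),
            (0.50, 0.50, "ignore", UNCHANGED),  # literal allele match
        ],
    )
    def test_palindromic_policies(self, panel_eaf, out_eaf, policy, expected):
        snp = _snp(ea="A", oa="T", eaf=panel_eaf)
        out = _outcome(ea="A", oa="T", eaf=out_eaf)
        (pair,) = harmonize([snp], [out], palindromic_policy=policy).pairs
        assert pair.action == expected

    def test_double_swap_is_identity(self):
        snp = _snp()
        out = _outcome(ea="G", oa="A", eaf=0.7, beta=0.05)
        (pair,) = harmonize([snp], [out]).pairs
        # flipping the already-flipped record restores the original values
        (pair2,) = harmonize(
            [_snp(ea="G", oa="A", eaf=0.7)], [pair.outcome]
        ).pairs
        assert pair2.action == SIGN_FLIPPED
        assert pair2.outcome.beta_outcome == pytest.approx(out.beta_outcome)
        assert pair2.outcome.eaf == pytest.approx(out.eaf)

    def test_harmonize_is_idempotent(self):
        panel = [_snp("rs1"), _snp("rs2", ea="C", oa="T", eaf=0.6)]
        outcome = [
            _outcome("rs1", ea="G", oa="A", eaf=0.7),
            _outcome("rs2", ea="T", oa="C", eaf=0.4),
        ]
        first = harmonize(panel, outcome)
        again = harmonize(panel, [p.outcome for p in first.kept])
        assert all(p.action == UNCHANGED for p in again.pairs)

    def test_unmatched_rsids_reported_not_dropped_silently(self):
        panel = [_snp("rs1"), _snp("rs2", ea="C", oa="T")]
        report = harmonize(panel, [_outcome("rs2", ea="C", oa="T"), _outcome("rs9", ea="C", oa="T")])
        assert report.unmatched_panel == ["rs1"]
        assert report.unmatched_outcome == ["rs9"]
        assert len(report.pairs) == 1

    def test_unknown_policy_rejected(self):
        with pytest.raises(ConfigError):
            harmonize([_snp()], [_outcome()], palindromic_policy="maybe")


class TestOrCiConversion:
    def test_null_or_maps_to_zero(self):
        assert or_ci_to_log(1.0, 1.0, 1.0) == (0.0, 0.0)

    def test_published_cell_conversion(self):
        beta, se = or_ci_to_log(0.93, 0.91, 0.95)
        assert beta == pytest.approx(-0.0726, abs=5e-5)
        assert se == pytest.approx(0.0110, abs=5e-5)

    def test_inverse_transform_recovers_ci(self):
        beta, se = or_ci_to_log(0.95, 0.91, 0.99)
        or_, lo, hi = log_to_or_ci(beta, se)
        assert (round(lo, 2), round(hi, 2)) == (0.91, 0.99)
        assert or_ == pytest.approx(0.95)

    @pytest.mark.parametrize("triple", [(0.0, 0.1, 0.2), (1.0, 1.1, 0.9), (0.5, 0.6, 0.7)])
    def test_invalid_inputs_rejected(self, triple):
        with pytest.raises(DomainError):
            or_ci_to_log(*triple)

    @given(
        beta=st.floats(-2, 2),
        se=st.floats(1e-6, 1.0),
        level=st.floats(0.5, 0.999),
    )
    def test_roundtrip_property(self, beta, se, level):
        or_, lo, hi = log_to_or_ci(beta, se, level)
        b2, s2 = or_ci_to_log(or_, lo, hi, level)
        assert math.isclose(b2, beta, abs_tol=1e-6)
        assert math.isclose(s2, se, abs_tol=1e-6)
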