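import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uriexc.features import (
    ProteinRecord,
    SequenceError,
    aa_composition,
    charge_features,
    compute_feature_vector,
    ctd_features,
    disorder_features,
    default_registry,
    glycosylation_features,
    henderson_hasselbalch_charge,
    isoelectric_point,
    membrane_motif_features,
    normalize_sequence,
    protparam_features,
    read_fasta,
    secondary_structure_content,
    signal_peptide_features,
)
from uriexc.features.tables import (
    KYTE_DOOLITTLE,
    PKA_CTERM,
    PKA_NTERM,
    SIMPLE_CHARGE,
    STANDARD_AA,
)

AA = st.sampled_from(STANDARD_AA)
SEQUENCES = st.text(alphabet=STANDARD_AA, min_size=1, max_size=400)


# --- records / FASTA ------------------------------------------------------


class TestReadFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">P1\nMKV\n")
        recs = read_fasta(p)
        assert [(r.id, r.sequence) for r in recs] == [("P1", "MKV")]

    def test_lowercase_uppercased(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">P1\nmkv\n")
        assert read_fasta(p)[0].sequence == "MKV"

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">P1\nMKV\n>P1\nACD\n")
        with pytest.raises(ValueError, match="P1"):
            read_fasta(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text("")
        with pytest.raises(ValueError):
            read_fasta(p)

    def test_wrapped_lines_and_order(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">B desc\nMK\nVA\n>A\nCCD\n")
        recs = read_fasta(p)
        assert [r.id for r in recs] == ["B", "A"]
        assert recs[0].sequence == "MKVA"


class TestNormalize:
    def test_nonstandard_mapped_to_x(self):
        assert normalize_sequence("MBZU") == "MXXX"

    def test_invalid_char_rejected(self):
        with pytest.raises(SequenceError):
            normalize_sequence("MK1V")

    def test_empty_rejected(self):
        with pytest.raises(SequenceError):
            normalize_sequence("")


# --- composition ----------------------------------------------------------


class TestAAComposition:
    def test_homopolymer(self):
        comp = aa_composition("AAAA")
        assert comp["A"] == 1.0
        assert sum(comp.values()) == pytest.approx(1.0)

    def test_hand_count(self):
        comp = aa_composition("ACDC")
        assert comp["A"] == 0.25
        assert comp["C"] == 0.50
        assert comp["D"] == 0.25

    def test_18mer(self):
        comp = aa_composition("MKWVTFISLLLLFSSAYS")
        assert sum(comp.values()) == pytest.approx(1.0, abs=1e-9)
        assert comp["W"] == pytest.approx(1 / 18)

    def test_x_excluded_from_denominator(self):
        comp = aa_composition("AX")
        assert comp["A"] == 1.0

    @given(seq=SEQUENCES)
    @settings(max_examples=50, deadline=None)
    def test_sums_to_one(self, seq):
        assert sum(aa_composition(seq).values()) == pytest.approx(1.0, abs=1e-9)


# --- charge ---------------------------------------------------------------


def hh_oracle(sequence, pH):
    """Independent Henderson-Hasselbalch sum from the shipped pKa set."""
    from uriexc.features.tables import PKA_SIDECHAIN_ACIDIC, PKA_SIDECHAIN_BASIC

    q = 1 / (1 + 10 ** (pH - PKA_NTERM)) - 1 / (1 + 10 ** (PKA_CTERM - pH))
    for aa in sequence:
        if aa in PKA_SIDECHAIN_BASIC:
            q += 1 / (1 + 10 ** (pH - PKA_SIDECHAIN_BASIC[aa]))
        if aa in PKA_SIDECHAIN_ACIDIC:
            q -= 1 / (1 + 10 ** (PKA_SIDECHAIN_ACIDIC[aa] - pH))
    return q


class TestCharge:
    def test_lysine_near_plus_one(self):
        assert charge_features("K")["net_charge"] == pytest.approx(1.0, abs=0.1)

    def test_aspartate_near_minus_one(self):
        assert charge_features("D")["net_charge"] == pytest.approx(-1.0, abs=0.1)

    def test_kd_balance(self):
        # equal K and D: side-chain contributions cancel; compare against a
        # sequence with no ionizable side chains at all
        net_kd = charge_features("KDGKDG")["net_charge"]
        net_gg = charge_features("GGGGGG")["net_charge"]
        assert abs(net_kd - net_gg) < 0.05

    def test_ph_out_of_range(self):
        with pytest.raises(ValueError):
            charge_features("K", pH=15.0)

    @given(seq=st.text(alphabet=STANDARD_AA, min_size=1, max_size=30),
           pH=st.floats(min_value=1.0, max_value=13.0))
    @settings(max_examples=50, deadline=None)
    def test_matches_oracle(self, seq, pH):
        got = henderson_hasselbalch_charge(seq, pH)
        assert got == pytest.approx(hh_oracle(seq, pH), abs=1e-9)

    def test_fraction_fields(self):
        f = charge_features("KKRRHDE")
        assert f["charge_frac_positive"] == pytest.approx(5 / 7)
        assert f["charge_frac_negative"] == pytest.approx(2 / 7)


# --- protparam ------------------------------------------------------------


class TestProtParam:
    def test_glycine_mass(self):
        assert protparam_features("G")["molecular_weight"] == pytest.approx(75.07, abs=0.05)

    def test_poly_ile_gravy(self):
        assert protparam_features("IIII")["gravy"] == pytest.approx(4.5)

    def test_pi_brackets_terminal_pkas(self):
        pi = protparam_features("GGGG")["isoelectric_point"]
        assert PKA_CTERM < pi < PKA_NTERM

    def test_pi_zero_charge(self):
        pi = isoelectric_point("MKWVTFISLLLLFSSAYS")
        assert abs(henderson_hasselbalch_charge("MKWVTFISLLLLFSSAYS", pi)) < 1e-3

    def test_length_one_instability_zero(self):
        assert protparam_features("G")["instability_index"] == 0.0

    def test_aliphatic_index_poly_ala(self):
        assert protparam_features("AAAA")["aliphatic_index"] == pytest.approx(100.0)


# --- disorder -------------------------------------------------------------


def fold_index_oracle(seq, window=51):
    """Direct evaluation of 2.785<H> - |<R>| - 1.151 per shrunk window."""
    n = len(seq)
    out = []
    for i in range(n):
        r = min(i, n - 1 - i, window // 2)
        win = seq[i - r : i + r + 1]
        h = sum((KYTE_DOOLITTLE[a] + 4.5) / 9 for a in win) / len(win)
        c = sum(SIMPLE_CHARGE[a] for a in win) / len(win)
        out.append(2.785 * h - abs(c) - 1.151)
    return out


class TestDisorder:
    def test_poly_ile_ordered(self):
        f = disorder_features("I" * 80)
        assert f["mean_fold_index"] > 0
        assert f["longest_disordered_run"] == 0.0

    def test_poly_glu_disordered(self):
        f = disorder_features("E" * 80)
        assert f["mean_fold_index"] < 0
        assert f["frac_disordered"] == 1.0

    @given(seq=SEQUENCES)
    @settings(max_examples=30, deadline=None)
    def test_fraction_in_unit_interval(self, seq):
        f = disorder_features(seq)
        assert 0.0 <= f["frac_disordered"] <= 1.0

    def test_matches_oracle(self, rng):
        from conftest import random_sequence

        seq = random_sequence(rng, 120)
        oracle = fold_index_oracle(seq)
        got = disorder_features(seq)
        assert got["mean_fold_index"] == pytest.approx(np.mean(oracle), abs=1e-9)
        assert got["frac_disordered"] == pytest.approx(np.mean(np.array(oracle) < 0), abs=1e-12)


# --- secondary structure --------------------------------------------------


class TestSecondaryStructure:
    @given(seq=SEQUENCES)
    @settings(max_examples=30, deadline=None)
    def test_sums_to_one(self, seq):
        f = secondary_structure_content(seq)
        assert sum(f.values()) == pytest.approx(1.0, abs=1e-9)

    def test_poly_ala_more_helix_than_poly_pro(self):
        assert (secondary_structure_content("A" * 40)["helix"]
                > secondary_structure_content("P" * 40)["helix"])

    def test_poly_val_more_strand_than_poly_ala(self):
        assert (secondary_structure_content("V" * 40)["strand"]
                > secondary_structure_content("A" * 40)["strand"])


# --- signal peptide -------------------------------------------------------


class TestSignalPeptide:
    def test_acidic_sequence_not_called(self):
        f = signal_peptide_features("DEDEDEDEDEDEDEDEDEDE")
        assert f["signal_call"] == 0.0

    def test_canonical_prefix_called(self):
        f = signal_peptide_features("MKKTLLALSLLAALSAPAFA" + "G" * 30)
        assert f["signal_call"] == 1.0
        # hand evaluation: best h-window LLALSLLAAL mean KD 2.74, n-region MKKT
        # holds 2 basic residues weighted 0.5 => score 3.74
        assert f["signal_score"] == pytest.approx(3.74, abs=1e-9)

    def test_short_sequence_floor(self):
        f = signal_peptide_features("MKVLLALSTV")  # length 10 < 15
        assert f == {"signal_score": 0.0, "signal_call": 0.0}


# --- membrane / motifs ----------------------------------------------------


class TestMembraneMotif:
    def test_embedded_leucine_stretch(self):
        seq = "S" * 25 + "L" * 19 + "S" * 25
        assert membrane_motif_features(seq)["tm_count"] >= 1

    def test_tat_motif(self):
        assert membrane_motif_features("MTRRNFLK" + "G" * 40)["tat_motif"] == 1.0

    def test_tat_motif_only_in_nterm(self):
        assert membrane_motif_features("G" * 40 + "TRRNFLK")["tat_motif"] == 0.0

    def test_all_glycine(self):
        f = membrane_motif_features("G" * 60)
        assert f["tm_count"] == 0.0
        assert f["tat_motif"] == 0.0

    def test_two_disjoint_segments(self):
        # strongly hydrophilic spacers so no spanning window qualifies
        seq = "D" * 19 + "L" * 19 + "D" * 19 + "I" * 19 + "D" * 19
        assert membrane_motif_features(seq)["tm_count"] == 2.0

    def test_alternation_raises_barrel_score(self):
        alternating = "LS" * 20
        uniform = "L" * 40
        assert (membrane_motif_features(alternating)["beta_barrel_propensity"]
                > membrane_motif_features(uniform)["beta_barrel_propensity"])


# --- glycosylation --------------------------------------------------------


class TestGlycosylation:
    @pytest.mark.parametrize("seq,count", [("NAS", 1), ("NPS", 0), ("NASNAT", 2)])
    def test_sequon_counts(self, seq, count):
        assert glycosylation_features(seq)["sequon_count"] == count

    def test_overlapping_sequons(self):
        # NNSS: N0-N-S yes, N1-S-S yes
        assert glycosylation_features("NNSS")["sequon_count"] == 2

    def test_st_density(self):
        assert glycosylation_features("STGG")["st_density"] == pytest.approx(0.5)


# --- CTD ------------------------------------------------------------------


class TestCTD:
    def test_homopolymer(self):
        f = ctd_features("K" * 10)
        # K is group 1 of the charge partition
        assert f["ctd_charge_comp_g1"] == 1.0
        assert f["ctd_charge_comp_g2"] == 0.0
        assert f["ctd_charge_trans_12"] == 0.0
        assert f["ctd_charge_trans_13"] == 0.0

    def test_alternating_transition(self):
        # K (positive group) / D (negative group) alternation: every adjacent
        # pair is a 1<->3 transition
        f = ctd_features("KDKDKD")
        assert f["ctd_charge_trans_13"] == pytest.approx(1.0)

    @given(seq=SEQUENCES)
    @settings(max_examples=30, deadline=None)
    def test_composition_triplets_sum_to_one(self, seq):
        f = ctd_features(seq)
        from uriexc.features.tables import CTD_PROPERTIES

        for prop in CTD_PROPERTIES:
            total = sum(f[f"ctd_{prop}_comp_g{g}"] for g in (1, 2, 3))
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_distribution_hand_check(self):
        # "KKKKK": group 1 occupies every position; quantile positions are
        # 1,2,3,4,5 normalized by 5
        f = ctd_features("KKKKK")
        assert f["ctd_charge_dist_g1_first"] == pytest.approx(0.2)
        assert f["ctd_charge_dist_g1_q50"] == pytest.approx(0.6)
        assert f["ctd_charge_dist_g1_last"] == pytest.approx(1.0)

    def test_short_sequence_distribution_zero(self):
        f = ctd_features("KDK")
        assert f["ctd_charge_dist_g1_first"] == 0.0


# --- full vector ----------------------------------------------------------


class TestFeatureVector:
    def test_dimension_243(self, registry):
        v = compute_feature_vector(ProteinRecord("P", "MKWVTFISLLLLFSSAYS"), registry)
        assert v.shape == (243,)

    def test_deterministic(self, registry):
        a = compute_feature_vector(ProteinRecord("P", "MKWVTFISLLLLFSSAYS"), registry)
        b = compute_feature_vector(ProteinRecord("P", "MKWVTFISLLLLFSSAYS"), registry)
        assert np.array_equal(a, b)

    def test_single_residue_perturbation_changes_vector(self, registry):
        base = "MKWVTFISLLLLFSSAYSAMKWVTFISLLL"
        mutated = base[:10] + "W" + base[11:]
        a = compute_feature_vector(ProteinRecord("P", base), registry)
        b = compute_feature_vector(ProteinRecord("P", mutated), registry)
        assert not np.array_equal(a, b)

    @given(seq=SEQUENCES)
    @settings(max_examples=25, deadline=None)
    def test_always_finite(self, registry, seq):
        v = compute_feature_vector(ProteinRecord("P", seq), registry)
        assert np.all(np.isfinite(v))

    def test_long_sequence(self, registry, rng):
        from conftest import random_sequence

        seq = random_sequence(rng, 10_000)
        v = compute_feature_vector(ProteinRecord("P", seq), registry)
        assert v.shape == (243,) and np.all(np.isfinite(v))

    def test_length_one(self, registry):
        v = compute_feature_vector(ProteinRecord("P", "M"), registry)
        assert v.shape == (243,) and np.all(np.isfinite(v))

    def test_registry_metadata(self, registry):
        assert registry.dimension == 243
        indices = [d.index for d in registry.descriptors]
        assert indices == list(range(243))
        assert len({d.name for d in registry.descriptors}) == 243

    def test_registry_json_roundtrip(self, registry, tmp_path):
        import json

        registry.to_json(tmp_path / "reg.json")
        payload = json.loads((tmp_path / "reg.json").read_text())
        assert payload["dimension"] == 243
        assert payload["descriptors"][0]["index"] == 0
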