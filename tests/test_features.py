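import numpy as np
import pytest

from loopscreen.features import (
    DEFAULT_MANIFEST,
    FINGERPRINT_BITS,
    INTERACTION_FEATURE_DIM,
    RNA_FEATURE_DIM,
    FeatureError,
    FeatureManifest,
    interaction_features,
    molecule_fingerprint,
    rna_feature_vector,
    rna_global_features,
    rna_structure_features,
)
from loopscreen.sequences import RnaSequence, join_interaction
from loopscreen.structure import parse_dotbracket


def _seq(bases, id="x"):
    return RnaSequence(id=id, bases=bases)


class TestGlobalFeatures:
    def test_gc_and_mono_ratios(self):
        g = rna_global_features(_seq("GGCC"))
        assert g["gc_content"] == pytest.approx(1.0)
        assert [g["mono_ratio"][b] for b in "ACGU"] == [0.0, 0.5, 0.5, 0.0]

    def test_uniform_sequence_ratios(self):
        g = rna_global_features(_seq("ACGU"))
        assert all(v == pytest.approx(0.25) for v in g["mono_ratio"].values())
        observed = {d: r for d, r in g["di_ratio"].items() if r > 0}
        assert observed == {
            "AC": pytest.approx(1 / 3),
            "CG": pytest.approx(1 / 3),
            "GU": pytest.approx(1 / 3),
        }

    def test_dinucleotide_ratios_match_sliding_counter(self, random_sequences):
        for seq in random_sequences(10, 10, 30, seed=51):
            g = rna_global_features(seq)
            counts = {}
            for p in range(len(seq) - 1):
                w = seq.bases[p : p + 2]
                counts[w] = counts.get(w, 0) + 1
            total = sum(counts.values())
            assert sum(g["di_ratio"].values()) == pytest.approx(1.0)
            for w, c in counts.items():
                assert g["di_ratio"][w] == pytest.approx(c / total)

    def test_linker_excluded_from_counts(self):
        with_linker = rna_global_features(_seq("GGCCNNNN"))
        plain = rna_global_features(_seq("GGCC"))
        assert with_linker["length"] == plain["length"]
        assert with_linker["gc_content"] == plain["gc_content"]

    def test_all_linker_rejected(self):
        with pytest.raises(FeatureError):
            rna_global_features(_seq("NNNN"))


class TestStructureFeatures:
    def test_all_unpaired_structure(self):
        seq = _seq("ACGUACGUA")
        f = rna_structure_features(seq, parse_dotbracket("........."))
        assert f["bp_count"] == 0
        assert all(v == 0 for v in f["window_bp_density"].values())
        assert f["unpaired_fraction"] == pytest.approx(1.0)

    def test_stacked_hairpin_counts(self):
        seq = _seq("GGGAAACCC")
        f = rna_structure_features(seq, parse_dotbracket("(((...)))"))
        assert f["bp_count"] == 3
        assert f["loop_class_count"]["hairpin"] == 1
        assert f["loop_class_count"]["bulge"] == 0
        assert f["loop_class_count"]["stack"] == 2

    def test_windowed_densities_bounded(self, random_sequences):
        from loopscreen.fold import fold_mfe

        for seq in random_sequences(6, 10, 30, seed=52):
            f = rna_structure_features(seq, fold_mfe(seq))
            assert all(0.0 <= v <= 1.0 for v in f["window_bp_density"].values())

    def test_length_mismatch_rejected(self):
        with pytest.raises(FeatureError):
            rna_structure_features(_seq("ACGU"), parse_dotbracket("....."))


class TestFeatureVector:
    def test_default_manifest_has_226_entries(self):
        assert len(DEFAULT_MANIFEST) == RNA_FEATURE_DIM

    def test_vector_matches_manifest_length(self):
        vec = rna_feature_vector(_seq("GCGCAAAAAGCGC"))
        assert len(vec) == RNA_FEATURE_DIM
        assert np.isfinite(vec.values).all()

    def test_ratio_groups_normalized(self):
        vec = rna_feature_vector(_seq("GCGCAAAAAGCGCAU"))
        by_extractor = {}
        for spec, v in zip(DEFAULT_MANIFEST.entries, vec.values):
            by_extractor.setdefault(spec.extractor, []).append(v)
        for group in ("mono_ratio", "di_ratio", "tri_ratio", "state_mono_ratio", "state_di_ratio"):
            assert sum(by_extractor[group]) == pytest.approx(1.0, abs=1e-9)

    def test_deterministic_for_identical_interactions(self):
        mi = RnaSequence(id="mi", bases="GGGGGAAAAA", kind="miRNA")
        site = RnaSequence(id="s", bases="UUUUUCCCCC")
        v1 = rna_feature_vector(join_interaction(mi, site))
        v2 = rna_feature_vector(join_interaction(mi, site))
        assert np.array_equal(v1.values, v2.values)

    def test_permuted_manifest_permutes_values(self):
        seq = _seq("GCGCAAAAAGCGC")
        base = rna_feature_vector(seq)
        permuted = FeatureManifest(entries=DEFAULT_MANIFEST.entries[::-1], version="perm")
        vec = rna_feature_vector(seq, manifest=permuted)
        assert np.array_equal(vec.values, base.values[::-1])

    def test_manifest_round_trips_through_table(self):
        frame = DEFAULT_MANIFEST.to_frame()
        back = FeatureManifest.from_frame(frame)
        assert back.entries == DEFAULT_MANIFEST.entries


class TestFingerprint:
    def test_smiles_spellings_give_identical_bits(self):
        a = molecule_fingerprint("CCO")
        b = molecule_fingerprint("OCC")
        assert np.array_equal(a.bits, b.bits)
        assert a.smiles_canonical == b.smiles_canonical

    def test_bit_vector_length(self):
        fp = molecule_fingerprint("c1ccccc1O")
        assert len(fp) == FINGERPRINT_BITS
        assert set(np.unique(fp.bits)) <= {0.0, 1.0}

    def test_unparseable_smiles_flagged_with_record(self):
        with pytest.raises(FeatureError) as err:
            molecule_fingerprint("not_a_smiles", record_id="MOL007")
        assert err.value.record_id == "MOL007"


class TestInteractionVector:
    def test_joined_dimension_is_1250(self):
        vec = interaction_features(_seq("GCGCAAAAAGCGC"), "CCO")
        assert len(vec) == INTERACTION_FEATURE_DIM

    def test_rna_block_leads(self):
        vec = interaction_features(_seq("GCGCAAAAAGCGC"), "CCO")
        assert np.array_equal(vec.joined[:RNA_FEATURE_DIM], vec.rna.values)
        assert np.array_equal(vec.joined[RNA_FEATURE_DIM:], vec.molecule.bits)

    def test_degenerate_manifest_supported(self):
        tiny = FeatureManifest(entries=DEFAULT_MANIFEST.entries[:2], version="tiny")
        vec = interaction_features(_seq("GCGCAAAAAGCGC"), "CCO", manifest=tiny)
        assert len(vec) == 2 + FINGERPRINT_BITS
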