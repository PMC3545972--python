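"""The 46-dimensional feature encoder."""

import numpy as np
import pytest

from premir.features import (
    FEATURE_NAMES,
    TRIPLET_CODES,
    FeatureError,
    FeatureVector,
    encode,
    mfe_features,
    pairing_features,
    structural_features,
    triplet_features,
)
from premir.fold import SecondaryStructure, fold, parse_anatomy
from premir.synth import FixtureSpec, make_hairpin


class TestMfeFeatures:
    def test_hand_worked_example(self):
        nmfe, nmfei, namfe = mfe_features(-30.0, 90, 50.0)
        assert nmfe == pytest.approx(0.03)
        assert nmfei == pytest.approx(0.66667 / 10, abs=1e-5)  # MFEI = 0.6667
        assert namfe == pytest.approx(3.3333, abs=1e-4)

    def test_zero_energy_gives_zero_features(self):
        assert mfe_features(0.0, 90, 50.0) == (0.0, 0.0, 0.0)

    def test_mfei_unit_value(self):
        # MFEI = (-100 * -45 / 90) / 50 = 1.0
        _, nmfei, _ = mfe_features(-45.0, 90, 50.0)
        assert nmfei == pytest.approx(0.1)

    def test_zero_gc_is_an_error(self):
        with pytest.raises(FeatureError):
            mfe_features(-30.0, 90, 0.0)


class TestPairingFeatures:
    def test_hand_counted_helix(self):
        anatomy = parse_anatomy("((((....))))")
        nnnb, nannb, nnns, ngc = pairing_features(anatomy, "GGGGAAAACCCC")
        assert nnnb == pytest.approx(0.004)
        assert nannb == pytest.approx(4 / 12)
        assert nnns == pytest.approx(0.5)
        assert ngc == pytest.approx(0.008)

    def test_unpaired_sequence_degenerates_to_zero(self):
        anatomy = parse_anatomy("........")
        nnnb, nannb, nnns, _ = pairing_features(anatomy, "ACGUACGU")
        assert (nnnb, nannb, nnns) == (0.0, 0.0, 0.0)

    def test_annb_at_filter_lower_bound(self):
        anatomy = parse_anatomy("(" * 27 + "...." + ")" * 27 + "." * 32)
        _, nannb, _, _ = pairing_features(anatomy, "A" * 90)
        assert nannb == pytest.approx(0.3)


class TestStructuralFeatures:
    def _structure(self, **kw):
        defaults = dict(
            dotbracket="((((....))))", mfe=-5.0, mfe_freq=0.5, diversity=3.0, mean_bp_distance=1.0
        )
        defaults.update(kw)
        return SecondaryStructure(**defaults)

    def test_balanced_a_u_counts_give_zero(self):
        anatomy = parse_anatomy("((((....))))")
        vals = structural_features(self._structure(), anatomy, "AUAUGGCCAUAU")
        assert vals[4] == 0.0  # N(|A-U|/LS)

    def test_no_internal_loops_means_zero_interloop(self):
        anatomy = parse_anatomy("((((....))))")
        vals = structural_features(self._structure(), anatomy, "GGGGAAAACCCC")
        assert vals[3] == 0.0

    def test_symmetry_scalings(self):
        anatomy = parse_anatomy("((((....))))")
        vals = structural_features(self._structure(), anatomy, "GGGGAAAACCCC")
        assert vals[6] == pytest.approx(0.04)  # l_sym = 4
        assert vals[5] == pytest.approx(0.04)

    def test_missing_ensemble_quantity_named_in_error(self):
        bare = SecondaryStructure("((((....))))", -5.0)
        with pytest.raises(FeatureError, match="mfe_freq"):
            structural_features(bare, parse_anatomy("((((....))))"), "GGGGAAAACCCC")


class TestTripletFeatures:
    def test_hand_counted_perfect_helix(self):
        v = triplet_features("GGGGAAAACCCC", "((((....))))")
        nonzero = {c: x for c, x in zip(TRIPLET_CODES, v) if x}
        assert nonzero == {"G(((": pytest.approx(0.5), "C(((": pytest.approx(0.5)}

    def test_normalisation(self):
        v = triplet_features("GCGCGAAAACGCGC", "(((((....)))))")
        assert v.sum() == pytest.approx(1.0)
        assert (v >= 0).all()

    def test_degenerate_stem_is_all_zero(self):
        v = triplet_features("GAAAC", "(...)")
        assert v.sum() == 0.0

    def test_terminal_loop_and_tails_excluded(self):
        # windows never span the loop: with 3-bp arms only 1 window per arm
        v = triplet_features("AAGGGUUUUCCCAA", "..(((....)))..")
        nonzero = {c: x for c, x in zip(TRIPLET_CODES, v) if x}
        assert nonzero == {"G(((": pytest.approx(0.5), "C(((": pytest.approx(0.5)}

    def test_alphabet_closure_on_folded_hairpin(self):
        rec = make_hairpin(FixtureSpec(seed=5, stem_bp=28, loop_len=6, n_bulges=2))
        s = fold(rec.seq)
        v = triplet_features(rec.seq, s.dotbracket)
        assert len(v) == 32 and v.sum() == pytest.approx(1.0)


class TestEncode:
    def test_feature_contract(self):
        rec = make_hairpin(FixtureSpec(seed=7))
        s = fold(rec.seq)
        fv = encode(rec.seq, s, parse_anatomy(s.dotbracket))
        assert len(fv) == 46
        assert fv.names == FEATURE_NAMES
        assert np.isfinite(fv.values).all()

    def test_deterministic(self):
        rec = make_hairpin(FixtureSpec(seed=8))
        s = fold(rec.seq)
        a = encode(rec.seq, s, parse_anatomy(s.dotbracket))
        b = encode(rec.seq, s, parse_anatomy(s.dotbracket))
        assert np.array_equal(a.values, b.values)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            FeatureVector(np.zeros(45))

    def test_scale_convention_on_random_windows(self, rng):
        """For 90-nt windows with MFE >= -100, every feature sits in [0, 10.2]."""
        lo = np.inf
        hi = -np.inf
        for _ in range(300):
            seq = "".join(rng.choice(list("ACGU"), 90))
            s = fold(seq)
            fv = encode(seq, s, parse_anatomy(s.dotbracket))
            lo, hi = min(lo, fv.values.min()), max(hi, fv.values.max())
        assert lo >= 0.0 and hi <= 10.2
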