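import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import herbnet as h
from herbnet.annotate import NEUTRAL_LOSSES, Tolerance

BAOHUOSIDE = h.CompoundRecord("baohuoside VI", "C39H50O19")
AKEBIASAPONIN = h.CompoundRecord("akebiasaponin D", "C47H76O18")
LOSS = {l.label: l for l in NEUTRAL_LOSSES}


def feature(mz, polarity="+", rt=15.37):
    return h.MSFeature(rt=rt, mz=mz, response=1.0, polarity=polarity)


@pytest.mark.parametrize(
    "obs,theo,expected",
    [
        (823.3022, 823.301911, 0.35),
        (927.4931, 927.495890, -3.0),
        (500.0, 500.0, 0.0),
    ],
)
def test_ppm_error(obs, theo, expected):
    assert h.ppm_error(obs, theo) == pytest.approx(expected, abs=0.05)


class TestMatching:
    def test_worked_positive_ion(self):
        """The observed ion at m/z 823.3022 annotates to C39H50O19 [M+H]+."""
        matches = h.match_features([feature(823.3022)], [BAOHUOSIDE, AKEBIASAPONIN])
        assert len(matches) == 1
        m = matches[0]
        assert (m.compound, m.adduct) == ("baohuoside VI", "[M+H]+")
        assert abs(m.error_mda) < 0.5

    def test_worked_negative_ion(self):
        matches = h.match_features(
            [feature(927.4931, polarity="-")], [BAOHUOSIDE, AKEBIASAPONIN]
        )
        assert [(m.compound, m.adduct) for m in matches] == [
            ("akebiasaponin D", "[M-H]-")
        ]
        assert abs(matches[0].error_mda) <= 5.0

    def test_out_of_tolerance(self):
        assert h.match_features([feature(830.0)], [BAOHUOSIDE]) == []

    def test_boundary_is_inclusive(self):
        """An error of exactly 5.000 mDa is still a match."""
        theo = h.adduct_mz(h.formula_mass("C39H50O19"), "[M+H]+")
        matches = h.match_features([feature(theo + 5.000e-3)], [BAOHUOSIDE])
        assert len(matches) == 1
        # 10 ppm boundary, on a mass where 10 ppm > 5 mDa
        small = h.CompoundRecord("tiny", "C6H10O5")
        theo2 = h.adduct_mz(h.formula_mass("C6H10O5"), "[M+H]+")
        hi = theo2 * (1 + 10e-6)
        assert len(h.match_features([feature(hi)], [small])) == 1

    def test_empty_library_warns_not_raises(self, caplog):
        with caplog.at_level("WARNING"):
            assert h.match_features([feature(823.3)], []) == []
        assert any("empty" in r.message for r in caplog.records)

    def test_sorted_by_error_with_name_tiebreak(self):
        # two isobaric entries: same formula, different names
        lib = [
            h.CompoundRecord("zeta", "C39H50O19"),
            h.CompoundRecord("alpha", "C39H50O19"),
        ]
        matches = h.match_features([feature(823.3022)], lib)
        assert [m.compound for m in matches] == ["alpha", "zeta"]

    def test_permutation_invariance(self):
        lib = [BAOHUOSIDE, AKEBIASAPONIN, h.CompoundRecord("x", "C20H22O8")]
        feats = [feature(823.3022), feature(927.4931, polarity="-")]
        a = h.match_features(feats, lib)
        b = h.match_features(feats, lib[::-1])
        assert [(m.compound, m.adduct) for m in a] == [(m.compound, m.adduct) for m in b]


@given(
    masses=st.lists(st.floats(min_value=150, max_value=1200), min_size=1, max_size=8),
    offset=st.floats(min_value=-20e-3, max_value=20e-3),
)
@settings(max_examples=100, deadline=None)
def test_every_match_is_within_tolerance(masses, offset):
    """Whatever the library, emitted matches satisfy the tolerance invariant."""
    lib = [
        h.CompoundRecord(f"c{i}", h.format_formula({"C": 10 + i, "H": 12, "O": 4}))
        for i in range(len(masses))
    ]
    feats = [feature(m + offset) for m in masses]
    tol = Tolerance()
    for m in h.match_features(feats, lib):
        assert (
            abs(m.error_mda) <= tol.mda
            or abs(m.error_ppm) <= tol.ppm
        )


class TestFragments:
    def test_worked_fragments_positive(self):
        """Fragments of protonated baohuoside VI: -rha and -2rha."""
        theo = h.adduct_mz(h.formula_mass("C39H50O19"), "[M+H]+")
        out = h.annotate_fragments(theo, [677.2438, 531.1860])
        assert out[0].losses == ("rha",)
        assert out[0].label == "-rha"
        assert out[1].losses == ("rha", "rha")
        assert out[1].label == "-2rha"
        assert all(a.error_mda < 1.0 for a in out)

    def test_worked_fragments_negative(self):
        """Fragment of deprotonated akebiasaponin D: loss of two glucoses."""
        theo = h.adduct_mz(h.formula_mass("C47H76O18"), "[M-H]-")
        (a,) = h.annotate_fragments(theo, [603.3904])
        assert a.losses == ("Glc", "Glc")

    def test_mixed_loss_fragment(self):
        """m/z 369.1328 = [M+H - Glc - 2rha]+ for baohuoside VI."""
        theo = h.adduct_mz(h.formula_mass("C39H50O19"), "[M+H]+")
        (a,) = h.annotate_fragments(theo, [369.1328])
        assert a.losses == ("Glc", "rha", "rha")

    def test_unexplained_fragment(self):
        theo = h.adduct_mz(h.formula_mass("C39H50O19"), "[M+H]+")
        losses = [LOSS["rha"], LOSS["Glc"]]
        (a,) = h.annotate_fragments(theo, [500.0], losses=losses)
        assert a.losses is None and a.label == ""

    def test_loss_multiplicity_cap(self):
        rha = LOSS["rha"]
        theo = 2000.0
        frag = theo - 5 * rha.mass  # would need five rha, above the per-label cap
        (a,) = h.annotate_fragments(theo, [frag], losses=[rha], max_losses=6)
        assert a.losses is None


def test_annotation_recovery_with_mass_noise():
    """>= 95% of features regain their source compound at sigma = 1 mDa."""
    cfg = h.GeneratorConfig(seed=42, mz_noise_mda=1.0)
    lib, feats, gt = h.gen_library_and_features(cfg)
    matches = h.match_features(feats, lib)
    best = {}
    for m in matches:  # matches are error-sorted; keep the best per feature
        best.setdefault(id(m.feature), m)
    correct = sum(
        1
        for f, src in zip(feats, gt.feature_sources)
        if id(f) in best and best[id(f)].compound == src["compound"]
    )
    assert correct / len(feats) >= 0.95
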