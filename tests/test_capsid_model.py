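import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capsidms import masscalc as mc
from capsidms.capsid_model import (
    ComponentLibrary,
    ConfigurationError,
    DefinitionError,
    SerotypeDefinition,
    apply_nterm_processing,
    build_component_library,
    derive_vp_sequences,
    dump_serotype_definitions,
    load_serotype_definitions,
)
from capsidms.synth import make_test_serotype

# A definition shaped like the AAV2 layout: mature positions 202 and 210 are
# Met, VP3 starts with the ATGSGAPM motif at 203.  Filler is inert (G/S).
_VP3_MOTIF = "ATGSGAPM"


def layout_definition(total=734, vp2_start=138, vp3_start=203, variant=211):
    filler = "GS" * 400
    mature = list(filler[: total])
    mature[0] = "A"
    mature[vp3_start - 2] = "M"
    for i, r in enumerate(_VP3_MOTIF):
        mature[vp3_start - 1 + i] = r  # also places M right before the variant
    mature[variant - 1] = "A"
    seq = "".join(mature)
    assert seq[variant - 2] == "M"
    return SerotypeDefinition(
        name="layout",
        vp1_sequence="M" + seq,
        vp2_start=vp2_start,
        vp3_start=vp3_start,
        variant_starts=(variant,),
    )


class TestDeriveVpSequences:
    def test_vp3_starts_with_motif_after_processing(self):
        d = layout_definition()
        chains = derive_vp_sequences(d)
        assert chains["VP3"].startswith("M" + _VP3_MOTIF)
        processed, acetyl = apply_nterm_processing(chains["VP3"], d.nterm_rule)
        assert processed.startswith(_VP3_MOTIF)
        assert acetyl

    def test_variant_chain_present(self):
        d = layout_definition()
        chains = derive_vp_sequences(d)
        assert "A211-VP3" in chains
        assert chains["A211-VP3"][0] == "M"

    def test_vp2_start_one_gives_mature_vp1(self):
        d = SerotypeDefinition(
            name="t", vp1_sequence="MAWDEFGHIKL", vp2_start=1, vp3_start=5
        )
        chains = derive_vp_sequences(d)
        assert chains["VP2"] == d.mature_sequence

    def test_toy_lengths(self):
        d = SerotypeDefinition(
            name="toy", vp1_sequence="WADEFGHIKL", vp2_start=3, vp3_start=5
        )
        chains = derive_vp_sequences(d)
        assert [len(chains[v]) for v in ("VP1", "VP2", "VP3")] == [10, 8, 6]

    def test_start_beyond_length_rejected(self):
        with pytest.raises(DefinitionError):
            SerotypeDefinition(
                name="bad", vp1_sequence="WADEFG", vp2_start=3, vp3_start=9
            )

    def test_unordered_starts_rejected(self):
        with pytest.raises(DefinitionError):
            SerotypeDefinition(
                name="bad", vp1_sequence="WADEFGHIKL", vp2_start=5, vp3_start=3
            )

    def test_non_canonical_sequence_rejected(self):
        with pytest.raises(DefinitionError):
            SerotypeDefinition(
                name="bad", vp1_sequence="WADEXGHIKL", vp2_start=3, vp3_start=5
            )

    @given(seed=st.integers(min_value=0, max_value=50))
    @settings(max_examples=20, deadline=None)
    def test_suffix_property(self, seed):
        d = make_test_serotype("s", seed=seed, variant_start=200)
        mature = d.mature_sequence
        chains = derive_vp_sequences(d)
        for name, chain in chains.items():
            if name == "VP1":
                continue
            assert mature.endswith(chain)
            assert mature[len(mature) - len(chain) :] == chain


class TestNTermProcessing:
    def test_vp1_like(self):
        processed, acetyl = apply_nterm_processing("MAADGYLPDWLED")
        assert processed == "AADGYLPDWLED"
        assert acetyl

    def test_vp3_like(self):
        processed, acetyl = apply_nterm_processing("MATGSGAPM")
        assert processed == "ATGSGAPM"
        assert acetyl

    def test_bulky_position2_not_cleaved(self):
        processed, acetyl = apply_nterm_processing("MWDEF")
        assert processed == "MWDEF"
        assert not acetyl

    def test_no_met_start_untouched(self):
        processed, acetyl = apply_nterm_processing("TAPGKK")
        assert processed == "TAPGKK"
        assert not acetyl

    def test_forced_acetylation(self):
        _, acetyl = apply_nterm_processing(
            "TAPGKK", {"cleave_met", "acetylate_always"}
        )
        assert acetyl

    def test_empty_sequence_rejected(self):
        with pytest.raises(DefinitionError):
            apply_nterm_processing("")

    @given(
        seq=st.text(
            alphabet=sorted(mc.CANONICAL_RESIDUES), min_size=1, max_size=30
        )
    )
    def test_idempotence(self, seq):
        once, ac1 = apply_nterm_processing(seq)
        twice, ac2 = apply_nterm_processing(once)
        assert twice == once
        # a cleaved chain never re-cleaves, so the second pass adds nothing
        assert not ac2 or not ac1 or once == seq


class TestBuildComponentLibrary:
    def test_empty_specs_empty_library(self, panel_definitions):
        lib = build_component_library(panel_definitions, proteoform_specs=[])
        assert lib.all_components() == []

    def test_four_serotypes_twelve_components(self, panel_library):
        comps = panel_library.all_components()
        assert len(comps) == 12
        for serotype in panel_library.serotypes():
            labels = [c.label for c in panel_library.entries[serotype]]
            assert len(labels) == len(set(labels))

    def test_rt_window_defaults(self, panel_library):
        for c in panel_library.all_components():
            expected = 0.60 if c.base_vp in ("VP1", "VP2") else 1.00
            assert c.rt_window == expected

    def test_unknown_vp_listed_in_error(self, panel_definitions):
        with pytest.raises(ConfigurationError, match="VP9"):
            build_component_library(
                panel_definitions, proteoform_specs=[("VP9", {})]
            )

    def test_unknown_ptm_listed_in_error(self, panel_definitions):
        with pytest.raises(ConfigurationError, match="glycation"):
            build_component_library(
                panel_definitions, proteoform_specs=[("VP3", {"glycation": 1})]
            )

    def test_printed_mass_table_reproduced_with_overrides(self):
        """Pinned per-VP theoretical masses propagate through PTM arithmetic."""
        d = layout_definition()
        overrides = {
            "VP1": 81854.90,
            "VP2": 66487.90,
            "VP3": 59973.78,
            "A211-VP3": mc.truncation_mass(59973.78, _VP3_MOTIF),
        }
        lib = build_component_library(
            [d],
            proteoform_specs=[
                ("VP1", {}),
                ("VP2", {}),
                ("VP3", {}),
                ("VP3", {"oxidation": 1}),
                ("A211-VP3", {}),
            ],
            mass_overrides=overrides,
        )
        masses = {c.label: c.theoretical_mass for c in lib.all_components()}
        assert len(masses) == 5
        expected = {
            "VP1": 81854.90,
            "VP2": 66487.90,
            "VP3 unmod": 59973.78,
            "VP3 ox": 59989.78,
            "A211": 59301.03,
        }
        by_value = sorted(masses.values())
        assert by_value == pytest.approx(
            sorted(expected.values()), abs=0.02
        )

    def test_mass_ordering(self, panel_library, panel_definitions):
        for d in panel_definitions:
            comps = {
                c.base_vp: c.theoretical_mass
                for c in panel_library.entries[d.name]
            }
            assert comps["VP1"] > comps["VP2"] > comps["VP3"]

    def test_variant_lighter_than_vp3(self):
        d = layout_definition()
        lib = build_component_library(
            [d], proteoform_specs=[("VP3", {}), ("A211-VP3", {})]
        )
        masses = {c.base_vp: c.theoretical_mass for c in lib.all_components()}
        assert masses["VP3"] > masses["A211-VP3"]

    def test_duplicate_labels_rejected(self, panel_definitions):
        with pytest.raises(ConfigurationError, match="duplicate"):
            build_component_library(
                panel_definitions[:1],
                proteoform_specs=[("VP3", {}), ("VP3", {})],
            )


class TestRoundTrips:
    def test_definitions_yaml(self, tmp_path, panel_definitions):
        path = tmp_path / "defs.yaml"
        dump_serotype_definitions(panel_definitions, path)
        loaded = load_serotype_definitions(path)
        assert loaded == panel_definitions

    def test_library_yaml(self, tmp_path, panel_library):
        path = tmp_path / "lib.yaml"
        panel_library.to_yaml(path)
        loaded = ComponentLibrary.from_yaml(path)
        assert loaded.to_dict() == panel_library.to_dict()
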