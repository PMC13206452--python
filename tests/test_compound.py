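import math

import pytest
from hypothesis import given, strategies as st

from pbpkddi.compound import (
    ClearanceSpec,
    CompoundModel,
    InteractionEntry,
    InvalidParameterError,
    PhysChem,
    TransporterKinetics,
    builtin_linezolid,
    builtin_rifampin,
    derive_kcat,
    derive_vmax,
)
from pbpkddi.io import compound_from_flat, compound_to_flat, load_compound, save_compound


class TestDerivations:
    @pytest.mark.parametrize(
        "clint, km, expected",
        [
            (16.0, 100.0, 1600.0),  # ABCG2 assay values
            (0.0, 100.0, 0.0),
            (2.1, 100.0, 210.0),  # ABCB1 assay values
        ],
    )
    def test_vmax_from_assay_clearance(self, clint, km, expected):
        assert derive_vmax(clint, km) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "vmax, abundance, expected",
        [
            (1600.0, 13.18, 121.3960546282246),
            (0.0, 10.0, 0.0),
            (210.0, 10.3, 20.388349514563107),
        ],
    )
    def test_kcat_per_transporter(self, vmax, abundance, expected):
        assert derive_kcat(vmax, abundance) == pytest.approx(expected, rel=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            derive_vmax(16.0, 0.0)
        with pytest.raises(InvalidParameterError):
            derive_kcat(1600.0, 0.0)
        with pytest.raises(InvalidParameterError):
            derive_vmax(-1.0, 100.0)

    @given(
        clint=st.floats(1e-3, 1e3),
        km=st.floats(1e-2, 1e4),
        abundance=st.floats(1e-2, 1e3),
    )
    def test_round_trip_equals_direct_arithmetic(self, clint, km, abundance):
        assert derive_kcat(derive_vmax(clint, km), abundance) == pytest.approx(
            clint * km / abundance, rel=1e-14
        )


class TestBuiltins:
    def test_victim_parameter_set(self):
        lzd = builtin_linezolid()
        pc = lzd.physchem
        assert (pc.molecular_weight, pc.logp, pc.pka) == (337.35, 0.55, 1.7)
        assert pc.compound_type == "monoprotic_base"
        assert pc.fu_plasma == 0.69
        assert pc.solubility_water == 3.0
        assert lzd.clearance.hepatic_plasma_cl == 0.65
        assert lzd.clearance.hepatic_cl_multiple_dose == 0.5
        b1 = lzd.transporter("ABCB1")
        g2 = lzd.transporter("ABCG2")
        assert (b1.kcat, b1.km, b1.reference_concentration) == (72.0, 51.0, 0.077)
        assert (g2.kcat, g2.km, g2.reference_concentration) == (720.0, 53.0, 0.025)
        assert lzd.intestinal_permeability == 9e-6
        assert lzd.organ_permeability == 9e-4
        assert lzd.interactions == ()

    def test_perpetrator_interaction_constants(self):
        rif = builtin_rifampin()
        ind = {
            e.target_transporter: e
            for e in rif.interaction_entries(mechanism="induction")
        }
        assert ind["ABCB1"].emax == 2.5 and ind["ABCB1"].ec50 == 0.34
        assert ind["ABCB1"].applies_to == "victim"
        assert ind["OATP1B1"].emax == 0.383 and ind["OATP1B1"].applies_to == "self"
        assert ind["AADAC"].emax == 0.985 and ind["AADAC"].ec50 == 0.34
        inh = {
            e.target_transporter: e.ki
            for e in rif.interaction_entries(mechanism="competitive_inhibition")
        }
        assert inh == {"ABCB1": 9.1, "ABCG2": 14.0}
        (fold,) = rif.interaction_entries(mechanism="static_fold")
        assert fold.target_transporter == "ABCG2" and fold.fold == 1.5

    def test_clearance_switch_selects_multiple_dose_value(self):
        clr = builtin_linezolid().clearance
        assert clr.for_regimen(1) == 0.65
        assert clr.for_regimen(14) == 0.5


class TestValidation:
    def test_unbound_fraction_bounds(self):
        with pytest.raises(InvalidParameterError):
            PhysChem(molecular_weight=300.0, logp=1.0, fu_plasma=1.2)

    def test_multiple_dose_clearance_cannot_exceed_single(self):
        with pytest.raises(InvalidParameterError):
            ClearanceSpec(hepatic_plasma_cl=0.5, hepatic_cl_multiple_dose=0.65)

    def test_duplicate_transporter_rejected(self):
        kin = TransporterKinetics("ABCB1", 72.0, 51.0, 0.077)
        with pytest.raises(InvalidParameterError):
            CompoundModel(
                name="x",
                physchem=PhysChem(molecular_weight=300.0, logp=1.0),
                clearance=ClearanceSpec(hepatic_plasma_cl=1.0),
                transporters=(kin, kin),
            )

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(mechanism="induction", emax=2.5),  # missing ec50
            dict(mechanism="competitive_inhibition"),  # missing ki
            dict(mechanism="static_fold", fold=0.0),
            dict(mechanism="osmosis"),
        ],
    )
    def test_interaction_entry_validation(self, kwargs):
        with pytest.raises(InvalidParameterError):
            InteractionEntry(target_transporter="ABCB1", **kwargs)


class TestSerialization:
    @pytest.mark.parametrize("factory", [builtin_linezolid, builtin_rifampin])
    def test_flat_round_trip_is_lossless(self, factory):
        compound = factory()
        assert compound_from_flat(compound_to_flat(compound)) == compound

    def test_file_round_trip(self, tmp_path):
        path = tmp_path / "linezolid.cfg"
        save_compound(builtin_linezolid(), path)
        assert load_compound(path) == builtin_linezolid()
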