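"""The multi-state pumping cycle: ladder energies, pmf shifts, profile
serialization."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

import pcetpump as pp
from pcetpump import EXACT
from pcetpump.pump import COMPLEX_I_LABELS, ComplexIParams


class TestComplexILadder:
    def test_seventeen_states_in_canonical_order(self, ubiquinone_model):
        assert ubiquinone_model.labels == COMPLEX_I_LABELS

    @pytest.mark.parametrize(
        "state, expected",
        [
            ("IIa", 0.0),     # quinone reduction nearly isoenergetic
            ("IIb", -4.0),    # N-side uptake onto the pKa-10 cluster
            ("IIc", -16.0),   # 60% of the redox drop released by Q motion
            ("IIIa", -17.0),
            ("IVa", -18.0),
            ("Va", -19.0),
            ("IX", -19.0),    # cycle closure onto -nF dE
        ],
    )
    def test_state_energies_match_qualitative_ladder(
        self, ubiquinone_model, state, expected
    ):
        prof = pp.apply_pmf(ubiquinone_model, 0.0)
        assert prof[state] == pytest.approx(expected, abs=0.5)

    def test_rounded_rendering_reproduces_printed_integers(self, ubiquinone_model):
        prof = pp.apply_pmf(ubiquinone_model, 0.0).rounded()
        assert prof["IIb"] == -4
        assert prof["IIc"] == -16
        assert prof["Va"] == -19
        assert prof["IX"] == -19

    def test_menaquinone_end_state_near_minus_11(self, menaquinone_model):
        prof = pp.apply_pmf(menaquinone_model, 0.0)
        assert prof["IX"] == pytest.approx(-11.0, abs=0.5)

    def test_end_state_equals_redox_boundary(self, ubiquinone_model):
        assert ubiquinone_model.states[-1].dG0 == pytest.approx(
            pp.dg_from_redox(410.0, 2), abs=1e-9
        )

    def test_custom_partitioning_hand_summed(self):
        """Full Q-motion fraction and zero relay steps: IIc carries the
        whole uptake + redox drop, and closure still lands IX on
        -nF dE."""
        params = ComplexIParams(q_motion_fraction=1.0, relay_step_dg=0.0)
        model = pp.build_complex_i_model(params)
        prof = pp.apply_pmf(model, 0.0)
        uptake = pp.proton_transfer_dg(7.0, 10.0)
        redox = pp.dg_from_redox(410.0, 2)
        assert prof["IIc"] == pytest.approx(uptake + redox, abs=1e-9)
        assert prof["IX"] == pytest.approx(redox, abs=1e-9)

    @given(
        st.floats(min_value=0.2, max_value=1.0),
        st.floats(min_value=-2.0, max_value=0.0),
        st.floats(min_value=-150.0, max_value=150.0),
    )
    def test_closure_independent_of_partitioning(self, frac, relay, acceptor):
        params = ComplexIParams(
            q_motion_fraction=frac, relay_step_dg=relay, acceptor_em_mv=acceptor
        )
        model = pp.build_complex_i_model(params)
        expected = pp.dg_from_redox(acceptor + 320.0, 2)
        assert model.states[-1].dG0 == pytest.approx(expected, abs=1e-9)

    def test_explicit_final_step_checked_against_closure(self):
        implied = pp.build_complex_i_model().states[-1].dG0 - (
            pp.build_complex_i_model().state("VIIIb").dG0
        )
        pp.build_complex_i_model(ComplexIParams(final_step_dg=implied + 0.4))
        with pytest.raises(pp.ClosureError, match="cycle closure"):
            pp.build_complex_i_model(ComplexIParams(final_step_dg=implied + 2.0))

    def test_pumping_steps_nearly_isoenergetic(self, ubiquinone_model):
        """The Va -> VIIIb backwave zigzags +-~3 kcal/mol with no large
        net drop: the free energy was already spent by the power
        stroke."""
        prof = pp.apply_pmf(ubiquinone_model, 0.0)
        va = prof["Va"]
        labels = list(COMPLEX_I_LABELS)
        zigzag = labels[labels.index("Va"): labels.index("VIIIb") + 1]
        for s in zigzag:
            assert abs(prof[s] - va) <= 3.0
        assert abs(prof["VIIIb"] - va) <= 3.0

    def test_backwave_release_order_L_M_N_H(self, ubiquinone_model):
        releases = [
            t.mechanism
            for t in ubiquinone_model.transitions
            if "release to the P-side" in t.mechanism
        ]
        subunits = []
        for mech in releases:
            for tag in ("NuoL", "NuoM", "NuoN", "NuoH"):
                if tag in mech:
                    subunits.append(tag)
        assert subunits == ["NuoL", "NuoM", "NuoN", "NuoH"]

    def test_four_protons_translocated_per_cycle(self, ubiquinone_model):
        assert ubiquinone_model.total_translocated_charge == pytest.approx(4.0)

    def test_unknown_final_barrier_flagged(self, ubiquinone_model):
        last = ubiquinone_model.transitions[-1]
        assert last.source == "VIIIb" and last.target == "IX"
        assert last.barrier is None

    def test_missing_parameter_names_the_quantity(self):
        params = ComplexIParams(acceptor_em_mv=None)
        with pytest.raises(ValueError, match="acceptor_em_mv.*quinone"):
            pp.build_complex_i_model(params)


class TestApplyPmf:
    def test_zero_pmf_reproduces_dG0_exactly(self, ubiquinone_model):
        prof = pp.apply_pmf(ubiquinone_model, 0.0)
        for state, dg in zip(ubiquinone_model.states, prof.dG):
            assert dg == state.dG0

    def test_end_state_near_minus_one_at_200mV(self, ubiquinone_model):
        prof = pp.apply_pmf(ubiquinone_model, 200.0)
        assert prof["IX"] == pytest.approx(-1.0, abs=1.0)

    def test_four_full_translocations_cost_about_18(self, ubiquinone_model):
        p0 = pp.apply_pmf(ubiquinone_model, 0.0)
        p200 = pp.apply_pmf(ubiquinone_model, 200.0)
        assert p200["IX"] - p0["IX"] == pytest.approx(4 * 4.6, abs=0.2)

    def test_buried_site_states_shift_by_half(self, ubiquinone_model):
        p0 = pp.apply_pmf(ubiquinone_model, 0.0)
        p200 = pp.apply_pmf(ubiquinone_model, 200.0)
        assert p200["IIb"] - p0["IIb"] == pytest.approx(2.3, abs=0.05)

    @given(st.floats(min_value=-300.0, max_value=300.0))
    def test_shifts_linear_in_pmf(self, ubiquinone_model, pmf):
        half = pp.apply_pmf(ubiquinone_model, pmf / 2)
        full = pp.apply_pmf(ubiquinone_model, pmf)
        p0 = pp.apply_pmf(ubiquinone_model, 0.0)
        for s in full.labels:
            assert full[s] - p0[s] == pytest.approx(
                2 * (half[s] - p0[s]), abs=1e-9
            )

    def test_end_state_strictly_increasing_in_pmf(self, ubiquinone_model):
        values = [
            pp.apply_pmf(ubiquinone_model, pmf)["IX"] for pmf in range(0, 401, 25)
        ]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_negative_pmf_stabilizes(self, ubiquinone_model):
        assert pp.apply_pmf(ubiquinone_model, -100.0)["IX"] < (
            pp.apply_pmf(ubiquinone_model, 0.0)["IX"]
        )


class TestSingleSite:
    def test_passive_transfer_pKa8_at_zero_pmf(self):
        prof = pp.single_site_pump_profile(8.0)
        assert prof["bound"] == pytest.approx(EXACT.ln10_RT * (7 - 8), abs=1e-9)
        assert prof["bound"] == pytest.approx(-1.4, abs=0.1)
        assert prof["P-side"] == pytest.approx(0.0, abs=1e-12)

    def test_passive_transfer_pKa8_at_200mV(self):
        prof = pp.single_site_pump_profile(8.0, pmf_mv=200.0)
        bound = EXACT.ln10_RT * (7 - 8) + 0.5 * EXACT.faraday_kcal * 0.2
        assert prof["bound"] == pytest.approx(bound, abs=1e-9)
        assert prof["bound"] == pytest.approx(-1.4 + 2.3, abs=0.05)
        assert prof["P-side"] == pytest.approx(4.6, abs=0.05)

    def test_symmetric_pH_zero_pmf_no_driving_force(self):
        prof = pp.single_site_pump_profile(9.5, pH_N=7.4, pH_P=7.4)
        assert prof["P-side"] == 0.0

    def test_microsecond_steps_give_about_10_kcal_barriers(self):
        prof = pp.single_site_pump_profile(8.0, step_time=1e-6)
        assert prof.barriers_out[0] == pytest.approx(10.0, abs=0.5)

    def test_nonpositive_step_time_rejected(self):
        with pytest.raises(ValueError):
            pp.single_site_pump_profile(8.0, step_time=0.0)


class TestProfileIO:
    @pytest.mark.parametrize("suffix", [".tsv", ".json"])
    def test_round_trip(self, ubiquinone_model, tmp_path, suffix):
        prof = pp.apply_pmf(ubiquinone_model, 137.5)
        dest = tmp_path / f"profile{suffix}"
        pp.write_profile(prof, dest)
        back = pp.read_profile(dest)
        assert back.isclose(prof, tol=1e-12)
        assert back.spec == prof.spec

    def test_unknown_barriers_written_as_null_not_zero(
        self, ubiquinone_model, tmp_path
    ):
        prof = pp.apply_pmf(ubiquinone_model, 0.0)
        dest = tmp_path / "profile.tsv"
        pp.write_profile(prof, dest)
        rows = [
            line for line in dest.read_text().splitlines()
            if line.startswith("VIIIb\t")
        ]
        assert rows and rows[0].split("\t")[2] == "null"
        assert pp.read_profile(dest).barriers_out[-2] is None

    def test_first_row_is_reference_state(self, ubiquinone_model):
        df = pp.apply_pmf(ubiquinone_model, 0.0).to_frame()
        assert df.iloc[0]["dG_kcal_mol"] == 0.0
        assert df.iloc[0]["pmf_mV"] == 0.0


class TestModelValidation:
    def test_barrier_below_step_rejected(self):
        with pytest.raises(ValueError, match="barrier"):
            pp.PumpModel(
                states=(
                    pp.PumpState("a", 0.0),
                    pp.PumpState("b", 5.0),
                ),
                transitions=(pp.Transition("a", "b", 2.0),),
            )

    def test_nonzero_reference_state_rejected(self):
        with pytest.raises(ValueError, match="dG0 = 0"):
            pp.PumpModel(
                states=(pp.PumpState("a", 1.0), pp.PumpState("b", 0.0)),
                transitions=(pp.Transition("a", "b", 5.0),),
            )

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            pp.PumpModel(
                states=(pp.PumpState("a", 0.0), pp.PumpState("a", -1.0)),
                transitions=(pp.Transition("a", "a", 5.0),),
            )
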