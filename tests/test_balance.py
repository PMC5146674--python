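"""Electron-ledger construction, closure, and pathway fractions."""

import numpy as np
import pandas as pd
import pytest

from mecflux import (
    SimConfig,
    electron_balance,
    pathway_fraction,
    simulate_batch_cycle,
    sink_equivalents,
    time_course_fractions,
    undefined_from_percentages,
)
from mecflux.balance import charge_equivalents
from mecflux.stoichiometry import FARADAY


class TestSinkEquivalents:
    def test_methane_millimole(self):
        assert sink_equivalents(1e-3, "methane") == pytest.approx(8e-3)

    def test_charge_definition_of_faraday(self):
        assert charge_equivalents(96.485) == pytest.approx(1.0e-3, rel=1e-4)

    def test_zero_amount(self):
        assert sink_equivalents(0.0, "acetate") == 0.0

    def test_unknown_compound(self):
        with pytest.raises(KeyError):
            sink_equivalents(1.0, "unobtainium")

    def test_negative_amount_rejected(self):
        with pytest.raises(ValueError):
            sink_equivalents(-1.0, "methane")


class TestLedgerClosure:
    def test_published_style_closure(self):
        measured = {"current": 56.0, "methane": 28.7, "hydrogen": 0.05}
        assert undefined_from_percentages(measured) == pytest.approx(15.25)

    def test_all_electrons_as_charge_gives_zero_undefined(self, noiseless_sim):
        record = noiseless_sim.record
        consumed = record.donor_consumed_mol()
        charge = FARADAY * 14 * consumed
        # strip gas so charge is the only measured sink
        record_only_charge = type(record)(
            anode_volume_m3=record.anode_volume_m3,
            cycle_days=record.cycle_days,
            set_potential_V=record.set_potential_V,
            initial_mM=record.initial_mM,
            final_mM=record.final_mM,
            gas=[],
            trace=record.trace,
        )
        balance = electron_balance(record_only_charge, charge_C=charge, basis="consumed")
        assert balance.percent["current"] == pytest.approx(100.0)
        assert balance.percent["undefined"] == pytest.approx(0.0, abs=1e-9)

    def test_noise_free_simulation_recovers_configured_fractions(self, noiseless_sim):
        """Ground-truth charge + noise-free gas: percentages equal the
        configured routing to 1e-9."""
        cfg = SimConfig(seed=7)
        balance = electron_balance(
            noiseless_sim.record,
            charge_C=noiseless_sim.ground_truth["charge_C"],
            basis="consumed",
        )
        assert balance.percent["current"] == pytest.approx(100 * cfg.f_current, abs=1e-9)
        assert balance.percent["methane"] == pytest.approx(100 * cfg.f_ch4, abs=1e-9)
        assert balance.percent["hydrogen"] == pytest.approx(
            100 * cfg.f_h2_residual, abs=1e-9
        )
        assert balance.percent["undefined"] == pytest.approx(
            100 * cfg.f_undefined, abs=1e-9
        )

    def test_meq_entries_sum_to_donor_eq(self, noiseless_sim):
        balance = electron_balance(noiseless_sim.record)
        assert sum(balance.milli_eq.values()) == pytest.approx(
            balance.donor_meq, rel=1e-12
        )

    def test_fed_basis_books_residual_donor(self, noiseless_sim):
        fed = electron_balance(noiseless_sim.record, basis="fed")
        consumed = electron_balance(noiseless_sim.record, basis="consumed")
        assert fed.percent["propionate"] > 0
        assert consumed.percent["propionate"] == 0.0
        assert fed.donor_meq > consumed.donor_meq

    def test_over_closure_flagged(self, noiseless_sim):
        huge_charge = 10 * noiseless_sim.ground_truth["charge_C"]
        with pytest.warns(UserWarning):
            balance = electron_balance(noiseless_sim.record, charge_C=huge_charge)
        assert balance.over_closed
        assert balance.percent["undefined"] < 0

    def test_table_frame_layout(self, noiseless_sim):
        frame = electron_balance(noiseless_sim.record).as_frame()
        assert list(frame.columns) == ["milli_e_eq", "percent"]
        assert frame.index[-1] == "undefined"
        assert frame["percent"].sum() == pytest.approx(100.0, abs=0.05)


class TestTimeCourse:
    def test_acetate_fraction_arithmetic(self):
        hplc = pd.DataFrame({"time_h": [70.0], "acetate_mM": [9.9], "formate_mM": [0.0]})
        tc = time_course_fractions(hplc, donor_initial_mM=36.0)
        # 100 * 8 * 9.9 / (14 * 36)
        assert tc.percent["acetate"].iloc[0] == pytest.approx(15.714, abs=1e-3)
        assert (tc.percent["formate"] == 0).all()

    def test_zero_concentrations_zero_percent(self):
        hplc = pd.DataFrame(
            {"time_h": np.arange(5.0), "acetate_mM": np.zeros(5), "formate_mM": np.zeros(5)}
        )
        tc = time_course_fractions(hplc, donor_initial_mM=36.0)
        assert (tc.percent.to_numpy() == 0).all()

    def test_missing_basis_rejected(self):
        hplc = pd.DataFrame({"time_h": [0.0], "acetate_mM": [1.0]})
        with pytest.raises(ValueError):
            time_course_fractions(hplc, donor_initial_mM=0.0)


class TestPathwayFraction:
    def test_propionate_to_acetate_and_h2(self):
        fractions, complete = pathway_fraction([("acetate", 1.0), ("hydrogen", 3.0)])
        assert fractions["acetate"] == pytest.approx(100 * 8 / 14)
        assert fractions["hydrogen"] == pytest.approx(100 * 6 / 14)
        assert sum(fractions.values()) == pytest.approx(100.0)
        assert complete

    def test_identity_pathway(self):
        fractions, complete = pathway_fraction([("propionate", 1.0)])
        assert fractions["propionate"] == pytest.approx(100.0)
        assert complete

    def test_incomplete_pathway_flagged(self):
        fractions, complete = pathway_fraction([("acetate", 1.0)])
        assert fractions["acetate"] == pytest.approx(57.14, abs=0.01)
        assert not complete

    def test_over_stoichiometric_pathway_rejected(self):
        with pytest.raises(ValueError):
            pathway_fraction([("acetate", 2.0)])


def test_permuting_gas_phases_leaves_balance_unchanged(noiseless_sim):
    record = noiseless_sim.record
    permuted = type(record)(
        anode_volume_m3=record.anode_volume_m3,
        cycle_days=record.cycle_days,
        set_potential_V=record.set_potential_V,
        initial_mM=record.initial_mM,
        final_mM=record.final_mM,
        gas=list(reversed(record.gas)),
        trace=record.trace,
    )
    a = electron_balance(record)
    b = electron_balance(permuted)
    assert a.percent == pytest.approx(b.percent)
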