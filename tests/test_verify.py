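"""Transition-state filter stack: frequency counts, drift, mode-bond matching."""

import numpy as np
import pytest

from rxnforge import verify as vf
from rxnforge.energetics import HARTREE_TO_KCAL
from rxnforge.mocks import (
    DEFECT_KINDS,
    _rigid_transform,
    make_verification_case,
    make_verification_suite,
)

from conftest import simple_graph


class TestImaginaryChecks:
    @pytest.mark.parametrize(
        "freqs,expected",
        [
            ([-612.3, 95.0, 210.0], (True, True)),
            ([-80.0, 150.0], (True, False)),  # conformational-scale imaginary mode
            ([-500.0, -300.0, 900.0], (False, False)),  # second-order saddle
            ([-100.0, 50.0], (True, True)),  # boundary magnitude kept
            ([100.0, 200.0], (False, False)),  # a minimum is not a TS
        ],
    )
    def test_count_and_magnitude(self, freqs, expected):
        assert vf.check_ts_imaginary(freqs) == expected

    def test_raising_cutoff_never_rescues(self):
        """Filter monotonicity: a triple failing at 100 cm^-1 also fails at any higher cutoff."""
        for freqs in ([-80.0, 150.0], [-120.0, 5.0], [-500.0, -300.0, 10.0], [-250.0, 9.0]):
            for lo, hi in ((100.0, 250.0), (100.0, 600.0)):
                low_ok = all(vf.check_ts_imaginary(freqs, lo))
                high_ok = all(vf.check_ts_imaginary(freqs, hi))
                assert high_ok <= low_ok

    def test_minimum_check(self):
        assert vf.check_minimum(_stub_result([100.0, 200.0, 300.0]))
        assert not vf.check_minimum(_stub_result([-5.0, 200.0]))
        assert vf.check_minimum(_stub_result([]))  # single atom, no modes


class TestEnergyDrift:
    @pytest.mark.parametrize(
        "drift_kcal,ok", [(2.9, True), (3.1, False), (3.0, True), (0.0, True)]
    )
    def test_threshold_boundary(self, drift_kcal, ok):
        e0 = -100.0
        assert vf.check_energy_drift(e0 + drift_kcal / HARTREE_TO_KCAL, e0) is ok


class TestModeMatch:
    def _collinear_transfer(self):
        """A-H...B toy: mode moves only the transferring H along the axis."""
        rg = simple_graph(["O", "H", "O"], [(0, 1)])
        pg = simple_graph(["O", "H", "O"], [(1, 2)])
        geometry = np.array([[0.0, 0.0, 0.0], [1.1, 0.0, 0.0], [2.3, 0.0, 0.0]])
        mode = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        ts = _stub_result([-900.0, 300.0], geometry=geometry, modes=[mode, _perp(mode)])
        return ts, rg, pg

    def test_collinear_transfer_passes(self):
        ts, rg, pg = self._collinear_transfer()
        ok, scores = vf.check_mode_match(ts, rg, pg)
        assert ok
        assert scores[(0, 1)] > 0 and scores[(1, 2)] > 0

    def test_spectator_mode_fails(self):
        rg = simple_graph(["O", "H", "O", "H"], [(0, 1), (2, 3)])
        pg = simple_graph(["O", "H", "O", "H"], [(1, 2), (2, 3)])
        geometry = np.array(
            [[0.0, 0.0, 0.0], [1.1, 0.0, 0.0], [2.3, 0.0, 0.0], [2.8, 0.9, 0.0]]
        )
        mode = np.zeros((4, 3))
        mode[3] = [0.35, 0.57, 0.0]  # along the unchanged O-H bond
        mode /= np.linalg.norm(mode)
        ts = _stub_result([-900.0, 10.0], geometry=geometry, modes=[mode, _perp(mode)])
        ok, _ = vf.check_mode_match(ts, rg, pg)
        assert not ok

    def test_tie_rejects(self):
        rg = simple_graph(["O", "H"], [(0, 1)])
        pg = simple_graph(["O", "H"], [])
        # zero mode projections everywhere -> min changing == max unchanged impossible;
        # construct equality via perpendicular mode (all scores zero, no unchanged bonds)
        geometry = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        mode = np.array([[0.0, 1.0, 0.0], [0.0, 1.0, 0.0]]) / np.sqrt(2)
        ts = _stub_result([-500.0], geometry=geometry, modes=[mode])
        ok, scores = vf.check_mode_match(ts, rg, pg)
        assert not ok and scores[(0, 1)] == pytest.approx(0.0)

    def test_identity_reaction_is_error(self, water):
        ts = _stub_result([-500.0], geometry=np.zeros((3, 3)) + np.eye(3), modes=None, natoms=3)
        with pytest.raises(vf.NoReactionError):
            vf.check_mode_match(ts, water, water)

    def test_rigid_motion_and_sign_invariance(self, rng):
        for k in range(30):
            case = make_verification_case(99, k)
            _, mode = case.ts.imaginary_mode()
            pairs = sorted(set(case.rg.bonds) | set(case.pg.bonds))
            ref = vf.mode_bond_scores(mode, case.ts.geometry, pairs)
            geom2, mode2 = _rigid_transform(rng, case.ts.geometry, mode)
            moved = vf.mode_bond_scores(mode2, geom2, pairs)
            flipped = vf.mode_bond_scores(-mode, case.ts.geometry, pairs)
            for b in pairs:
                assert moved[b] == pytest.approx(ref[b], abs=1e-10)
                assert flipped[b] == pytest.approx(ref[b], abs=1e-12)


class TestVerifyReaction:
    def test_clean_triple_passes(self):
        case = make_verification_case(5, 0)
        report = vf.verify_reaction(case.r, case.ts, case.p, case.rg, case.pg, case.string)
        assert report.passed
        assert report.details["energy_drift_kcal"] <= 3.0

    @pytest.mark.parametrize("defect", DEFECT_KINDS)
    def test_each_defect_fails_its_own_check(self, defect):
        case = make_verification_case(5, 0, defect)
        report = vf.verify_reaction(case.r, case.ts, case.p, case.rg, case.pg, case.string)
        assert not report.passed
        expected_flag = {
            "two_imaginary": "one_imaginary",
            "low_imaginary": "imag_magnitude_ok",
            "energy_drift": "energy_drift_ok",
            "spectator_mode": "mode_match_ok",
        }[defect]
        assert getattr(report, expected_flag) is False

    def test_passed_is_conjunction(self):
        for case in make_verification_suite(17, n_per_class=4):
            report = vf.verify_reaction(
                case.r, case.ts, case.p, case.rg, case.pg, case.string
            )
            flags = (
                report.one_imaginary,
                report.imag_magnitude_ok,
                report.energy_drift_ok,
                report.mode_match_ok,
                report.endpoints_are_minima,
            )
            assert report.passed == all(flags)

    def test_atom_count_mismatch_is_input_error(self, water):
        case = make_verification_case(5, 0)
        with pytest.raises(vf.VerificationInputError):
            vf.verify_reaction(case.r, case.ts, case.p, water, water, case.string)


def _perp(mode):
    """A unit mode orthogonal-ish to the given one (placeholder real mode)."""
    out = np.roll(mode, 1, axis=1) + 0.3
    return out / np.linalg.norm(out)


def _stub_result(freqs, geometry=None, modes=None, natoms=None):
    from rxnforge.qcio import OptFreqResult

    if geometry is None:
        n = natoms or 3
        geometry = np.arange(3 * n, dtype=float).reshape(n, 3)
    geometry = np.asarray(geometry, dtype=float)
    n = geometry.shape[0]
    if modes is None:
        modes = []
        for k in range(len(freqs)):
            m = np.zeros((n, 3))
            m[k % n, k % 3] = 1.0
            modes.append(m)
    modes = np.asarray(modes, dtype=float)
    if len(freqs) == 0:
        modes = np.zeros((0, n, 3))
    return OptFreqResult(tuple(["O"] * n), geometry, -100.0, tuple(freqs), modes)
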