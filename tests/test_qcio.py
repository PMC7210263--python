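"""Engine-interface I/O: XYZ, opt+freq logs, string paths, engine inputs."""

import numpy as np
import pytest

from rxnforge import qcio
from rxnforge.mocks import random_optfreq_spec


class TestXYZ:
    def test_single_atom(self):
        elements, geometry = qcio.read_xyz("1\n\nH 0 0 0\n")
        assert elements == ["H"] and np.allclose(geometry, [[0, 0, 0]])

    def test_roundtrip(self, rng):
        elements = ["C", "H", "O", "N"]
        geometry = rng.uniform(-3, 3, size=(4, 3))
        e2, g2 = qcio.read_xyz(qcio.write_xyz(elements, geometry))
        assert e2 == elements
        assert np.abs(g2 - geometry).max() < 1e-6

    def test_count_mismatch_is_error(self):
        with pytest.raises(qcio.ParseError):
            qcio.read_xyz("3\n\nH 0 0 0\nH 1 0 0\n")


class TestOptFreqLog:
    def test_field_recovery(self):
        text = qcio.make_mock_optfreq_log(
            ["O", "H"], [[0, 0, 0], [0.97, 0, 0]], -100.5, [-500.0, 1200.0]
        )
        r = qcio.parse_optfreq_log(text)
        assert r.energy == -100.5
        assert r.frequencies == (-500.0, 1200.0)
        assert r.modes.shape == (2, 2, 3)
        assert r.converged

    def test_roundtrip_randomized(self, rng):
        for _ in range(200):
            els, geom, e, freqs, modes = random_optfreq_spec(rng, int(rng.integers(1, 9)))
            r = qcio.parse_optfreq_log(
                qcio.make_mock_optfreq_log(els, geom, e, freqs, modes)
            )
            assert r.elements == tuple(els)
            assert r.energy == pytest.approx(e, abs=5e-11)
            assert np.abs(r.geometry - geom).max() < 1e-8
            assert r.frequencies == tuple(round(f, 4) for f in freqs)
            for got, want in zip(r.modes, modes):
                assert np.abs(got - want).max() < 1e-9

    def test_truncated_log_is_incomplete(self):
        text = qcio.make_mock_optfreq_log(["H", "H"], [[0, 0, 0], [0.7, 0, 0]], -1.1, [4000.0])
        truncated = text[: text.index("nmodes")]
        with pytest.raises(qcio.IncompleteLogError):
            qcio.parse_optfreq_log(truncated)

    def test_nonconverged_flag_preserved(self):
        text = qcio.make_mock_optfreq_log(["H"], [[0, 0, 0]], -0.5, [], converged=False)
        assert qcio.parse_optfreq_log(text).converged is False

    def test_inconsistent_spec_rejected(self):
        with pytest.raises(qcio.SpecError):
            qcio.make_mock_optfreq_log(
                ["H"], [[0, 0, 0]], -0.5, [100.0, 200.0], np.ones((1, 1, 3))
            )

    def test_seeded_batch_distinct_and_reproducible(self):
        def batch(seed):
            rng = np.random.default_rng(seed)
            return [
                qcio.make_mock_optfreq_log(*random_optfreq_spec(rng, 4)[:5])
                for _ in range(50)
            ]

        a, b = batch(11), batch(11)
        assert a == b
        assert len(set(a)) == 50


class TestStringPath:
    def test_ts_node_is_argmax(self):
        geom = np.zeros((1, 3))
        sp = qcio.parse_string_output(
            qcio.make_mock_string_output(["H"], [0.0, 0.030, 0.010], geom, geom)
        )
        assert sp.ts_node_index == 1

    def test_tie_takes_first_occurrence(self):
        geom = np.zeros((1, 3))
        sp = qcio.parse_string_output(
            qcio.make_mock_string_output(["H"], [0.0, 0.5, 0.5, 0.1], geom, geom)
        )
        assert sp.ts_node_index == 1

    def test_single_node_path_rejected(self):
        geom = np.zeros((1, 3))
        with pytest.raises(qcio.SpecError):
            qcio.make_mock_string_output(["H"], [0.0], geom, geom)
        with pytest.raises(qcio.DegeneratePathError):
            qcio.StringPath((0.0,), geom, geom, ("H",))
        degenerate = (
            "STRING-PATH 1\nnatoms 1\nnodes 1\nenergies\n0.0\n"
            "endpoint_geometry\nH 0 0 0\nts_geometry\nH 0 0 0\nend\n"
        )
        with pytest.raises(qcio.DegeneratePathError):
            qcio.parse_string_output(degenerate)


class TestEngineInput:
    def test_deterministic_bytes(self):
        cfg = qcio.EngineConfig("wB97X-D3", "def2-TZVP", "opt+freq")
        geom = np.arange(15, dtype=float).reshape(5, 3)
        els = ["C", "H", "H", "H", "H"]
        a = qcio.write_engine_input(geom, els, cfg)
        b = qcio.write_engine_input(geom, els, cfg)
        assert a == b
        assert sum(1 for ln in a.splitlines() if ln.startswith(("C ", "H "))) == 5

    def test_empty_basis_rejected(self):
        with pytest.raises(qcio.ConfigError):
            qcio.EngineConfig("B97-D3", "", "opt+freq")

    def test_parse_back(self):
        cfg = qcio.EngineConfig("B97-D3", "def2-mSVP", "ts-opt+freq")
        geom = np.array([[0.0, 0.0, 0.0], [1.1, 0.0, 0.0]])
        text = qcio.write_engine_input(geom, ["O", "O"], cfg, comment="tsopt 0001")
        comment, els, g2, charge, mult, rem = qcio.parse_engine_input(text)
        assert comment == "tsopt 0001"
        assert els == ["O", "O"] and np.allclose(g2, geom)
        assert rem["jobtype"] == "ts-opt+freq"


def test_qchem_reader_minimal_log():
    """The best-effort reader recovers energy/geometry/frequencies from engine-style text."""
    log = """
 Optimization complete.
        Standard Nuclear Orientation (Angstroms)
    I     Atom           X                Y                Z
 ----------------------------------------------------------------
    1      O       0.0000000000     0.0000000000     0.1173000000
    2      H       0.0000000000     0.7572000000    -0.4692000000
 ----------------------------------------------------------------
 Final energy is   -76.4089210000

 Frequency:   1700.00  3800.00
               X      Y      Z        X      Y      Z
    O         0.000  0.000  0.070    0.000  0.000  0.050
    H         0.000  0.430 -0.560    0.580  0.400  0.250
"""
    r = qcio.parse_qchem_log(log)
    assert r.energy == pytest.approx(-76.408921)
    assert r.elements == ("O", "H")
    assert r.frequencies == (1700.0, 3800.0)
    assert np.allclose(np.linalg.norm(r.modes.reshape(2, -1), axis=1), 1.0)
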