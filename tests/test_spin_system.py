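"""Spin basis, exchange law and Hamiltonian structure."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rpcidnp.spin_system import (
    ConfigError,
    ExchangeModel,
    NucleusSpec,
    RadicalPairSystem,
    RadicalSpec,
    SizingError,
    build_pair_basis,
    exchange_coupling,
    hamiltonian,
    subsystem,
)

TABLE_EXCHANGE = ExchangeModel(J0_mT=-1.6e9, alpha_invA=2.14)


def pair(nuclei1=(), nuclei2=(), exchange=TABLE_EXCHANGE, **kw):
    return RadicalPairSystem(
        radical1=RadicalSpec("F", 2.0034, tuple(nuclei1)),
        radical2=RadicalSpec("W", 2.0025, tuple(nuclei2)),
        exchange=exchange,
        **kw,
    )


class TestBasis:
    @pytest.mark.parametrize(
        "nuclei2, dim",
        [
            ((), 4),
            ((NucleusSpec("a", 0.5, 1.0, 2), NucleusSpec("b", 0.5, 0.3, 2)), 16),
            ((NucleusSpec("n14", 1.0, 0.5, 2),), 12),
        ],
    )
    def test_dimension(self, nuclei2, dim):
        assert build_pair_basis(pair(nuclei2=nuclei2)).dim == dim

    def test_singlet_projector_idempotent_hermitian(self):
        basis = build_pair_basis(pair(nuclei2=(NucleusSpec("n14", 1.0, 0.5, 2),)))
        ps = basis.projector_singlet
        assert np.allclose(ps @ ps, ps, atol=1e-12)
        assert np.allclose(ps, ps.conj().T, atol=1e-14)
        # one singlet level per nuclear sublevel
        assert np.isclose(np.trace(ps).real, 3.0)

    def test_trace_of_projector_counts_nuclear_states(self):
        sys2 = pair(
            nuclei1=(NucleusSpec("f1", 0.5, -0.2, 1),),
            nuclei2=(NucleusSpec("w1", 0.5, 1.0, 2),),
        )
        basis = build_pair_basis(sys2)
        assert np.isclose(np.trace(basis.projector_singlet).real, basis.nuclear_dim)

    def test_dimension_cap_names_offenders(self):
        many = tuple(NucleusSpec(f"h{i}", 0.5, 0.5, 2) for i in range(5))
        with pytest.raises(SizingError, match="h4"):
            build_pair_basis(pair(nuclei2=many))

    def test_subsystem_keeps_requested_nuclei(self):
        sys2 = pair(nuclei2=(NucleusSpec("a", 0.5, 1.0, 2), NucleusSpec("b", 0.5, 0.3, 2)))
        sub = subsystem(sys2, ["b"])
        assert [n.label for n in sub.nuclei] == ["b"]
        with pytest.raises(ConfigError):
            subsystem(sys2, ["nope"])


class TestExchange:
    def test_table_parameters_reproduce_quoted_coupling(self):
        # J0 exp(-alpha r) at the effective separation, 3 significant figures
        j = exchange_coupling(TABLE_EXCHANGE, 9.14)
        assert j == pytest.approx(-5.12, abs=0.005)

    def test_decay_limit(self):
        assert exchange_coupling(TABLE_EXCHANGE, 1e3) == pytest.approx(0.0, abs=1e-300)

    def test_no_decay(self):
        assert exchange_coupling(ExchangeModel(-7.0, 0.0), 123.0) == -7.0

    def test_domain_error(self):
        with pytest.raises(ValueError):
            exchange_coupling(TABLE_EXCHANGE, 0.0)


class TestHamiltonian:
    @given(
        b=st.floats(0.0, 7000.0),
        r=st.floats(4.0, 20.0),
        a=st.floats(-2.0, 2.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_hermitian_for_any_inputs(self, b, r, a):
        sys1 = pair(nuclei2=(NucleusSpec("h", 0.5, a, 2),))
        H = hamiltonian(sys1, b, r)
        norm = np.linalg.norm(H, 2)
        assert np.max(np.abs(H - H.conj().T)) <= 1e-12 * max(norm, 1.0)

    @given(b=st.floats(0.0, 100.0), r=st.floats(4.0, 20.0))
    @settings(max_examples=20, deadline=None)
    def test_no_hyperfine_means_no_singlet_triplet_mixing(self, b, r):
        # equal g-factors: without hyperfine couplings (and without the
        # Delta-g S-T0 pathway) the singlet projector is conserved
        sys0 = RadicalPairSystem(
            RadicalSpec("F", 2.002319),
            RadicalSpec("W", 2.002319),
            TABLE_EXCHANGE,
        )
        basis = build_pair_basis(sys0)
        H = hamiltonian(sys0, b, r, basis)
        comm = H @ basis.projector_singlet - basis.projector_singlet @ H
        assert np.max(np.abs(comm)) < 1e-12

    def test_zero_field_gap_is_exchange_coupling(self):
        sys0 = pair()
        r = 9.14
        H = hamiltonian(sys0, 0.0, r)
        ev = np.sort(np.linalg.eigvalsh(H))
        gap = ev[-1] - ev[0]
        assert gap == pytest.approx(abs(exchange_coupling(TABLE_EXCHANGE, r)), rel=1e-10)

    def test_st_minus_levels_cross_at_field_equal_to_J(self):
        # negative J: the T- level meets S exactly at B = |J_ex| (exact for
        # the free-electron g; radical g-factors shift it by ~2e-4 B)
        sys0 = RadicalPairSystem(
            RadicalSpec("F", 2.002319),
            RadicalSpec("W", 2.002319),
            TABLE_EXCHANGE,
        )
        basis = build_pair_basis(sys0)
        j = abs(exchange_coupling(TABLE_EXCHANGE, 9.14))
        states = basis.electron_states()

        def st_gap(b):
            H = hamiltonian(sys0, b, 9.14, basis)
            es = states["S"].conj() @ H @ states["S"]
            etm = states["T-"].conj() @ H @ states["T-"]
            return (es - etm).real

        assert st_gap(j) == pytest.approx(0.0, abs=1e-9)
        assert st_gap(j - 1.0) * st_gap(j + 1.0) < 0  # genuine crossing

    def test_single_nucleus_spectrum_matches_closed_form(self):
        # a I.S for two spin-1/2 particles: eigenvalues a/4 (triplet) and
        # -3a/4 (singlet); the spectator electron doubles each multiplicity
        a = 1.0
        sys1 = pair(
            nuclei2=(NucleusSpec("h", 0.5, a, 2),),
            exchange=ExchangeModel(0.0, 0.0),
        )
        H = hamiltonian(sys1, 0.0, 9.0, nuclear_zeeman=False)
        ev = np.sort(np.linalg.eigvalsh(H))
        expected = np.sort([a / 4] * 6 + [-3 * a / 4] * 2)
        assert np.allclose(ev, expected, atol=1e-12)

    def test_negative_field_rejected(self):
        with pytest.raises(ValueError):
            hamiltonian(pair(), -1.0, 9.0)


class TestValidation:
    def test_bad_spin(self):
        with pytest.raises(ConfigError):
            NucleusSpec("x", 0.7, 1.0, 2)

    def test_bad_g(self):
        with pytest.raises(ConfigError):
            RadicalSpec("x", 2.5)

    def test_duplicate_labels(self):
        with pytest.raises(ConfigError):
            pair(
                nuclei1=(NucleusSpec("h", 0.5, 1.0, 1),),
                nuclei2=(NucleusSpec("h", 0.5, 1.0, 2),),
            )

    def test_negative_alpha(self):
        with pytest.raises(ConfigError):
            ExchangeModel(-1.0, -0.1)
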