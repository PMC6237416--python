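"""Energy-model checks against independent scalar re-implementations."""

import math

import numpy as np
import pytest

from twistslide.energy import (
    CONFINE_K,
    FLANK_WIDTH,
    gradient,
    smoothstep,
    total_energy,
    twist_energy,
)
from twistslide.model import (
    ChemicalState,
    DefectSiteParams,
    ParameterSet,
    SystemState,
    effective_params,
)


def lse_twist(d, k, mup, mum, temp=0.2):
    """Independent scalar evaluation of the smoothed three-well form."""
    branches = [mum + 0.5 * k * (d + 1) ** 2, 0.5 * k * d * d, mup + 0.5 * k * (d - 1) ** 2]
    m = min(branches)
    return m - temp * math.log(sum(math.exp(-(b - m) / temp) for b in branches))


class TestTwistEnergy:
    def test_reference_well_is_zero(self):
        p = DefectSiteParams(k=15.0, mu_plus=3.0, mu_minus=3.0)
        assert twist_energy(0.0, p) == pytest.approx(0.0, abs=1e-6)

    def test_defect_wells_at_stated_penalties(self):
        p = DefectSiteParams(k=15.0, mu_plus=3.0, mu_minus=2.0)
        assert twist_energy(1.0, p) == pytest.approx(3.0, abs=1e-6)
        assert twist_energy(-1.0, p) == pytest.approx(2.0, abs=1e-6)

    @pytest.mark.parametrize("d", [-2.0, -0.7, 0.5, 0.9, 1.4, 3.0])
    def test_matches_scalar_closed_form(self, d):
        p = DefectSiteParams(k=15.0, mu_plus=3.0, mu_minus=3.0)
        assert twist_energy(d, p) == pytest.approx(lse_twist(d, 15.0, 3.0, 3.0), rel=1e-12)

    def test_outer_branch_continues_quadratically(self):
        # beyond the outer wells the energy keeps rising: the documented clamp
        p = DefectSiteParams(k=15.0, mu_plus=3.0, mu_minus=3.0)
        assert twist_energy(3.5, p) > twist_energy(2.5, p) > twist_energy(1.0, p)


def scalar_total_energy(s: SystemState, ps: ParameterSet) -> float:
    """Term-by-term scalar oracle for the documented energy terms."""
    e = 0.0
    y1, y2 = s.y1, s.y2
    u = y1 - y2
    e += ps.grip_mult * ps.grip1 * 0.5 * (1 - math.cos(2 * math.pi * y1))
    e += ps.grip_mult * ps.grip2 * 0.5 * (1 - math.cos(2 * math.pi * y2))
    e += ps.closure_barrier * 0.5 * (1 - math.cos(2 * math.pi * u))
    e += CONFINE_K * (max(-(u + 0.25), 0.0) ** 2 + max(u - 1.25, 0.0) ** 2)
    e += (ps.closure_offset - ps.lobe_coupling) * float(smoothstep(u))
    e += ps.lobe1_strain * (1 - float(smoothstep(y1 - ps.y_anchor)))
    if ps.naked:
        return e
    for j in range(14):
        x = s.x[j]
        e += ps.contact_depth[j] * 0.5 * (1 - math.cos(2 * math.pi * x))
        e += ps.contact_flank[j] * float(smoothstep(abs(x - round(x)) / FLANK_WIDTH))
        e += ps.tilt[j] * x
    for i in range(13):
        e += lse_twist(s.x[i + 1] - s.x[i], ps.twist_k[i], ps.twist_mu_plus[i],
                       ps.twist_mu_minus[i], ps.smoothing)
    xbar = 0.5 * (s.x[8] + s.x[9])
    rho = xbar - 0.5 * (y1 + y2)
    e += ps.wall_height * max(abs(rho) - ps.wall_halfwidth, 0.0) ** 2
    r1 = xbar - y1
    e -= ps.eps_elec * math.exp(-(r1**2) / (2 * ps.elec_width**2))
    return e


def test_total_energy_matches_scalar_oracle(atp_params, rng):
    for _ in range(25):
        s = SystemState.from_vector(rng.normal(0, 0.8, 16))
        assert total_energy(s, atp_params) == pytest.approx(
            scalar_total_energy(s, atp_params), rel=1e-10
        )


def test_mutant_reference_energy_gap(base_params, polyapg_profile):
    """At the reference state the spring contributes exactly -eps_elec."""
    wt = effective_params(base_params, polyapg_profile, ChemicalState.APO)
    mut = effective_params(base_params.mutant(), polyapg_profile, ChemicalState.APO)
    s = SystemState.zeros()
    assert total_energy(s, mut) - total_energy(s, wt) == pytest.approx(
        base_params.eps_elec, abs=1e-10
    )


class TestTranslationalSymmetry:
    def test_dna_terms_invariant_under_register_shift(self, base_params, uniform_profile):
        """All DNA-octamer terms are 1-bp periodic: shifting the DNA register
        with the translocase terms switched off leaves the energy unchanged."""
        from twistslide.protocols import no_remodeler_params
        from twistslide.sequences import profile_from_sequence, build_sequence

        ps = effective_params(no_remodeler_params(),
                              profile_from_sequence(build_sequence("polyApG")),
                              ChemicalState.APO)
        rng = np.random.default_rng(7)
        for _ in range(20):
            v = rng.normal(0, 0.6, 16)
            s = SystemState.from_vector(v)
            s2 = SystemState.from_vector(v + 1.0)
            assert total_energy(s2, ps) == pytest.approx(total_energy(s, ps), abs=1e-10)

    def test_full_potential_invariant_with_anchor_shift(self, base_params, uniform_profile):
        """The registration-anchored terms shift with the cycle anchor: the
        co-shifted potential is exactly translation invariant."""
        import dataclasses

        ps = effective_params(base_params, uniform_profile, ChemicalState.ATP)
        ps_shift = dataclasses.replace(ps, y_anchor=ps.y_anchor + 1.0)
        rng = np.random.default_rng(8)
        for _ in range(20):
            v = rng.normal(0, 0.6, 16)
            a = total_energy(SystemState.from_vector(v), ps)
            b = total_energy(SystemState.from_vector(v + 1.0), ps_shift)
            assert b == pytest.approx(a, abs=1e-10)


def test_gradient_matches_finite_differences(atp_params, apo_params, rng):
    h = 1e-6
    for ps in (atp_params, apo_params):
        for _ in range(50):
            v = rng.normal(0, 0.9, 16)
            s = SystemState.from_vector(v)
            g = gradient(s, ps)
            for i in rng.choice(16, size=6, replace=False):
                vp, vm = v.copy(), v.copy()
                vp[i] += h
                vm[i] -= h
                fd = (
                    total_energy(SystemState.from_vector(vp), ps)
                    - total_energy(SystemState.from_vector(vm), ps)
                ) / (2 * h)
                assert g[i] == pytest.approx(fd, rel=2e-4, abs=2e-4)


def test_gradient_vanishes_at_symmetric_minimum(apo_params):
    g = gradient(SystemState.zeros(), apo_params)
    assert np.allclose(g, 0.0, atol=1e-10)


def test_tilt_adds_linearly_to_gradient(base_params):
    import dataclasses

    from twistslide.sequences import build_sequence, profile_from_sequence

    prof = profile_from_sequence(build_sequence("601"))
    ps = effective_params(base_params, prof, ChemicalState.APO)
    ps0 = dataclasses.replace(ps, tilt=np.zeros(14))
    s = SystemState.from_vector(np.random.default_rng(3).normal(0, 0.5, 16))
    assert np.allclose(gradient(s, ps)[:14] - gradient(s, ps0)[:14], ps.tilt, atol=1e-12)


def test_ratchet_asymmetry(base_params, polyapg_profile):
    """With the wild-type ATP parameters, the closed slid configuration lies
    below the closed unslid one; without the electrostatic spring and tilt
    the two registers are nearly degenerate."""
    ps = effective_params(base_params, polyapg_profile, ChemicalState.ATP)
    x_f = np.ones(14)
    slid = SystemState(x=x_f, y1=1.0, y2=0.0)
    unslid = SystemState(x=np.zeros(14), y1=1.0, y2=0.0)
    assert total_energy(slid, ps) < total_energy(unslid, ps)
    import dataclasses

    ps_nospring = dataclasses.replace(ps, eps_elec=0.0, lobe1_strain=0.0)
    d = total_energy(
        SystemState(x=x_f, y1=1.0, y2=0.0), ps_nospring
    ) - total_energy(SystemState(x=np.zeros(14), y1=1.0, y2=0.0), ps_nospring)
    assert abs(d) < 0.2


def test_steric_wall_blocks_body_excursion(apo_params):
    """In the open apo state, sliding the site DNA a full step away from the
    body costs at least the quadratic wall penalty."""
    x = np.zeros(14)
    x[8] = x[9] = 1.0  # site DNA slid, lobes not
    s = SystemState(x=x, y1=0.0, y2=0.0)
    base = SystemState.zeros()
    penalty = apo_params.wall_height * (1.0 - apo_params.wall_halfwidth) ** 2
    assert total_energy(s, apo_params) - total_energy(base, apo_params) >= penalty * 0.99
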