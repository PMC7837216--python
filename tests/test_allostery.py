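import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eif2btools.allostery import (
    STATE_NAMES,
    LinkageParameters,
    competition_curve,
    fit_competition_curve,
    free_isrib_with_depletion,
    gef_activity,
    isrib_occupancy,
    mutant_transform,
    phosphorylation_timecourse,
    species_distribution,
)
from oracles import enumerate_linkage_populations

TITRATION = np.logspace(-3, 1.5, 25)

log_const = st.floats(min_value=-2.0, max_value=2.0)
log_coupling = st.floats(min_value=-3.0, max_value=1.0)
conc = st.floats(min_value=0.0, max_value=100.0)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(kp1=log_const, kp2=log_const, cp=log_coupling, g1=log_coupling,
       g2=log_coupling, isrib=conc, alphap=conc)
def test_populations_form_a_distribution(kp1, kp2, cp, g1, g2, isrib, alphap):
    p = LinkageParameters(k_p1_per_uM=10**kp1, k_p2_per_uM=10**kp2,
                          c_p=10**cp, g1=10**g1, g2=10**g2)
    dist = species_distribution(p, isrib, alphap)
    total = sum(dist.populations.values())
    assert abs(total - 1.0) < 1e-9
    assert all(v >= 0 for v in dist.populations.values())


def test_no_ligands_means_pure_ground_state():
    dist = species_distribution(LinkageParameters(), 0.0, 0.0)
    assert dist.by_name()["ground"] == pytest.approx(1.0, abs=1e-12)


def test_independence_limit_factorises_exactly():
    p = LinkageParameters(c_p=1.0, g1=1.0, g2=1.0)
    for alphap in (0.0, 0.3, 5.0, 50.0):
        occ = isrib_occupancy(p, 5.0, alphap)
        expected = (p.k_isrib_per_nM * 5.0) / (1.0 + p.k_isrib_per_nM * 5.0)
        assert occ == pytest.approx(expected, abs=1e-12)


def test_populations_match_microstate_enumeration():
    """State populations equal a brute-force enumeration over the 2x2x2
    microstates (the two αP sites treated as distinguishable)."""
    rng = np.random.default_rng(13)
    for _ in range(50):
        p = LinkageParameters(
            k_isrib_per_nM=10 ** rng.uniform(-2, 0),
            k_p1_per_uM=10 ** rng.uniform(-1, 1),
            k_p2_per_uM=10 ** rng.uniform(-1, 1),
            c_p=10 ** rng.uniform(-1, 2),
            g1=10 ** rng.uniform(-3, 0),
            g2=10 ** rng.uniform(-3, 0),
        )
        isrib, alphap = rng.uniform(0, 20), rng.uniform(0, 5)
        ours = species_distribution(p, isrib, alphap).populations
        theirs = enumerate_linkage_populations(p, isrib, alphap)
        for state in STATE_NAMES:
            assert ours[state] == pytest.approx(theirs[state], abs=1e-12)


def test_uncoupled_competition_curve_is_flat():
    p = LinkageParameters(c_p=1.0, g1=1.0, g2=1.0)
    trace = competition_curve(p, 2.5, TITRATION)
    assert trace.meta["flat"]
    assert np.ptp(trace.y) < 1e-9


def test_cooperative_antagonism_gives_steep_curve():
    p = LinkageParameters(g1=0.5, g2=0.01, c_p=20.0)
    trace = competition_curve(p, 2.5, TITRATION)
    assert not trace.meta["flat"]
    analysis = fit_competition_curve(trace)
    assert analysis["hill_slope"] > 1.5
    assert analysis["hill_slope"] < 2.1  # bounded by the two-site stoichiometry


def test_apparent_ic50_tracks_alphap_affinity():
    base = LinkageParameters()
    stronger = LinkageParameters(k_p1_per_uM=base.k_p1_per_uM * 10,
                                 k_p2_per_uM=base.k_p2_per_uM * 10)
    ic50_base = fit_competition_curve(competition_curve(base, 2.5, TITRATION))["ic50_uM"]
    ic50_strong = fit_competition_curve(
        competition_curve(stronger, 2.5, np.logspace(-4, 0.5, 25)))["ic50_uM"]
    ratio = ic50_base / ic50_strong
    assert 5.0 < ratio < 20.0  # ~10-fold, monotone in the expected direction


def test_titration_needs_enough_points():
    with pytest.raises(ValueError, match=">= 6"):
        competition_curve(LinkageParameters(), 2.5, [0.1, 1.0, 10.0])


class TestMutantTransform:
    def test_identity_at_d_one(self):
        p = LinkageParameters()
        q = mutant_transform(p, 1.0)
        assert q.k_p1_per_uM == p.k_p1_per_uM and q.k_p2_per_uM == p.k_p2_per_uM
        assert q.k_isrib_per_nM == p.k_isrib_per_nM

    def test_desensitisation_right_shifts_ic50(self):
        p = LinkageParameters()
        wt = fit_competition_curve(competition_curve(p, 2.5, TITRATION))
        mut = fit_competition_curve(
            competition_curve(mutant_transform(p, 10.0), 2.5,
                              np.logspace(-3, 2.5, 25)))
        assert mut["ic50_uM"] / wt["ic50_uM"] >= 5.0

    def test_extreme_desensitisation_flattens_the_curve(self):
        trace = competition_curve(mutant_transform(LinkageParameters(), 1e9),
                                  2.5, TITRATION)
        assert trace.meta["flat"]

    def test_invalid_factor_rejected(self):
        with pytest.raises(ValueError):
            mutant_transform(LinkageParameters(), 0.0)


class TestGefActivity:
    def test_apo_activity_is_one(self):
        assert gef_activity(LinkageParameters(), 0.0, 0.0) == pytest.approx(1.0)

    def test_saturating_alphap_approaches_state_ii_activity(self):
        p = LinkageParameters()
        assert gef_activity(p, 0.0, 1e4) == pytest.approx(p.activities["II"],
                                                          abs=1e-3)

    def test_isrib_rescues_activity_at_subsaturating_alphap(self):
        p = LinkageParameters()  # g2 << g1 <= 1
        without = gef_activity(p, 0.0, 0.5)
        with_isrib = gef_activity(p, 100.0, 0.5)
        assert with_isrib > without


class TestPhosphorylationTimecourse:
    def test_no_kinase_is_flat(self):
        trace = phosphorylation_timecourse(LinkageParameters(), 0.0, 0.6, 2.5)
        assert np.ptp(trace.y) < 1e-12

    def test_wild_type_signal_decays_monotonically(self):
        trace = phosphorylation_timecourse(LinkageParameters(), 0.15, 0.6, 2.5)
        assert np.all(np.diff(trace.y) <= 1e-12)
        assert trace.y[-1] < trace.y[0]

    def test_desensitised_mutant_decays_less(self):
        wt = phosphorylation_timecourse(LinkageParameters(), 0.15, 0.6, 2.5)
        mut = phosphorylation_timecourse(
            mutant_transform(LinkageParameters(), 30.0), 0.15, 0.6, 2.5)
        assert (wt.y[0] - wt.y[-1]) > 3.0 * (mut.y[0] - mut.y[-1])


def test_parameter_and_concentration_validation():
    with pytest.raises(ValueError):
        LinkageParameters(k_isrib_per_nM=0.0)
    with pytest.raises(ValueError):
        LinkageParameters(activities={"ground": 0.9, "ground_isrib": 1.0,
                                      "I": 0.5, "II": 0.0, "III": 0.5, "IV": 0.0})
    with pytest.raises(ValueError, match=">= 0"):
        species_distribution(LinkageParameters(), -1.0, 0.0)


def test_depletion_solver_conserves_probe():
    p = LinkageParameters()
    free = free_isrib_with_depletion(p, eif2b_total_nM=100.0, isrib_total_nM=2.5,
                                     alphaP_uM=0.0)
    bound = isrib_occupancy(p, free, 0.0) * 100.0
    assert free + bound == pytest.approx(2.5, abs=1e-9)
    assert free < 2.5  # receptor excess depletes the probe
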