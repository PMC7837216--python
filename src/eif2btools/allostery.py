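"""Thermodynamic linkage model of ISRIB / phospho-eIF2 antagonism on eIF2B.

eIF2B carries one central ISRIB pocket and two equivalent regulatory sites for
phosphorylated eIF2 [eIF2(αP)]. Occupancy states are labelled (i, j) with
i ∈ {0, 1} ISRIB molecules and j ∈ {0, 1, 2} bound eIF2(αP); the named states
of the antagonistic-allostery scheme are

    ground = (0,0)   I = (0,1)   II = (0,2)   ground·ISRIB = (1,0)
    III = (1,1)      IV = (1,2)

Equilibrium populations follow from a binding polynomial with statistical
factor 2 for the first of the two equivalent αP sites:

    w(i, j) = (K_I·[I])^i · s_j · g1^[i=1, j=1] · g2^[i=1, j=2]
    s_0 = 1,  s_1 = 2·K_P1·[P],  s_2 = K_P1·K_P2·[P]²·c_P

K_I is the ISRIB association constant (per nM), K_P1/K_P2 the first/second
αP-site association constants (per µM), c_P the αP-αP cooperativity factor,
and g1, g2 couple ISRIB with one or two bound αP (g < 1 = antagonism; the
hierarchy g2 << g1 ≤ 1 encodes ISRIB's preferential exclusion of the doubly
occupied, strongly inhibited state). Each state carries a relative nucleotide
exchange activity a_state (ground ≡ 1), so the ensemble GEF activity is the
population-weighted mean.

The treatment is purely equilibrium (the governing kinetic parameters are
experimentally undetermined); time courses assume rapid re-equilibration
against a slowly growing pool of phosphorylated eIF2. Ligand concentrations
are free concentrations by default (the fluorescent ISRIB probe is used far
below its Kd, so depletion is negligible); a conservation-aware solver is
available behind a flag. The default parameter set is illustrative, not
fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .binding_models import KineticTrace, fit

__all__ = [
    "STATE_NAMES",
    "LinkageParameters",
    "SpeciesDistribution",
    "species_distribution",
    "isrib_occupancy",
    "competition_curve",
    "fit_competition_curve",
    "mutant_transform",
    "gef_activity",
    "phosphorylation_timecourse",
    "free_isrib_with_depletion",
]

#: (i, j) occupancy → state name in the antagonistic-allostery scheme
STATE_NAMES: dict[tuple[int, int], str] = {
    (0, 0): "ground",
    (0, 1): "I",
    (0, 2): "II",
    (1, 0): "ground_isrib",
    (1, 1): "III",
    (1, 2): "IV",
}


@dataclass(frozen=True)
class LinkageParameters:
    """Equilibrium constants, coupling factors and state activities.

    Defaults are an illustrative (not fitted) wild-type-like set: ISRIB Kd
    ~10 nM, αP half-effect in the few-hundred-nM range, positive αP-αP
    cooperativity, strong ISRIB antagonism of the second αP (g2 << g1), and
    activities encoding one blocked catalytic site per bound αP trimer plus
    full allosteric inhibition in state II.
    """

    k_isrib_per_nM: float = 0.1
    k_p1_per_uM: float = 0.8
    k_p2_per_uM: float = 0.8
    c_p: float = 50.0
    g1: float = 0.5
    g2: float = 1e-3
    activities: dict = field(
        default_factory=lambda: {
            "ground": 1.0,
            "ground_isrib": 1.0,
            "I": 0.5,
            "II": 0.02,
            "III": 0.5,
            "IV": 0.02,
        }
    )
    label: str = "illustrative, not fitted"

    def __post_init__(self) -> None:
        for name in ("k_isrib_per_nM", "k_p1_per_uM", "k_p2_per_uM", "c_p", "g1", "g2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        acts = self.activities
        if set(acts) != set(STATE_NAMES.values()):
            raise ValueError(f"activities must cover states {sorted(set(STATE_NAMES.values()))}")
        if acts["ground"] != 1.0:
            raise ValueError("ground-state activity is the reference and must be 1")
        if any(not 0.0 <= a <= 1.0 for a in acts.values()):
            raise ValueError("state activities must lie in [0, 1]")


@dataclass
class SpeciesDistribution:
    """Fractional population of each occupancy state."""

    populations: dict[tuple[int, int], float]
    isrib_nM: float
    alphaP_uM: float

    def __post_init__(self) -> None:
        total = sum(self.populations.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"populations sum to {total}, not 1")
        if any(p < 0 for p in self.populations.values()):
            raise ValueError("negative population")

    def by_name(self) -> dict[str, float]:
        return {STATE_NAMES[k]: v for k, v in self.populations.items()}

    @property
    def isrib_bound_fraction(self) -> float:
        return sum(v for (i, _), v in self.populations.items() if i == 1)

    @property
    def alphaP_site_occupancy(self) -> float:
        """Mean fraction of the two αP sites occupied."""
        return sum(j * v for (_, j), v in self.populations.items()) / 2.0


def _state_weights(p: LinkageParameters, isrib_nM: float, alphaP_uM: float) -> dict:
    ki = p.k_isrib_per_nM * isrib_nM
    s = {
        0: 1.0,
        1: 2.0 * p.k_p1_per_uM * alphaP_uM,
        2: p.k_p1_per_uM * p.k_p2_per_uM * alphaP_uM**2 * p.c_p,
    }
    coupling = {0: 1.0, 1: p.g1, 2: p.g2}
    return {
        (i, j): (ki**i) * s[j] * (coupling[j] if i == 1 else 1.0)
        for i in (0, 1)
        for j in (0, 1, 2)
    }


def species_distribution(
    p: LinkageParameters, isrib_nM: float, alphaP_uM: float
) -> SpeciesDistribution:
    """Boltzmann-weighted populations of the six occupancy states at the given
    free ligand concentrations (depletion ignored)."""
    if isrib_nM < 0 or alphaP_uM < 0:
        raise ValueError("concentrations must be >= 0")
    w = _state_weights(p, isrib_nM, alphaP_uM)
    z = sum(w.values())
    return SpeciesDistribution({k: v / z for k, v in w.items()}, isrib_nM, alphaP_uM)


def isrib_occupancy(p: LinkageParameters, isrib_nM: float, alphaP_uM: float) -> float:
    """Fraction of eIF2B with ISRIB bound."""
    return species_distribution(p, isrib_nM, alphaP_uM).isrib_bound_fraction


def competition_curve(
    p: LinkageParameters,
    probe_isrib_nM: float,
    alphaP_uM: Sequence[float],
    flat_tol: float = 0.05,
) -> KineticTrace:
    """Fraction of ISRIB-bound eIF2B across an eIF2(αP) titration.

    Emulates the steady-state fluorescence-polarization competition readout;
    the returned trace (x = [αP] in µM) feeds directly into the 4PL fit. A
    curve without a transition in range is flagged in ``meta['flat']``.
    """
    conc = np.asarray(alphaP_uM, float)
    if len(conc) < 6:
        raise ValueError("titration needs >= 6 points spanning the transition")
    frac = np.array([isrib_occupancy(p, probe_isrib_nM, c) for c in conc])
    trace = KineticTrace(conc, frac, x_units="uM", y_units="fraction bound",
                         meta={"probe_isrib_nM": probe_isrib_nM, "label": p.label})
    trace.meta["flat"] = bool(frac.max() - frac.min() < flat_tol)
    return trace


def fit_competition_curve(trace: KineticTrace) -> dict:
    """4PL fit of a competition trace; returns apparent IC50 and Hill slope.

    X is log10[αP]; zero concentrations are dropped. The apparent Hill slope
    is reported as a magnitude (descending curves fit with a negative sign in
    the logistic parameterisation).
    """
    mask = trace.x > 0
    logx = np.log10(trace.x[mask])
    y = trace.y[mask]
    res = fit("fourpl_inhibition", KineticTrace(logx, y))
    return {
        "ic50_uM": 10.0 ** res.params["LogIC50"],
        "hill_slope": abs(res.params["HillSlope"]),
        "hill_slope_signed": res.params["HillSlope"],
        "fit": res,
    }


def mutant_transform(p: LinkageParameters, desensitization: float) -> LinkageParameters:
    """ISR-desensitised variant: both αP association constants divided by
    ``desensitization`` (> 1); ISRIB affinity untouched (the desensitising
    eIF2Bδ substitutions bind the fluorescent ISRIB probe with wild-type
    affinity)."""
    if desensitization <= 0:
        raise ValueError("desensitization factor must be > 0")
    return replace(
        p,
        k_p1_per_uM=p.k_p1_per_uM / desensitization,
        k_p2_per_uM=p.k_p2_per_uM / desensitization,
        label=f"{p.label}; desensitized x{desensitization:g}",
    )


def gef_activity(p: LinkageParameters, isrib_nM: float, alphaP_uM: float) -> float:
    """Ensemble nucleotide-exchange activity relative to apo eIF2B (in [0, 1])."""
    dist = species_distribution(p, isrib_nM, alphaP_uM)
    return sum(p.activities[STATE_NAMES[k]] * v for k, v in dist.populations.items())


def phosphorylation_timecourse(
    p: LinkageParameters,
    k_phos_per_min: float,
    total_eif2_uM: float,
    probe_isrib_nM: float,
    t_min: Sequence[float] | None = None,
) -> KineticTrace:
    """Fluorescence-polarization proxy signal during gradual eIF2 phosphorylation.

    A kinase introduced at t = 0 converts the eIF2 pool first-order:
    [αP](t) = total·(1 − e^(−k_phos·t)). Binding is assumed to re-equilibrate
    quickly relative to phosphorylation, so the signal at each time point is
    the equilibrium ISRIB-bound fraction at the instantaneous [αP].
    """
    if k_phos_per_min < 0:
        raise ValueError("k_phos must be >= 0")
    t = np.asarray(t_min if t_min is not None else np.linspace(0.0, 60.0, 61), float)
    alphap = total_eif2_uM * (1.0 - np.exp(-k_phos_per_min * t))
    signal = np.array([isrib_occupancy(p, probe_isrib_nM, a) for a in alphap])
    return KineticTrace(t, signal, x_units="min", y_units="fraction bound",
                        meta={"k_phos_per_min": k_phos_per_min,
                              "total_eif2_uM": total_eif2_uM, "label": p.label})


def free_isrib_with_depletion(
    p: LinkageParameters,
    eif2b_total_nM: float,
    isrib_total_nM: float,
    alphaP_uM: float,
) -> float:
    """Free ISRIB concentration solving the conservation equation
    ``total = free + bound_fraction(free)·[eIF2B]`` (bisection).

    Only needed when the probe is not in large excess of Kd⁻¹; the default
    pipeline ignores depletion.
    """
    if isrib_total_nM == 0:
        return 0.0

    def balance(free: float) -> float:
        return free + isrib_occupancy(p, free, alphaP_uM) * eif2b_total_nM - isrib_total_nM

    return float(brentq(balance, 0.0, isrib_total_nM, xtol=1e-12, rtol=1e-12))
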