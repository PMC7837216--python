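# Methods

This note records the models implemented by `eif2btools`, the numerical
choices behind them, what the synthetic data do and do not emulate, and the
known limitations. It is the design rationale for maintainers; the README
shows the user-facing workflow.

## Structure handling and role assignment

Entries are reduced to a Cα trace per polymer chain (plus all ligand atoms).
That is deliberate: every metric the pipeline reports is defined on Cα atoms,
and cryo-EM side chains at 4 Å resolution would add noise, not signal. Both
author and label residue numbering are retained; all selections use author
numbering because that is the numbering the literature quotes (eIF2Bδ helix
α3 = human residues 247–267), with label numbering kept as a fallback for
entries with unusual author schemes.

Chains are assigned to roles (eIF2B α/β/γ/δ/ε, eIF2 α/γ, ISRIB) by global
edit-distance identity against a per-role reference library, with a default
acceptance threshold of 60% identity — far above chance for unrelated
sequences and far below the identity of any correct match, so the exact value
is uncritical. Chains matching nothing are recorded as unassigned warnings
rather than errors (deposited entries may contain tags or fragments). For
deposited entries the library can be bootstrapped from one well-annotated
entry's `_entity.pdbx_description` fields (`reference_library: "entry:7D43"`
in a config). The two protomers are separated geometrically: each β/δ/γ/ε
chain is grouped with the nearer of the two eIF2Bα chains ("unit1" is the α
chain with the lexicographically smaller id, making the tagging
deterministic); if both copies of a role land in one group the assignment
fails loudly. Cross-entry correspondence is by (role, protomer, author
residue number); residues missing in either member of a pair are dropped and
the count used is reported, since unmodelled loops are the norm in these
maps.

The ISRIB pocket shell is defined once, in an entry that actually contains
the ligand (6CAJ among the deposited entries, the fixture's dummy ligand in
tests), as all Cα atoms within 10 Å of any ligand atom, and transferred to
ligand-free entries by residue identity. Membership depends only on internal
distances, so it is invariant under any rigid motion of the reference entry
(a property test enforces this).

## Conformational metrics

Superposition is the classical least-squares rigid fit (Kabsch, via SVD with
a determinant correction to exclude reflections), which attains the global
optimum of the orthogonal Procrustes problem. Point sets with fewer than
three atoms or a second singular value of ~0 (collinear) are rejected. The
test suite checks the RMSD against an independent quaternion-eigenvalue
implementation (Horn's method) to 1e-8 on random point sets — two genuinely
different algorithms for the same optimum.

The helix-axis estimator has two stages. First, for consecutive Cα positions
the second differences d_k = p_{k-1} − 2p_k + p_{k+1} of an ideal helix point
exactly radially, so every cross product d_k × d_l is parallel to the axis;
the sign-aligned mean over all pairs gives a closed-form axis that is exact
on an ideal helix of any length. Second, that axis seeds a least-squares fit
of a full parametric helix (axis tilt, center, radius, phase, rise, twist) to
the trace. The parametric stage is what sets noise performance: with 0.3 Å
Gaussian coordinate noise on a 21-residue helix the axis error stays below
2° (simulated over 100 replicates), whereas purely local estimators
(consecutive cross products, or PCA of the smoothed trace) carry either
several degrees of noise amplification or an O(1°) finite-length bias that
would contaminate rotation angles recovered from rigid motions. Axes are
oriented N→C; the rotation between two entries is the angle between oriented
axes after frame superposition, in [0°, 180°].

Displacement metrics are means of per-atom Euclidean distances over paired
probe Cα atoms after frame alignment. The direction label ("toward"/"away
from" eIF2Bβ) compares the helix-centroid-to-β-centroid distance *within*
each entry — an internal distance needing no alignment — using the
same-protomer β chain; ties within 1e-6 Å give "n/a". δ-α3 metrics are
computed for both protomers and reported per protomer plus mean, because the
published numbers do not say which copy was measured; validation against
published values takes the closer protomer and the comparison table exposes
both. The pocket metric aligns on one βδ half-shell and measures the other;
both orientations are computed for the same reason.

The "four C-terminal domains" alignment frame for deposited entries ships as
config defaults (β 140–345, δ 300–520) because the exact domain boundaries
are not published; the β-only alignment RMSD (published as 0.7 Å for apo vs
the doubly-occupied complex) is the calibration control for these ranges, and
they are user-overridable. All metrics are invariant under arbitrary rigid
motions of either input entry (frame alignment absorbs them); this is
property-tested to 1e-6.

## Regression models

The seven equations are implemented exactly as used by the assays (see
`binding_models` docstrings for the formulas). Fitting choices:

- **Optimizer**: unweighted Levenberg–Marquardt (no weighting scheme is
  published for these assays). Initialisation is data-driven: endpoints for
  Y0/Plateau/Top/Bottom, a log-linearised rate estimate for K, the half-span
  abscissa for midpoint parameters, slope sign from the data for the
  logistic. Five deterministically jittered restarts guard against bad
  starts; the best SSR wins. Noiseless generate→fit round-trips recover every
  parameter of every model to better than 1e-9 relative.
- **Confidence intervals**: t-distribution on the asymptotic standard errors
  from the covariance at the optimum — the convention behind the "95% CI"
  figures these assays report. Calibration is tested by simulation: with 2%
  noise, each true parameter falls inside its reported CI in ≥ 90/100
  simulations for every model.
- **Biphasic fits** are canonicalised to KFast ≥ KSlow after convergence
  (swapping relabels PercentFast as its complement), removing the label
  ambiguity of two-exponential models. The simulated biosensor traces sample
  the fast phase densely; uniform grids with spacing wider than the fast
  half-life leave KFast/PercentFast ill-determined, which is a property of
  the experiment design, not the estimator.
- **4PL convention**: X is log10(concentration), and the midpoint parameter
  is LogIC50, as in the printed formula. Note this parameterisation is
  *increasing* in X for HillSlope > 0, so descending inhibition curves fit
  with a negative HillSlope; apparent Hill slopes are therefore reported as
  magnitudes, matching how steepness is quoted for such curves.
- Fits refuse silently bad outcomes: too few points, non-convergence after
  restarts, and degenerate constant-response inputs raise or flag; R² < 0 is
  flagged.

Derived values: t₁/₂ = ln 2 / K with the CI mapped through the monotone
transform; %Fast-vs-concentration dose responses are fitted with the
hyperbolic agonist model (EC50). At the reported off-rate of 0.74 min⁻¹ the
half-life is 0.937 min.

## Linkage model

Occupancy states (i ∈ {0,1} ISRIB, j ∈ {0,1,2} eIF2(αP)) are weighted by a
binding polynomial with a statistical factor 2 for the first of the two
equivalent regulatory sites, association constants K_I (per nM) and
K_P1/K_P2 (per µM), an αP–αP cooperativity factor c_P, and ISRIB–αP coupling
factors g1, g2 (g < 1 = antagonism; the biology of interest is the hierarchy
g2 ≪ g1 ≤ 1, which makes ISRIB selectively exclude the doubly occupied,
strongly inhibited state). Each state carries a relative GEF activity
(ground ≡ 1; singly occupied states ~0.5 for one sterically blocked catalytic
site; doubly occupied ~0 for the additional allosteric inhibition), and the
ensemble activity is the population-weighted mean.

The treatment is equilibrium-only: the governing rate constants are
experimentally undetermined, and the emulated readouts are steady-state or
slow-relaxation measurements. Time courses assume binding re-equilibrates
fast against first-order phosphorylation of the eIF2 pool. Concentrations
are free-ligand by default — the fluorescent probe is used at 2.5 nM, well
below its ~10 nM Kd scale — with a conservation-aware bisection solver
available for receptor-excess regimes. Populations are validated against a
brute-force microstate enumeration (distinguishable sites, 2×2×2 states),
which doubles as the detailed-balance/path-independence check.

The default parameter set is labelled "illustrative, not fitted" in every
output: association constants on the observed scales (ISRIB Kd ~10 nM,
apparent αP IC50 a few hundred nM), c_P = 50, g1 = 0.5, g2 = 1e-3. Two
qualitative signatures are properties of the model structure, not of tuning:
the simulated competition curve is sigmoid with an apparent Hill magnitude
between 1.5 and 2 whenever double occupancy is effectively cooperative
(bounded above by the two-site stoichiometry), and dividing K_P1/K_P2 by a
desensitisation factor d (the ISR-insensitive eIF2Bδ substitutions, which
keep wild-type ISRIB affinity) right-shifts the apparent IC50 by ~d.
Whether the quadruply-ligated state IV is merely rare or strictly forbidden
is left to the user (set g2 = 0-adjacent or larger); the default keeps it
allowed but strongly disfavoured.

## Synthetic data

The structural fixture is ten ideal poly-Cα helices arranged with two-fold
pseudo-symmetry, a δ chain numbered to contain the 247–267 probe helix, and
a three-atom dummy ligand on the symmetry axis between the β/δ chains of
both protomers. It is deliberately non-physical — it exercises parsing,
role/protomer assignment, selection, and geometry against analytically known
answers, not biology. Helices are kept ideal (seeds vary placements, phases
and sequences, not atom-level jitter) so that injected motions have exact
expected values: the motion ledger records mean ‖T(p) − p‖ over the moved
atoms and the angle between a helix's construction axis and its image under
the injected rotation, both computed in the generator, never by the pipeline
under test. Closure of pipeline against ledger holds to ~1e-7 (the residual
is mmCIF round-off), tested at translations of 0.5–4 Å and rotations of
2–15°.

Simulated traces are the exact model curves plus seeded Gaussian noise
(default σ = 2% of curve span); regeneration with the same ledger is
bit-identical. The default trace set uses the reported assay values as true
parameters (k_off 0.74 min⁻¹; IC50 0.25 µM with Hill 2.4; K_half 15.2 nM
total-binding and 29.8 nM specific-binding; %Fast 75 biphasic dissociation;
EC50 1.8 nM dose response). What passing these tests shows is that the
estimators are correct and calibrated *under the stated noise model*;
real traces carry instrument drift, correlated noise, and depletion effects
that the generator does not emulate.

Problem sizes throughout (25–30 points per trace, 100 Monte-Carlo replicates
per model, 100 oracle point-sets, one fixture per motion) were chosen so the
complete no-download suite runs in well under two minutes on one CPU while
keeping the binomial noise on coverage counts small against the 90/100
acceptance line.

## Limitations

- Reproduction of the published structural metrics requires the deposited
  mmCIF entries; they are fetched once over HTTPS and cached, never bundled.
  The frame-range defaults were chosen against the published β-RMSD control
  and remain config, not fact.
- The linkage model is a minimal two-site-plus-effector scheme: no
  decamer/tetramer assembly equilibria, no kinetics, no global fitting of
  its parameters to experimental curves (the underlying datasets are not
  deposited in numeric form).
- Regression fitting is per-trace; shared-parameter global fits across
  concentration series are out of scope.
- The mmCIF writer emits Cα-only models; it is a fixture format, not a
  general-purpose structure exporter.
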