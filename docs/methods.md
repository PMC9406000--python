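# Methods

## Scope and data model

The package analyses assigned titration peak lists; it performs no
spectral processing, peak picking, or exchange-regime classification.
Its in-memory objects mirror the experiment: a `ShiftTable` is one
titration point (one assigned ¹⁵N/¹H peak per residue, prolines
excluded, plus condition metadata in mM/ppm/°C), a `CSPProfile` holds
per-residue shift differences relative to the apo reference across all
points, a `SiteFit` is the global fit of one binding site, and a
`PersistenceProfile` summarises ion contacts over a trajectory.

Condition metadata (ligand and protein concentration, pH, NaCl) is
supplied by the caller or a conditions CSV, never parsed from Sparky
lists, which do not carry it. Residue numbering is taken verbatim from
the assignment strings (for TTR, mature-protein numbering 1–127). The
Sparky reader accepts the `D99N-H`, `D99N-HN`, `D99NH` and bare `D99`
assignment dialects; by default w1 is ¹⁵N and w2 is ¹H, with an
`axis_order="hn"` switch for lists exported with the opposite
convention. Dilution over a titration is neglected (stock additions are
kept to ≈1.5% total volume in the emulated design); the simulator's
concentrations are exact.

## Combined CSP and the significance rule

The combined amide CSP is Δδ = √(ΔδH² + (ΔδN/s)²) with the ¹⁵N divisor
s = 6.5 by default (configurable; 5 is also common in the literature).
Profiles are always computed relative to the zero-ligand reference, so
Δδ at the reference point is identically zero and Δδ ≥ 0 everywhere.
Residues missing from the reference are excluded with a warning;
residues missing at an individual point are marked untracked at that
point only and skipped by downstream statistics.

Significance at a chosen titration point flags residues with
Δδ > mean + 2·sd, where mean and sd run over *tracked* residues only
and sd is the sample (n−1) standard deviation — conventional for small
residue panels; the comparison is strict so a zero-variance panel flags
nothing.

Calibration caveat: Δδ under pure peak-position noise is the magnitude
of a 2-D Gaussian (Rayleigh-like), whose probability of exceeding
mean + 2·sample-sd is ≈4% per residue. An n-residue null panel is
therefore entirely clean with probability ≈0.96ⁿ — about 80% at n = 10
and near zero at n = 100. The mean + 2σ rule is a ranking heuristic,
not a false-positive-controlled test, and the test suite measures this
honestly rather than asserting a cleaner behaviour than the rule has.
Cross-referencing flags against a salt control (below) is the intended
guard against over-interpretation.

## Salt specificity

To separate specific cation binding from generic electrostatic
screening, a cation titration is compared with a salt (NaCl) control at
a matched concentration (nearest point within 10%). The summary
statistic is the control's mean ± sd amide-proton shift — the
conventional bulk-salt-effect number — and the cation-specific set is
flagged(test) \ flagged(control).

## Global Kd fitting

The 1:1 bound fraction is evaluated as 2·L₀/(S + √(S² − 4·T₀·L₀)) with
S = T₀ + L₀ + K_d, algebraically identical to the quadratic-root form
but immune to catastrophic cancellation at µM protein (T₀ ≪ K_d), the
regime of these experiments. T₀ is *monomeric* protein concentration;
the CLI can convert from tetramer units (×4).

A site's residues are fitted jointly — one shared K_d, one Δδ_max per
residue, observable = combined CSP — by `scipy.optimize.least_squares`
(trust-region reflective, bounds K_d ∈ (0, 10⁴] mM, Δδ_max ∈ [0, 10]
ppm, xtol = ftol = 1e-14). The fit is multi-started from the
concentration of half-maximal mean CSP plus three log-spaced K_d
guesses spanning the titration range, keeping the lowest-cost solution;
zero-ligand observations are included (they pin the baseline). Each
residue must be tracked at ≥3 points, and the total observation count
must reach the parameter count, else a hard error; optimiser
non-convergence is reported in the `converged` flag rather than raised.

Standard errors come from the Jacobian-based covariance
(JᵀJ)⁻¹·RSS/(n−p) at the optimum; R² = 1 − RSS/SS_tot is pooled over
all residue-point observations. The reported p-value is an F-test of
the fitted model against the all-zero model on the pooled observations
— one defensible reading of a per-site fit p-value, chosen because no
standard definition exists for this quantity; it should be read as
"does this site shift at all", not as a model-comparison statistic.

## Occupancy and screening

At free-ligand concentration L the ligand-excess occupancy is
L/(L + K_d) (valid when ligand ≫ protein, as in plasma). Percentages
and fold changes round half away from zero. The default physiological
reference is 2.4 mM free Ca²⁺; with the physiological-salt site-1
K_d of 32.7 mM this gives 6.8% ≈ 7% bound protein, and the low-salt
(8.7 mM) vs physiological-salt K_d pair gives the ≈4-fold screening
factor. The occupancy report prints the site-2 estimate alongside
site-1, since either site's constant could plausibly anchor the in-vivo
estimate.

## Trajectory contact persistence

A residue is in contact in a frame when the minimum distance between
its atoms (scope: all / side-chain / backbone; hydrogens included by
default, excludable) and any ion is ≤ 3.5 Å — the first-shell
criterion for Ca²⁺. Persistence is the exact rational
contact-frames/total-frames; the persistent set uses strict > against
the 0.5 default threshold, so exactly-50% residues are excluded. Ions
are selected by *residue* name ({CA, CAL} by default) to avoid the PDB
collision between Cα atom names and Ca²⁺. Coordinates are assumed
wrapped; no periodic minimum-image correction is applied, and a warning
is raised if a distance exceeds the box diagonal when box information
is present. Multi-model PDB reading and writing go through biotite;
models must have matching atom counts, and a file without MODEL records
is treated as a single frame with a warning.

## Synthetic data: what it emulates and what it does not

`simulate_titration` reproduces the study design: 8 points at 0, 5, 10,
20, 40, 60, 80, 100 mM ligand; 0.1 mM monomeric protein; per-residue
peak positions base + Δδ_max·b(L) + ε with independent homoscedastic
Gaussian ε (σ_H = 0.002, σ_N = 0.01 ppm — the digital resolution of a
well-sampled 2D correlation spectrum); optional per-point dropout for
untrackable residues (never at the reference). Preset scenarios: a
low-salt two-site system (K_d 8.7 and 13.5 mM), a screened single site
(32.7 mM at 154 mM NaCl) with attenuated amplitudes, and an inert NaCl
control. True per-residue amplitudes are not experimentally known, so
the presets use plausible synthetic values giving combined amplitudes
of 0.05–0.3 ppm; the default inert panel is 20 residues, a scaled-down
stand-in for the ~100-residue panels of a real protein. Not emulated:
lineshapes, peak overlap, slow/intermediate exchange, systematic drift,
correlated noise — so passing tests demonstrate correctness of the
estimators under the stated noise model, not robustness to spectral
artefacts.

`simulate_trajectory` is a geometric construction, not physics: single
atom residues on a 10 Å line, one ion placed at 0.9·cutoff
(perpendicular to the line) of the target residue in exactly the
prescribed frames and parked >3·cutoff away otherwise, making target
fractions exact by construction. One free ion can satisfy fraction sums
≤ 1 only; infeasible prescriptions raise unless the cutoff is large
enough (≥ half the grid spacing) for a shared midpoint placement.

## Problem sizes and determinism

Simulation-based checks use 50 seeds for Kd-recovery statistics, 100
seeds for null-rule calibration, and ≤100-frame toy trajectories —
sizes at which the sampling distributions of the reported medians and
fractions are already stable. All generators draw from a single
`numpy.random.default_rng(seed)`; identical seeds reproduce outputs
bit-for-bit, and the pipeline report separates deterministic results
from run metadata (timestamps) so repeated runs are byte-comparable.

## Known limitations

- Each site is fitted independently with 1:1 stoichiometry; no
  competitive, cooperative, or ternary (protein–ligand–salt) models.
- Salt screening enters only as separate fits per condition, not as a
  thermodynamic ionic-strength model.
- The mean + 2σ rule's false-positive behaviour scales with panel size
  (see above).
- Peak matching is by assignment only; no nearest-neighbour tracking of
  unassigned peaks.
- No kinetic information (k_on, k_off, exchange rates) is extracted.
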