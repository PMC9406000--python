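# shiftbind

Quantitative analysis of weak protein–ion binding by NMR chemical-shift
perturbation (CSP), built around the low-affinity association of Ca²⁺ with
the plasma transport protein transthyretin (TTR): per-residue combined amide
CSP profiling across a ligand titration, mean + 2σ significance flagging,
global per-site dissociation-constant fitting with the exact 1:1 binding
isotherm, cation-vs-salt specificity comparison, MD ion-contact persistence
analysis, and physiological occupancy estimation.

It is written for NMR spectroscopists and structural biologists who have
assigned 2D ¹H–¹⁵N peak lists from a titration series and want the numbers
that follow from them — Kd ± SE per binding site, flagged residues,
occupancy at physiological ligand concentration — plus a synthetic-data
generator with known ground truth for validating every stage, since raw
titration spectra for this system are not publicly deposited.

## The model

Under fast exchange each backbone amide shows one peak at the
population-weighted average of its free and bound positions. The combined
CSP of a residue relative to the apo reference is

```
Δδ = √( ΔδH² + (ΔδN / 6.5)² )          [ppm]
```

Residues with Δδ above the panel mean + 2σ are flagged as significantly
perturbed. For a 1:1 equilibrium P + L ⇌ PL with dissociation constant
K_d, mass balance on total protein T₀ and total ligand L₀ gives the exact
bound fraction

```
b(L₀) = ( T₀ + L₀ + K_d − √((T₀ + L₀ + K_d)² − 4·T₀·L₀) ) / (2·T₀)
```

and the observed CSP is Δδ_obs = Δδ_max · b(L₀). The residues of one
binding site are fitted globally — one shared K_d, one Δδ_max per residue —
by trust-region nonlinear least squares. At µM protein and mM K_d this
reduces to the hyperbola L/(L + K_d), which is also the occupancy of the
site at free-ligand concentration L.

For MD trajectories, a residue's contact persistence is the fraction of
frames with an ion within 3.5 Å of any of its atoms; residues above 50%
(strictly) are persistent interactors.

## Worked example

```python
import shiftbind as sb

# synthetic two-site titration with known truth: Kd 8.7 and 13.5 mM,
# 0.1 mM monomeric protein, ligand 0–100 mM, realistic peak noise
tables, truth = sb.simulate_titration(sb.two_site_spec(seed=1))

profile = sb.build_profile(tables)                    # combined CSPs vs apo
sig = sb.significance(profile, len(profile.points) - 1)
fit = sb.fit_site(profile, sb.TTR_SITES["site-1"])    # global 1:1 fit
print(sorted(sig.flagged), fit)

est = sb.fraction_bound(2.4, 32.7)                    # physiological Ca²⁺
ratio, fold = sb.kd_ratio(32.7, 8.7)                  # salt screening
print(est.percent, fold)
```

prints

```
[10, 99] SiteFit(site-1: Kd = 8.6 ± 0.1 mM, R² = 1.000, p = 3.1e-28)
7 4
```

i.e. the largest-amplitude reporters of the two sites are flagged, the
shared site-1 Kd is recovered within its standard error, about 7% of the
protein is Ca²⁺-bound at a physiological 2.4 mM with the salt-screened
Kd of 32.7 mM, and raising NaCl to physiological levels screens the
site-1 affinity roughly 4-fold (32.7/8.7 mM).

The same stages are scripted as a narrative under `analysis/`
(`01_simulate_titrations.py` → `06_trajectory_contacts.py`), each writing
its tables under `results/`, and are available from a shell via the
`shiftbind` CLI (subcommands `csp`, `fit`, `occupancy`, `contacts`,
`simulate-titration`, `simulate-trajectory`, `run`).

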