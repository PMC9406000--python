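"""Exact 1:1 binding isotherm, global per-site Kd fitting and occupancy.

For a single-site equilibrium P + L ⇌ PL with dissociation constant Kd,
mass balance on total protein T0 and total ligand L0 gives the bound
fraction without the ligand-excess approximation:

    b(L0) = (S − sqrt(S² − 4·T0·L0)) / (2·T0),   S = T0 + L0 + Kd,

and the observed CSP of a residue is Δδ_obs = Δδ_max · b(L0).  Residues
assigned to the same binding site share one Kd but keep individual
saturation amplitudes Δδ_max, so a site is fitted globally as a system
of curves with 1 + n_residues free parameters.

At weak (mM) affinity and µM protein the ligand is effectively free and
b reduces to the hyperbola L/(L + Kd), which is also the physiological
occupancy of the site at free-ligand concentration L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import optimize, stats

__all__ = [
    "BindingSiteDef",
    "SiteFit",
    "OccupancyEstimate",
    "isotherm",
    "bound_fraction",
    "fit_site",
    "fraction_bound",
    "kd_ratio",
    "round_half_away",
    "TTR_SITES",
    "load_sites_yaml",
]

KD_BOUNDS = (1e-9, 1e4)  # mM
DMAX_BOUNDS = (0.0, 10.0)  # ppm


@dataclass(frozen=True)
class BindingSiteDef:
    """A named binding site: the residues whose amides report on it."""

    site_id: str
    residues: frozenset[int]

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"site {self.site_id!r} has no residues")
        object.__setattr__(self, "residues", frozenset(self.residues))


#: Transthyretin Ca²⁺ sites (mature-protein numbering 1–127).  Site-1 is
#: the D99/E66 carboxylate site seen crystallographically; site-2 the
#: C10/H56 region reported through R104 and K126; the rest are putative
#: electrostatic sites identified by CSP only.
TTR_SITES: dict[str, BindingSiteDef] = {
    "site-1": BindingSiteDef("site-1", frozenset({66, 99})),
    "site-2": BindingSiteDef("site-2", frozenset({10, 104, 126})),
    "site-3": BindingSiteDef("site-3", frozenset({51})),
    "site-4": BindingSiteDef("site-4", frozenset({62})),
    "site-5": BindingSiteDef("site-5", frozenset({76, 89})),
    "site-6": BindingSiteDef("site-6", frozenset({14, 15, 25, 53, 54, 55, 109})),
}


def load_sites_yaml(path: str | Path) -> dict[str, BindingSiteDef]:
    """Load site definitions from a YAML mapping site_id -> residue list.

    The single key ``ttr_sites`` selects the built-in transthyretin preset.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw == "ttr_sites" or raw == ["ttr_sites"]:
        return dict(TTR_SITES)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping site_id -> residues")
    return {
        str(k): BindingSiteDef(str(k), frozenset(int(r) for r in v))
        for k, v in raw.items()
    }


def bound_fraction(T0: float, L0, kd: float):
    """Exact bound fraction of protein from the quadratic mass balance.

    Evaluated as 2·L0 / (S + sqrt(S² − 4·T0·L0)) to avoid the
    catastrophic cancellation of the textbook (S − sqrt)/2T0 form at
    small T0.  Accepts scalar or array L0.
    """
    if T0 <= 0:
        raise ValueError(f"protein concentration T0 must be > 0, got {T0}")
    if kd < 0:
        raise ValueError(f"kd must be >= 0, got {kd}")
    L0 = np.asarray(L0, dtype=float)
    if np.any(L0 < 0):
        raise ValueError("ligand concentration must be >= 0")
    S = T0 + L0 + kd
    disc = S * S - 4.0 * T0 * L0
    b = 2.0 * L0 / (S + np.sqrt(np.maximum(disc, 0.0)))
    return b[()]


def isotherm(T0: float, L0, kd: float, dmax: float):
    """Observed CSP (ppm) at total ligand L0: Δδ_max times the exact
    1:1 bound fraction."""
    return dmax * bound_fraction(T0, L0, kd)


@dataclass
class SiteFit:
    """Global fit result for one binding site."""

    site_id: str
    kd: float
    kd_se: float
    dmax: dict[int, float]
    dmax_se: dict[int, float]
    r_squared: float
    p_value: float
    n_obs: int
    converged: bool
    residues: tuple[int, ...]
    T0: float
    rss: float = math.nan
    message: str = ""

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"SiteFit({self.site_id}: Kd = {self.kd:.1f} ± {self.kd_se:.1f} mM, "
            f"R² = {self.r_squared:.3f}, p = {self.p_value:.2g})"
        )


def _gather_observations(profile, site: BindingSiteDef):
    """Per-residue (ligand_conc, delta_combined) arrays over tracked points."""
    concs = profile.ligand_concs
    obs: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for resnum in sorted(site.residues):
        if resnum not in profile.records:
            raise ValueError(
                f"site {site.site_id!r}: residue {resnum} absent from profile"
            )
        rec = profile.records[resnum]
        mask = rec.tracked & np.isfinite(rec.delta_combined)
        if mask.sum() < 3:
            raise ValueError(
                f"site {site.site_id!r}: residue {resnum} tracked at only "
                f"{int(mask.sum())} points (need >= 3)"
            )
        obs[resnum] = (concs[mask], rec.delta_combined[mask])
    return obs


def _kd_starts(obs: Mapping[int, tuple[np.ndarray, np.ndarray]]) -> list[float]:
    """Initial Kd guesses: concentration of half-maximal mean CSP plus
    log-spaced alternatives to escape local minima."""
    all_L = np.concatenate([L for L, _ in obs.values()])
    Lmax = float(all_L.max())
    mean_by_conc: dict[float, list[float]] = {}
    for L, y in obs.values():
        for li, yi in zip(L, y):
            mean_by_conc.setdefault(float(li), []).append(float(yi))
    concs = sorted(mean_by_conc)
    means = np.array([np.mean(mean_by_conc[c]) for c in concs])
    half = means.max() / 2.0
    above = [c for c, m in zip(concs, means) if m >= half and c > 0]
    kd_half = above[0] if above else Lmax / 2.0
    starts = [kd_half] + list(np.geomspace(max(Lmax / 50.0, 1e-3), Lmax * 2.0, 3))
    return [float(np.clip(s, *KD_BOUNDS)) for s in starts]


def fit_site(profile, site: BindingSiteDef, T0: float | None = None) -> SiteFit:
    """Globally fit one site's residues with a shared Kd.

    Minimises Σ_{r,i} (Δδ_obs(r, i) − Δδ_max,r · b(L_i; T0, Kd))² by
    trust-region-reflective least squares, multi-started over Kd.
    Standard errors come from the Jacobian-based covariance scaled by the
    residual variance; R² is pooled over all residue-point observations;
    the p-value is an F-test of the fitted model against the all-zero
    model.  Non-convergence is reported in the result, not raised.
    """
    if T0 is None:
        T0 = profile.reference.protein_conc_monomer
    if T0 <= 0:
        raise ValueError(f"protein concentration T0 must be > 0, got {T0}")
    obs = _gather_observations(profile, site)
    residues = sorted(obs)
    n_obs = int(sum(len(L) for L, _ in obs.values()))
    n_par = 1 + len(residues)
    if n_obs < n_par:
        raise ValueError(
            f"site {site.site_id!r}: {n_obs} observations for {n_par} parameters"
        )

    y_all = np.concatenate([obs[r][1] for r in residues])

    def residual(theta: np.ndarray) -> np.ndarray:
        kd = theta[0]
        out = []
        for j, r in enumerate(residues):
            L, y = obs[r]
            out.append(isotherm(T0, L, kd, theta[1 + j]) - y)
        return np.concatenate(out)

    lo = np.array([KD_BOUNDS[0]] + [DMAX_BOUNDS[0]] * len(residues))
    hi = np.array([KD_BOUNDS[1]] + [DMAX_BOUNDS[1]] * len(residues))

    best = None
    for kd0 in _kd_starts(obs):
        dmax0 = [
            float(np.clip(obs[r][1].max(), 1e-6, DMAX_BOUNDS[1])) for r in residues
        ]
        x0 = np.clip(np.array([kd0] + dmax0), lo, hi)
        try:
            res = optimize.least_squares(
                residual, x0, bounds=(lo, hi), method="trf", xtol=1e-14, ftol=1e-14
            )
        except Exception:  # pragma: no cover - pathological start
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError(f"site {site.site_id!r}: optimiser failed at every start")

    theta = best.x
    rss = float(2.0 * best.cost)
    dof = n_obs - n_par
    # covariance from J^T J at the optimum, scaled by residual variance
    J = best.jac
    try:
        cov = np.linalg.pinv(J.T @ J) * (rss / dof if dof > 0 else np.nan)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:  # pragma: no cover
        se = np.full(n_par, np.nan)

    ss_tot = float(np.sum((y_all - y_all.mean()) ** 2))
    r_squared = 1.0 - rss / ss_tot if ss_tot > 0 else float("nan")
    r_squared = float(np.clip(r_squared, 0.0, 1.0))

    ss_zero = float(np.sum(y_all**2))
    if dof > 0 and rss > 0:
        f_stat = ((ss_zero - rss) / n_par) / (rss / dof)
        p_value = float(stats.f.sf(max(f_stat, 0.0), n_par, dof))
    else:
        p_value = 0.0 if ss_zero > rss else 1.0
    p_value = min(max(p_value, np.finfo(float).tiny), 1.0)

    return SiteFit(
        site_id=site.site_id,
        kd=float(theta[0]),
        kd_se=float(se[0]),
        dmax={r: float(theta[1 + j]) for j, r in enumerate(residues)},
        dmax_se={r: float(se[1 + j]) for j, r in enumerate(residues)},
        r_squared=r_squared,
        p_value=p_value,
        n_obs=n_obs,
        converged=bool(best.status > 0),
        residues=tuple(residues),
        T0=float(T0),
        rss=rss,
        message=best.message,
    )


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (not banker's)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass(frozen=True)
class OccupancyEstimate:
    """Ligand-excess occupancy of a site at free-ligand concentration L."""

    ligand_conc: float
    kd: float
    fraction_bound: float
    percent: int


def fraction_bound(ligand_conc: float, kd: float) -> OccupancyEstimate:
    """Occupancy L/(L + Kd) in the ligand-excess limit (free ≈ total),
    with the percentage rounded half away from zero."""
    if kd <= 0:
        raise ValueError(f"kd must be > 0, got {kd}")
    if ligand_conc < 0:
        raise ValueError(f"ligand_conc must be >= 0, got {ligand_conc}")
    frac = ligand_conc / (ligand_conc + kd)
    return OccupancyEstimate(
        ligand_conc=ligand_conc,
        kd=kd,
        fraction_bound=frac,
        percent=round_half_away(100.0 * frac),
    )


def kd_ratio(kd_a: float, kd_b: float) -> tuple[float, int]:
    """Fold change kd_a / kd_b and its nearest-integer rounding
    (half away from zero)."""
    if kd_b <= 0:
        raise ValueError(f"kd_b must be > 0, got {kd_b}")
    if kd_a <= 0:
        raise ValueError(f"kd_a must be > 0, got {kd_a}")
    ratio = kd_a / kd_b
    return ratio, round_half_away(ratio)
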