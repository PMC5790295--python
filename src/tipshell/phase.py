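"""Stability phase diagram, bifurcation boundary and size-control tables.

Maps trajectory outcomes over the (gamma, lambda_X/lambda_m) control plane,
locates the critical feedback strength gamma* separating unstable (apical
thinning / lysis) from stable steady growth by bisection, and tabulates the
predicted projection radius R against the exocytosis length scale lambda_X
and the feedback strength gamma (size control: R grows with lambda_X, and is
nearly independent of gamma).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dynamics import Outcome, TrajectoryRecord, run_to_outcome
from .params import (
    DimensionlessParameters,
    NumericsConfig,
    PhysicalParameters,
    nondimensionalize,
)

__all__ = [
    "PhaseDiagram",
    "StabilityBoundary",
    "CriticalGamma",
    "RadiusScaling",
    "BracketingError",
    "sweep",
    "critical_gamma",
    "radius_scaling_table",
    "DEFAULT_GAMMAS",
    "DEFAULT_LAM_RATIOS",
]

log = logging.getLogger(__name__)

#: default (coarse) acceptance grid -- each cell is a full PDE run
DEFAULT_GAMMAS = (0.0, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0)
DEFAULT_LAM_RATIOS = (0.1, 0.3, 1.0, 3.0, 10.0)


class BracketingError(ValueError):
    """Bisection bracket endpoints do not straddle the stability boundary."""


class RunCache:
    """Memoises run_to_outcome by (parameters, numerics); sweeps are
    embarrassingly parallel and resumable, so results must be independent of
    execution order."""

    def __init__(self) -> None:
        self._store: dict = {}

    @staticmethod
    def key(p: DimensionlessParameters, numerics: NumericsConfig):
        return (tuple(sorted(p.to_dict().items())),
                tuple(sorted(numerics.to_dict().items())))

    def run(self, p: DimensionlessParameters,
            numerics: NumericsConfig) -> TrajectoryRecord:
        k = self.key(p, numerics)
        if k not in self._store:
            self._store[k] = run_to_outcome(p, numerics)
        return self._store[k]


_GLOBAL_CACHE = RunCache()


@dataclass
class PhaseDiagram:
    """Outcome labels (and observables where STABLE) on a parameter grid."""

    table: pd.DataFrame
    numerics: NumericsConfig
    base: DimensionlessParameters

    def outcome(self, gamma: float, lam_ratio: float) -> Outcome:
        t = self.table
        row = t[(t.gamma == gamma) & (t.lam_ratio == lam_ratio)]
        if len(row) != 1:
            raise KeyError(f"no unique grid point ({gamma}, {lam_ratio})")
        return Outcome(row.outcome.iloc[0])

    @property
    def n_stable(self) -> int:
        return int((self.table.outcome == Outcome.STABLE.value).sum())


@dataclass(frozen=True)
class CriticalGamma:
    """Bisection result for one lam_ratio."""

    lam_ratio: float
    gamma_star: float
    bracket: tuple[float, float]  #: (unstable side, stable side)
    tol: float
    n_runs: int


@dataclass
class StabilityBoundary:
    """Critical-gamma curve gamma*(lam_ratio)."""

    points: list[CriticalGamma] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"lam_ratio": c.lam_ratio, "gamma_star": c.gamma_star,
              "gamma_lo": c.bracket[0], "gamma_hi": c.bracket[1],
              "tol": c.tol} for c in self.points])


def sweep(
    gammas=DEFAULT_GAMMAS,
    lam_ratios=DEFAULT_LAM_RATIOS,
    numerics: NumericsConfig | None = None,
    base: DimensionlessParameters | None = None,
    cache: RunCache | None = None,
) -> PhaseDiagram:
    """Classify every (gamma, lam_ratio) grid point by a full simulation.

    Individual failures are recorded per point (outcome TIMEOUT with the
    error message) and never abort the sweep.
    """
    numerics = numerics if numerics is not None else NumericsConfig()
    base = base if base is not None else DimensionlessParameters(1.0, 1.0)
    cache = cache if cache is not None else _GLOBAL_CACHE
    rows = []
    for lam in lam_ratios:
        for g in gammas:
            p = replace(base, gamma=float(g), lam_ratio=float(lam))
            try:
                rec = cache.run(p, numerics)
                out, err = rec.outcome, rec.error
            except Exception as exc:  # defensive: never abort a sweep
                rec, out, err = None, Outcome.TIMEOUT, f"{type(exc).__name__}: {exc}"
                log.warning("sweep point (%g, %g) failed: %s", g, lam, err)
            row = {"gamma": g, "lam_ratio": lam, "outcome": out.value,
                   "t_end": rec.t[-1] if rec is not None else np.nan,
                   "error": err or ""}
            obs = rec.profile.observables if (rec and rec.profile) else None
            for k in ("R", "H", "eps0", "kappa0", "rhoA0", "rhoI0", "tip_speed"):
                row[k] = getattr(obs, k) if obs else np.nan
            rows.append(row)
    return PhaseDiagram(table=pd.DataFrame(rows), numerics=numerics, base=base)


def _is_stable(p: DimensionlessParameters, numerics: NumericsConfig,
               cache: RunCache) -> bool:
    rec = cache.run(p, numerics)
    if rec.outcome is Outcome.STABLE:
        return True
    if rec.outcome is Outcome.LYSIS_THINNING:
        return False
    if rec.outcome is Outcome.TIMEOUT:
        # critical slowing down: near-boundary runs may exhaust t_max
        # without classifying; count them as not-yet-stable so the returned
        # gamma* bounds the strength guaranteeing steady growth within t_max
        log.warning("TIMEOUT at gamma=%g, lam_ratio=%g treated as unstable "
                    "side of the boundary", p.gamma, p.lam_ratio)
        return False
    raise BracketingError(
        f"outcome {rec.outcome.value} at gamma={p.gamma}, "
        f"lam_ratio={p.lam_ratio} is neither stable nor thinning; "
        "choose a bracket crossing the lysis boundary")


def critical_gamma(
    lam_ratio: float,
    bracket: tuple[float, float],
    tol: float = 0.25,
    numerics: NumericsConfig | None = None,
    base: DimensionlessParameters | None = None,
    cache: RunCache | None = None,
) -> CriticalGamma:
    """Bisect the critical feedback strength gamma*(lam_ratio).

    ``bracket`` = (gamma_unstable, gamma_stable); the lower endpoint must
    classify as LYSIS_THINNING and the upper as STABLE, otherwise a
    BracketingError is raised.  Converges in ceil(log2(width/tol)) runs.
    """
    numerics = numerics if numerics is not None else NumericsConfig()
    base = base if base is not None else DimensionlessParameters(1.0, 1.0)
    cache = cache if cache is not None else _GLOBAL_CACHE
    lo, hi = float(bracket[0]), float(bracket[1])
    if not lo < hi:
        raise ValueError("bracket must be (low, high) with low < high")

    def stable(g: float) -> bool:
        return _is_stable(replace(base, gamma=g, lam_ratio=float(lam_ratio)),
                          numerics, cache)

    n_runs = 2
    if stable(lo) or not stable(hi):
        raise BracketingError(
            f"bracket ({lo}, {hi}) does not straddle the boundary at "
            f"lam_ratio={lam_ratio}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        n_runs += 1
        if stable(mid):
            hi = mid
        else:
            lo = mid
    return CriticalGamma(lam_ratio=float(lam_ratio),
                         gamma_star=0.5 * (lo + hi), bracket=(lo, hi),
                         tol=float(tol), n_runs=n_runs)


@dataclass
class RadiusScaling:
    """R over a (lambda_X, gamma) grid plus its summary statistics."""

    table: pd.DataFrame  #: columns lambda_X, gamma, lam_ratio, R (dimensional), R_hat
    slope: float  #: least-squares slope of R vs lambda_X (pooled over gamma)
    intercept: float
    r_squared: float
    max_rel_spread: float  #: max over lambda_X of R spread across gamma


def radius_scaling_table(
    lambda_X_values,
    gamma_values,
    base: PhysicalParameters,
    numerics: NumericsConfig | None = None,
    cache: RunCache | None = None,
) -> RadiusScaling:
    """Dimensional projection radius R over a (lambda_X, gamma) grid.

    All physical parameters except lambda_X and Gamma are held at ``base``;
    lam_ratio therefore co-varies linearly with lambda_X.  Non-stable points
    are excluded with a warning.  Reports the pooled least-squares fit of
    R against lambda_X and the maximal relative spread of R across gamma at
    fixed lambda_X (the paper's size-control statistics).
    """
    numerics = numerics if numerics is not None else NumericsConfig()
    cache = cache if cache is not None else _GLOBAL_CACHE
    rows = []
    for lamX in lambda_X_values:
        for g in gamma_values:
            phys = replace(base, lambda_X=float(lamX), Gamma=float(g))
            p = nondimensionalize(phys)
            rec = cache.run(p, numerics)
            if rec.outcome is not Outcome.STABLE:
                log.warning("excluding non-stable point lambda_X=%g gamma=%g "
                            "(%s)", lamX, g, rec.outcome.value)
                continue
            R_hat = rec.profile.observables.R
            rows.append({"lambda_X": lamX, "gamma": g,
                         "lam_ratio": p.lam_ratio, "R_hat": R_hat,
                         "R": R_hat * phys.length_scale})
    df = pd.DataFrame(rows)
    if len(df) < 2 or df.lambda_X.nunique() < 2:
        raise ValueError("need stable points at >= 2 lambda_X values")
    A = np.vstack([df.lambda_X, np.ones(len(df))]).T
    coef, *_ = np.linalg.lstsq(A, df.R, rcond=None)
    pred = A @ coef
    ss_res = float(np.sum((df.R - pred) ** 2))
    ss_tot = float(np.sum((df.R - df.R.mean()) ** 2))
    spread = 0.0
    for lamX, grp in df.groupby("lambda_X"):
        if len(grp) > 1:
            spread = max(spread, float((grp.R.max() - grp.R.min()) / grp.R.mean()))
    return RadiusScaling(table=df, slope=float(coef[0]),
                         intercept=float(coef[1]),
                         r_squared=1.0 - ss_res / ss_tot,
                         max_rel_spread=spread)
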