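"""Candidate count models for patch density versus patch area and landscape.

Eight models (D1-D8) combine two component kinds over the three landscape
classes (50 / 30 / 10 % forest cover):

* ``CONSTANT_NB`` — density is negative-binomial with a constant mean
  (log-scale intercept plus a dispersion parameter k; var = mu + mu^2/k),
  used where no patch-area effect is postulated (counts are over-dispersed
  there);
* ``LINEAR_POIS`` — density is Poisson with log mean linear in log10(patch
  area in ha).

Each component contributes 2 parameters.  D1/D2 pool all landscapes into a
single global component; D3-D8 assign one component per landscape, with the
area effect placed in none, all, or particular landscapes.  The model
log-likelihood is the sum of independently fitted component log-likelihoods,
and models are ranked by AICc over n = number of patches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats, special

from .capture_data import DensityRecord, VALID_LANDSCAPES
from . import model_selection

K_CAP = 1e6  # dispersion bound: beyond this the NB is indistinguishable from Poisson
_GRADIENT_TOL = 1e-8


class ComponentKind(Enum):
    CONSTANT_NB = "constant_nb"
    LINEAR_POIS = "linear_pois"


@dataclass(frozen=True)
class ComponentSpec:
    """One component function and the landscape classes it covers.

    A multi-landscape scope pools the covered landscapes into one shared
    component (used by the global models D1/D2 only); per-landscape effects
    are expressed as separate single-landscape components, so slopes and
    dispersions are never shared across landscapes within D3-D8.
    """

    kind: ComponentKind
    scope: frozenset[int]

    def __post_init__(self) -> None:
        if not self.scope or not self.scope <= set(VALID_LANDSCAPES):
            raise ValueError(f"scope must be a nonempty subset of {VALID_LANDSCAPES}")

    @property
    def n_params(self) -> int:
        return 2  # intercept+slope (linear) or log-mean+dispersion (constant)


@dataclass(frozen=True)
class DensityModelSpec:
    model_id: str
    components: tuple[ComponentSpec, ...]

    def __post_init__(self) -> None:
        covered: list[int] = []
        for c in self.components:
            covered.extend(c.scope)
        if sorted(covered) != sorted(VALID_LANDSCAPES):
            raise ValueError(
                f"{self.model_id}: component scopes must cover each landscape "
                "exactly once"
            )

    @property
    def k(self) -> int:
        return sum(c.n_params for c in self.components)


@dataclass
class ComponentFit:
    spec: ComponentSpec
    intercept: float          # log-scale intercept (log mean for constant)
    slope: float              # per unit log10(area); 0 for constant components
    dispersion: float | None  # NB size k; None for Poisson components
    loglik: float
    boundary: bool = False    # MLE on the parameter-space boundary


@dataclass
class DensityFit:
    spec: DensityModelSpec
    components: list[ComponentFit]
    loglik: float
    aicc: float | None = None
    delta: float | None = None
    weight: float | None = None

    @property
    def boundary(self) -> bool:
        return any(c.boundary for c in self.components)


def candidate_set() -> list[DensityModelSpec]:
    """The eight candidate models.

    D1 global constant; D2 global linear; D3 per-landscape constants;
    D4 per-landscape linears; D5-D8 mix the area effect into particular
    landscapes (D5: 50%; D6: 30% and 10%; D7: 50% and 30%; D8: 30% only).
    """
    C, L = ComponentKind.CONSTANT_NB, ComponentKind.LINEAR_POIS

    def comp(kind: ComponentKind, *scope: int) -> ComponentSpec:
        return ComponentSpec(kind=kind, scope=frozenset(scope))

    def per_landscape(kinds: dict[int, ComponentKind]) -> tuple[ComponentSpec, ...]:
        return tuple(comp(kinds[ls], ls) for ls in (50, 30, 10))

    return [
        DensityModelSpec("D1", (comp(C, 50, 30, 10),)),
        DensityModelSpec("D2", (comp(L, 50, 30, 10),)),
        DensityModelSpec("D3", per_landscape({50: C, 30: C, 10: C})),
        DensityModelSpec("D4", per_landscape({50: L, 30: L, 10: L})),
        DensityModelSpec("D5", per_landscape({50: L, 30: C, 10: C})),
        DensityModelSpec("D6", per_landscape({50: C, 30: L, 10: L})),
        DensityModelSpec("D7", per_landscape({50: L, 30: L, 10: C})),
        DensityModelSpec("D8", per_landscape({50: C, 30: L, 10: C})),
    ]


# ---------------------------------------------------------------------------
# component fits
# ---------------------------------------------------------------------------

def fit_linear_poisson(
    counts: Sequence[int], areas_ha: Sequence[float]
) -> tuple[float, float, float]:
    """MLE of the Poisson log-linear model  log mu = a + b * log10(area).

    Returns ``(intercept, slope, loglik)``; the log-likelihood includes the
    full Poisson mass (factorial term).  All-zero counts give the boundary
    fit (intercept -> -inf, represented as -inf with loglik 0).
    """
    y = np.asarray(counts, dtype=float)
    x = np.log10(np.asarray(areas_ha, dtype=float))
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct areas for a slope")
    if y.sum() == 0:
        return -np.inf, 0.0, 0.0
    X = sm.add_constant(x)
    res = sm.GLM(y, X, family=sm.families.Poisson()).fit(tol=_GRADIENT_TOL)
    a, b = res.params
    ll = float(stats.poisson.logpmf(y, np.exp(a + b * x)).sum())
    return float(a), float(b), ll


def _nb_loglik(y: np.ndarray, mu: float, k: float) -> float:
    # NB2: var = mu + mu^2 / k ; scipy's nbinom(n=k, p=k/(k+mu))
    return float(stats.nbinom.logpmf(y, k, k / (k + mu)).sum())


def fit_constant_nb(counts: Sequence[int]) -> tuple[float, float, float, bool]:
    """MLE of a constant negative-binomial component.

    Returns ``(log_mean, dispersion_k, loglik, boundary)``.  The mean MLE is
    the sample mean exactly; k maximises the profile likelihood by bounded
    1-D search on log k, capped at ``K_CAP`` (flagged) for under-dispersed or
    degenerate data.
    """
    y = np.asarray(counts, dtype=float)
    if len(y) < 2:
        raise ValueError("need n >= 2")
    mu = float(y.mean())
    if mu == 0.0:
        # all zeros: point mass at 0, loglik 0 regardless of k
        return -np.inf, K_CAP, 0.0, True
    res = optimize.minimize_scalar(
        lambda logk: -_nb_loglik(y, mu, np.exp(logk)),
        bounds=(np.log(1e-6), np.log(K_CAP)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    k = float(np.exp(res.x))
    boundary = k > 0.99 * K_CAP or k < 1.01e-6
    if boundary:
        k = K_CAP if k > 1.0 else 1e-6
    return float(np.log(mu)), k, _nb_loglik(y, mu, k), boundary


# ---------------------------------------------------------------------------
# model fitting and selection
# ---------------------------------------------------------------------------

def _subset(records: Sequence[DensityRecord], scope: frozenset[int]):
    sub = [r for r in records if r.landscape_class in scope]
    y = np.array([r.count for r in sub])
    a = np.array([r.area_ha for r in sub])
    return y, a


def fit_model(records: Sequence[DensityRecord], spec: DensityModelSpec) -> DensityFit:
    """Fit one candidate model; loglik is the sum over its components."""
    comps: list[ComponentFit] = []
    for cs in spec.components:
        y, areas = _subset(records, cs.scope)
        if len(y) < 2:
            raise ValueError(f"{spec.model_id}: <2 records in scope {set(cs.scope)}")
        if cs.kind is ComponentKind.LINEAR_POIS:
            a, b, ll = fit_linear_poisson(y, areas)
            comps.append(
                ComponentFit(cs, a, b, None, ll, boundary=not np.isfinite(a))
            )
        else:
            logmu, k, ll, bnd = fit_constant_nb(y)
            comps.append(ComponentFit(cs, logmu, 0.0, k, ll, boundary=bnd))
    return DensityFit(spec=spec, components=comps, loglik=sum(c.loglik for c in comps))


def select(
    records: Sequence[DensityRecord],
    specs: Sequence[DensityModelSpec] | None = None,
) -> tuple[pd.DataFrame, list[DensityFit]]:
    """Fit and rank candidate models by AICc (n = number of patches).

    Models with ``n <= K + 1`` are excluded with a warning column rather than
    failing the whole selection.  Returns the ranked table and the fits
    (table order).
    """
    import warnings

    if specs is None:
        specs = candidate_set()
    if not specs:
        raise ValueError("empty candidate set")
    n = len(records)
    fits: dict[str, DensityFit] = {}
    for spec in specs:
        if n <= spec.k + 1:
            warnings.warn(
                f"model {spec.model_id} excluded: n={n} <= K+1={spec.k + 1}"
            )
            continue
        fits[spec.model_id] = fit_model(records, spec)
    if not fits:
        raise ValueError("no fittable models in the candidate set")
    tab = model_selection.selection_table(
        list(fits.keys()),
        [f.loglik for f in fits.values()],
        [f.spec.k for f in fits.values()],
        n,
    )
    for _, row in tab.iterrows():
        f = fits[row["model"]]
        f.aicc, f.delta, f.weight = row["aicc"], row["delta"], row["weight"]
    ordered = [fits[m] for m in tab["model"]]
    return tab, ordered


def predicted_curves(
    fit: DensityFit, areas_ha: Sequence[float] | None = None
) -> pd.DataFrame:
    """Fitted mean density per landscape over a grid of areas (for plotting)."""
    if areas_ha is None:
        areas_ha = np.geomspace(1, 400, 60)
    areas = np.asarray(areas_ha, dtype=float)
    rows = []
    for comp in fit.components:
        for ls in sorted(comp.spec.scope, reverse=True):
            mu = np.exp(comp.intercept + comp.slope * np.log10(areas))
            for a, m in zip(areas, mu):
                rows.append(
                    {"landscape": ls, "area_ha": a, "mean_density": m,
                     "model": fit.spec.model_id}
                )
    return pd.DataFrame(rows)
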