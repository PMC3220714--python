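"""Joint robust-design likelihood: Huggins closed captures within primary
sessions, Pradel-lambda open dynamics between them.

Within a primary session of K secondary occasions the population is assumed
closed; detection follows a behavioural-response model with first-capture
probability p and recapture probability c per occasion, and the likelihood is
conditioned on capture at least once (Huggins), so abundance N is derived as
M_{t+1} / p* rather than estimated as a parameter.  Between sessions, an
individual's collapsed (per-session) detection history follows an entry/exit
process parameterised by time-constant apparent survival phi and population
rate of change lambda: relative expected abundances E_t = lambda^(t-1) imply
per-capita entry masses B_1 = 1, B_t = E_t - phi * E_{t-1}, normalised to the
entry distribution beta.  The open-process likelihood is also conditioned on
detection at least once, which makes the two parts combine cleanly for
animals that are never seen.

Nine parameter structures (I1-I9) vary whether phi and lambda are constant,
landscape-specific, or patch-specific; capture and recapture rates are
additive in patch and session on the logit scale (p_(pa+t), c_(pa+t)).
Links: logit for phi, p, c; log for lambda.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit
from statsmodels.tools import numdiff

from .capture_data import RobustDesignDataset, StudyDesign, mt1_per_session
from . import model_selection

_Z95 = 1.959963984540054
_PENALTY_WEIGHT = 1e4
_P_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# parameter structures
# ---------------------------------------------------------------------------

FACTOR_LEVELS = ("constant", "landscape", "patch")


@dataclass(frozen=True)
class RDParameterStructure:
    """Which effects drive phi, lambda and the detection rates.

    ``phi_factor`` / ``lambda_factor`` are one of ``constant``, ``landscape``
    or ``patch``.  ``p_factors`` / ``c_factors`` are subsets of
    ``{"patch", "session"}`` entering additively on the logit scale (the
    conventional reading of p_(pa+t)); the empty set gives a constant rate.
    """

    phi_factor: str
    lambda_factor: str
    p_factors: frozenset[str] = frozenset({"patch", "session"})
    c_factors: frozenset[str] = frozenset({"patch", "session"})
    name: str = ""

    def __post_init__(self) -> None:
        for f in (self.phi_factor, self.lambda_factor):
            if f not in FACTOR_LEVELS:
                raise ValueError(f"factor must be one of {FACTOR_LEVELS}: {f!r}")
        for fs in (self.p_factors, self.c_factors):
            if not fs <= {"patch", "session"}:
                raise ValueError("detection factors must be subset of patch/session")

    def label(self) -> str:
        def det(fs: frozenset[str]) -> str:
            parts = [s for s, key in (("pa", "patch"), ("t", "session")) if key in fs]
            return "+".join(parts) if parts else "."

        fmap = {"constant": ".", "landscape": "ls", "patch": "pa"}
        return (
            f"phi({fmap[self.phi_factor]}) lam({fmap[self.lambda_factor]}) "
            f"p({det(self.p_factors)}) c({det(self.c_factors)})"
        )


def table1_structures() -> dict[str, RDParameterStructure]:
    """The nine candidate structures I1-I9 (additive patch+session detection)."""
    combos = {
        "I1": ("constant", "constant"),
        "I2": ("landscape", "landscape"),
        "I3": ("landscape", "constant"),
        "I4": ("constant", "landscape"),
        "I5": ("patch", "landscape"),
        "I6": ("landscape", "patch"),
        "I7": ("patch", "constant"),
        "I8": ("constant", "patch"),
        "I9": ("patch", "patch"),
    }
    return {
        name: RDParameterStructure(phi_factor=phi, lambda_factor=lam, name=name)
        for name, (phi, lam) in combos.items()
    }


def count_parameters(
    structure: RDParameterStructure,
    n_patches: int,
    n_sessions: int,
    n_landscapes: int = 2,
) -> int:
    """Number of estimated parameters K for a structure.

    phi and lambda contribute 1 (constant), ``n_landscapes`` or ``n_patches``
    levels; each detection block contributes an intercept plus
    ``n_patches - 1`` patch effects and/or ``n_sessions - 1`` session effects.
    """
    if n_patches < 1 or n_sessions < 2:
        raise ValueError("need n_patches >= 1 and n_sessions >= 2")
    levels = {"constant": 1, "landscape": n_landscapes, "patch": n_patches}

    def det_block(fs: frozenset[str]) -> int:
        return (
            1
            + (n_patches - 1 if "patch" in fs else 0)
            + (n_sessions - 1 if "session" in fs else 0)
        )

    return (
        levels[structure.phi_factor]
        + levels[structure.lambda_factor]
        + det_block(structure.p_factors)
        + det_block(structure.c_factors)
    )


# ---------------------------------------------------------------------------
# likelihood building blocks
# ---------------------------------------------------------------------------

def pstar(p_occasions: Sequence[float]) -> float:
    """Session-level detection: probability of >= 1 capture, 1 - prod(1-p_j)."""
    p = np.asarray(p_occasions, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("occasion capture probabilities must lie in [0, 1]")
    return float(1.0 - np.prod(1.0 - p))


def _huggins_suffstats(session_histories: Sequence[Sequence[int]]) -> tuple:
    """Sufficient statistics (n, A, R1, R0) of within-session histories.

    n: individuals; A: total occasions before first capture; R1/R0: captures
    and misses after first capture.  The behavioural-response conditional
    likelihood depends on the data only through these.
    """
    n = A = r1 = r0 = 0
    for h in session_histories:
        h = np.asarray(h, dtype=int)
        if not h.any():
            raise ValueError("within-session history must contain a capture")
        j = int(np.argmax(h))
        n += 1
        A += j
        post = h[j + 1:]
        r1 += int(post.sum())
        r0 += int(len(post) - post.sum())
    return n, A, r1, r0


def _huggins_loglik_stats(
    n: int, A: int, r1: int, r0: int, k_occ: int, p: float, c: float
) -> float:
    if n == 0:
        return 0.0
    ps = 1.0 - (1.0 - p) ** k_occ
    return (
        A * np.log1p(-p)
        + n * np.log(p)
        + (r1 * np.log(c) if r1 else 0.0)
        + (r0 * np.log1p(-c) if r0 else 0.0)
        - n * np.log(ps)
    )


def huggins_session_loglik(
    session_histories: Sequence[Sequence[int]], p: float, c: float
) -> float:
    """Huggins conditional log-likelihood of one closed session.

    Each individual contributes log[ (1-p)^(j-1) p * prod_{m>j} c^h (1-c)^(1-h)
    / p* ] with first capture at occasion j.  An empty session carries no
    information (log-likelihood 0).
    """
    if not (0 < p < 1 and 0 < c < 1):
        raise ValueError("p and c must lie in (0, 1)")
    if len(session_histories) == 0:
        return 0.0
    k_occ = len(np.asarray(session_histories[0]))
    stats_ = _huggins_suffstats(session_histories)
    return float(_huggins_loglik_stats(*stats_, k_occ, p, c))


@dataclass(frozen=True)
class AbundanceEstimate:
    """Huggins-derived abundance for one patch-session (Table-2 shape).

    The 95% CI is lognormal on f0 = N - M_{t+1}, so the lower limit never
    drops below the number of distinct animals actually caught.
    """

    n_hat: float
    se: float
    ci_low: float
    ci_high: float
    m_t1: int
    patch_id: str = ""
    session: int = 0
    unstable: bool = False


def huggins_abundance(
    m_t1: int,
    pstar_value: float,
    var_pstar: float = 0.0,
    patch_id: str = "",
    session: int = 0,
) -> AbundanceEstimate:
    """Abundance N = M_{t+1} / p* with delta-method SE and lognormal CI.

    The variance combines the binomial sampling term M(1-p*)/p*^2 with the
    propagated detection-parameter uncertainty (M/p*^2)^2 var(p*).
    """
    if m_t1 < 0:
        raise ValueError("M_{t+1} must be non-negative")
    if not (0 < pstar_value <= 1):
        raise ValueError("p* must lie in (0, 1]")
    unstable = pstar_value < 1e-2 and m_t1 > 0
    n_hat = m_t1 / pstar_value
    var = (
        m_t1 * (1.0 - pstar_value) / pstar_value**2
        + (m_t1 / pstar_value**2) ** 2 * var_pstar
    )
    se = float(np.sqrt(var))
    f0 = n_hat - m_t1
    if f0 < 1e-12 or se < 1e-12:
        lo, hi = float(m_t1), float(n_hat) if se < 1e-12 else float(n_hat + _Z95 * se)
        lo = max(lo, float(m_t1))
    else:
        cfac = np.exp(_Z95 * np.sqrt(np.log1p(var / f0**2)))
        lo, hi = m_t1 + f0 / cfac, m_t1 + f0 * cfac
    return AbundanceEstimate(
        n_hat=float(n_hat),
        se=se,
        ci_low=float(lo),
        ci_high=float(max(hi, n_hat)),
        m_t1=int(m_t1),
        patch_id=patch_id,
        session=session,
        unstable=unstable,
    )


def entry_distribution(
    phi: float, lam: float, n_sessions: int
) -> tuple[np.ndarray, float]:
    """Per-capita entry probabilities beta over sessions, plus a penalty.

    Relative expected abundances E_t = lam^(t-1) give entry masses B_1 = 1
    and B_t = E_t - phi * E_{t-1}.  When lam < phi the raw masses go
    negative (growth slower than survival allows with non-negative
    recruitment); they are floored at zero and a smooth quadratic penalty on
    the violation is returned for the optimiser to absorb.
    """
    if not (0 < phi < 1):
        raise ValueError("phi must lie in (0, 1)")
    if not lam > 0:
        raise ValueError("lambda must be positive")
    t = np.arange(n_sessions, dtype=float)
    e = lam**t
    b_raw = np.concatenate(([1.0], e[1:] - phi * e[:-1]))
    neg = np.minimum(b_raw, 0.0)
    penalty = _PENALTY_WEIGHT * float(np.sum(neg**2))
    b = np.maximum(b_raw, 0.0)
    return b / b.sum(), penalty


def _collapsed_matrix(histories) -> tuple[np.ndarray, np.ndarray]:
    """Unique collapsed detection vectors and their multiplicities."""
    H = np.asarray(
        [h.detected if hasattr(h, "detected") else h for h in histories], dtype=float
    )
    uniq, counts = np.unique(H, axis=0, return_counts=True)
    return uniq, counts.astype(float)


def _open_loglik_core(
    H: np.ndarray,
    w: np.ndarray,
    phi: float,
    beta: np.ndarray,
    pstar_t: np.ndarray,
) -> float:
    """Conditional open-process log-likelihood on unique collapsed histories.

    For history h, P(h) sums over entry session b <= first(h) and last-alive
    session d >= last(h) of  beta_b * phi^(d-b) * exit(d) * prod_{t=b..d}
    p*_t^h_t (1-p*_t)^(1-h_t), with exit(d) = (1-phi) for d < T and survival
    to the end for d = T.  The contribution conditions on detection:
    log[P(h) / (1 - P(never detected))].
    """
    T = H.shape[1]
    first = np.argmax(H, axis=1)          # 0-based
    last = T - 1 - np.argmax(H[:, ::-1], axis=1)
    # cumulative log detection terms; products of <= T probabilities, so
    # linear-space accumulation cannot underflow at study scale
    with np.errstate(divide="ignore"):
        lt = H * np.log(pstar_t) + (1.0 - H) * np.log1p(-pstar_t)
    S = np.concatenate([np.zeros((H.shape[0], 1)), np.cumsum(lt, axis=1)], axis=1)
    l0 = np.log1p(-pstar_t)
    S0 = np.concatenate([[0.0], np.cumsum(l0)])
    P = np.zeros(H.shape[0])
    P0 = 0.0
    for b in range(T):
        for d in range(b, T):
            term = beta[b] * phi ** (d - b) * ((1.0 - phi) if d < T - 1 else 1.0)
            mask = (first >= b) & (last <= d)
            if mask.any():
                P[mask] += term * np.exp(S[mask, d + 1] - S[mask, b])
            P0 += term * np.exp(S0[d + 1] - S0[b])
    P = np.maximum(P, 1e-300)
    denom = max(1.0 - P0, 1e-300)
    return float(np.sum(w * np.log(P)) - w.sum() * np.log(denom))


def open_history_loglik(
    collapsed_histories,
    phi: float,
    lam: float,
    pstar_by_session: Sequence[float],
) -> float:
    """Conditional Pradel-lambda log-likelihood of collapsed histories.

    Accepts ``CollapsedHistory`` objects or raw binary vectors.  The smooth
    recruitment-non-negativity penalty from the entry distribution is
    subtracted (it is zero whenever lam >= phi).
    """
    ps = np.asarray(pstar_by_session, dtype=float)
    if ((ps <= 0) | (ps >= 1)).any():
        raise ValueError("session-level p* must lie in (0, 1)")
    H, w = _collapsed_matrix(collapsed_histories)
    beta, penalty = entry_distribution(phi, lam, len(ps))
    return _open_loglik_core(H, w, phi, beta, ps) - penalty


# ---------------------------------------------------------------------------
# joint model fitting
# ---------------------------------------------------------------------------

class _PreparedData:
    """Per-patch sufficient statistics extracted once before optimisation."""

    def __init__(self, data: RobustDesignDataset):
        self.design = data.design
        d = self.design
        self.n_individuals = len(data)
        self.landscape_index = {ls: i for i, ls in enumerate(d.landscapes)}
        self.patch_landscape = np.array(
            [self.landscape_index[ls] for _, ls in d.patches]
        )
        self.huggins: list[list[tuple]] = []   # [patch][session] -> (n, A, r1, r0)
        self.collapsed: list[tuple[np.ndarray, np.ndarray]] = []
        by_patch = data.by_patch()
        for pid in d.patch_ids:
            recs = by_patch[pid]
            per_session = []
            for t in range(d.n_primary):
                hists = [
                    r.encounters[t] for r in recs if r.encounters[t].any()
                ]
                per_session.append(
                    _huggins_suffstats(hists) if hists else (0, 0, 0, 0)
                )
            self.huggins.append(per_session)
            if recs:
                self.collapsed.append(
                    _collapsed_matrix(
                        [(r.encounters.sum(axis=1) > 0).astype(float) for r in recs]
                    )
                )
            else:
                self.collapsed.append((np.zeros((0, d.n_primary)), np.zeros(0)))


class _ParamMap:
    """Pack/unpack the link-scale parameter vector for a structure."""

    def __init__(self, structure: RDParameterStructure, design: StudyDesign):
        self.structure = structure
        self.design = design
        d = design
        self.n_landscapes = len(d.landscapes)
        self.k_phi = {"constant": 1, "landscape": self.n_landscapes,
                      "patch": d.n_patches}[structure.phi_factor]
        self.k_lam = {"constant": 1, "landscape": self.n_landscapes,
                      "patch": d.n_patches}[structure.lambda_factor]
        self.k_p = self._det_k(structure.p_factors)
        self.k_c = self._det_k(structure.c_factors)
        self.k = self.k_phi + self.k_lam + self.k_p + self.k_c
        self.slices = {}
        off = 0
        for name, size in (("phi", self.k_phi), ("lam", self.k_lam),
                           ("p", self.k_p), ("c", self.k_c)):
            self.slices[name] = slice(off, off + size)
            off += size
        ls_idx = {ls: i for i, ls in enumerate(d.landscapes)}
        self.patch_ls = np.array([ls_idx[ls] for _, ls in d.patches])

    def _det_k(self, factors: frozenset[str]) -> int:
        d = self.design
        return (1 + (d.n_patches - 1 if "patch" in factors else 0)
                + (d.n_primary - 1 if "session" in factors else 0))

    def _factor_per_patch(self, vec: np.ndarray, factor: str) -> np.ndarray:
        if factor == "constant":
            return np.repeat(vec[0], self.design.n_patches)
        if factor == "landscape":
            return vec[self.patch_ls]
        return vec

    def _det_matrix(self, vec: np.ndarray, factors: frozenset[str]) -> np.ndarray:
        """Logit-scale detection rate per (patch, session)."""
        d = self.design
        eta = np.full((d.n_patches, d.n_primary), vec[0])
        off = 1
        if "patch" in factors:
            eta[1:, :] += vec[off:off + d.n_patches - 1, None]
            off += d.n_patches - 1
        if "session" in factors:
            eta[:, 1:] += vec[off:off + d.n_primary - 1][None, :]
        return eta

    def unpack(self, theta: np.ndarray):
        phi = expit(self._factor_per_patch(
            theta[self.slices["phi"]], self.structure.phi_factor))
        lam = np.exp(self._factor_per_patch(
            theta[self.slices["lam"]], self.structure.lambda_factor))
        p = expit(self._det_matrix(theta[self.slices["p"]], self.structure.p_factors))
        c = expit(self._det_matrix(theta[self.slices["c"]], self.structure.c_factors))
        eps = _P_FLOOR
        return (np.clip(phi, eps, 1 - eps), lam,
                np.clip(p, eps, 1 - eps), np.clip(c, eps, 1 - eps))


@dataclass
class RDFit:
    """A fitted robust-design model under one parameter structure."""

    structure: RDParameterStructure
    design: StudyDesign
    params: np.ndarray
    cov: np.ndarray | None
    loglik: float
    k: int
    n_individuals: int
    aicc: float | None
    converged: bool
    phi_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    lambda_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    abundances: list[AbundanceEstimate] = field(default_factory=list)
    delta: float | None = None
    weight: float | None = None

    @property
    def deviance(self) -> float:
        """-2 log-likelihood (constant-free)."""
        return -2.0 * self.loglik


def _neg_loglik(theta: np.ndarray, prep: _PreparedData, pmap: _ParamMap) -> float:
    phi, lam, p, c = pmap.unpack(theta)
    d = prep.design
    T, K = d.n_primary, d.n_secondary
    total = 0.0
    for i in range(d.n_patches):
        for t in range(T):
            total += _huggins_loglik_stats(*prep.huggins[i][t], K, p[i, t], c[i, t])
        H, w = prep.collapsed[i]
        if len(w) == 0:
            continue
        ps_t = 1.0 - (1.0 - p[i]) ** K
        ps_t = np.clip(ps_t, _P_FLOOR, 1 - _P_FLOOR)
        beta, penalty = entry_distribution(phi[i], lam[i], T)
        total += _open_loglik_core(H, w, phi[i], beta, ps_t) - penalty
    if not np.isfinite(total):
        return 1e12
    return -total


def _initial_theta(prep: _PreparedData, pmap: _ParamMap) -> np.ndarray:
    n = sum(s[0] for pt in prep.huggins for s in pt)
    A = sum(s[1] for pt in prep.huggins for s in pt)
    r1 = sum(s[2] for pt in prep.huggins for s in pt)
    r0 = sum(s[3] for pt in prep.huggins for s in pt)
    p0 = np.clip(n / max(A + n, 1), 0.05, 0.95)
    c0 = np.clip(r1 / max(r1 + r0, 1), 0.05, 0.95)
    theta = np.zeros(pmap.k)
    theta[pmap.slices["p"].start] = logit(p0)
    theta[pmap.slices["c"].start] = logit(c0)
    return theta


def fit(
    data: RobustDesignDataset,
    structure: RDParameterStructure,
    n_random_starts: int = 5,
    seed: int = 0,
) -> RDFit:
    """Maximum-likelihood fit of one parameter structure.

    Optimises the joint (Huggins + open-process) conditional log-likelihood
    by L-BFGS-B from a data-driven null start plus ``n_random_starts``
    perturbed starts; the variance matrix is the inverse observed
    information.  Returns the fit with ``converged=False`` when no start
    converges (callers drop such fits from selection tables).
    """
    if data.design.n_primary < 2:
        raise ValueError("robust design needs >= 2 primary sessions")
    if len(data) == 0:
        raise ValueError("no encounter records")
    prep = _PreparedData(data)
    pmap = _ParamMap(structure, data.design)
    k_expected = count_parameters(
        structure, data.design.n_patches, data.design.n_primary,
        n_landscapes=len(data.design.landscapes),
    )
    assert pmap.k == k_expected, "parameter map inconsistent with counting rule"

    rng = np.random.default_rng(seed)
    base = _initial_theta(prep, pmap)
    starts = [base] + [
        base + rng.normal(0.0, 0.5, size=pmap.k) for _ in range(n_random_starts)
    ]
    def ok(res) -> bool:
        # accept optimizer status, or a stalled line search at a stationary
        # point (projected gradient effectively zero)
        return np.isfinite(res.fun) and (
            bool(res.success) or float(np.max(np.abs(res.jac))) < 1e-3
        )

    results = [
        optimize.minimize(
            _neg_loglik, x0, args=(prep, pmap), method="L-BFGS-B",
            options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-6},
        )
        for x0 in starts
    ]
    good = [r for r in results if ok(r)]
    best_any = min(results, key=lambda r: r.fun)
    if good:
        best = min(good, key=lambda r: r.fun)
        # a non-converged run that found a materially better optimum wins,
        # but flags the fit
        if best_any.fun < best.fun - 1e-4 * (1 + abs(best.fun)):
            best, converged = best_any, False
        else:
            converged = True
    else:
        best, converged = best_any, False
    theta = best.x
    loglik = -float(best.fun)

    cov = None
    if converged:
        try:
            hess = numdiff.approx_hess1(theta, _neg_loglik, args=(prep, pmap))
            cov = np.linalg.pinv(hess)
            if not np.all(np.isfinite(cov)):
                cov = None
        except Exception:  # singular information: keep fit, SEs unavailable
            cov = None

    n_ind = prep.n_individuals
    try:
        aicc_val = model_selection.aicc(loglik, pmap.k, n_ind)
    except ValueError:
        aicc_val = None

    fit_obj = RDFit(
        structure=structure, design=data.design, params=theta, cov=cov,
        loglik=loglik, k=pmap.k, n_individuals=n_ind, aicc=aicc_val,
        converged=converged,
    )
    _attach_real_scale(fit_obj, prep, pmap)
    _attach_abundances(fit_obj, data, prep, pmap)
    return fit_obj


def _attach_real_scale(fit_obj: RDFit, prep: _PreparedData, pmap: _ParamMap) -> None:
    d = prep.design
    theta, cov = fit_obj.params, fit_obj.cov
    rows_phi, rows_lam = [], []
    for i, (pid, ls) in enumerate(d.patches):
        for which, rows in (("phi", rows_phi), ("lam", rows_lam)):
            sl = pmap.slices[which]
            factor = (pmap.structure.phi_factor if which == "phi"
                      else pmap.structure.lambda_factor)
            if factor == "constant":
                j = sl.start
            elif factor == "landscape":
                j = sl.start + pmap.patch_ls[i]
            else:
                j = sl.start + i
            eta = theta[j]
            var_eta = cov[j, j] if cov is not None else np.nan
            var_eta = max(var_eta, 0.0) if np.isfinite(var_eta) else np.nan
            se_eta = np.sqrt(var_eta) if np.isfinite(var_eta) else np.nan
            if which == "phi":
                est = float(expit(eta))
                se = se_eta * est * (1 - est) if np.isfinite(se_eta) else np.nan
                lo = float(expit(eta - _Z95 * se_eta)) if np.isfinite(se_eta) else np.nan
                hi = float(expit(eta + _Z95 * se_eta)) if np.isfinite(se_eta) else np.nan
            else:
                est = float(np.exp(eta))
                se = se_eta * est if np.isfinite(se_eta) else np.nan
                lo = float(np.exp(eta - _Z95 * se_eta)) if np.isfinite(se_eta) else np.nan
                hi = float(np.exp(eta + _Z95 * se_eta)) if np.isfinite(se_eta) else np.nan
            rows.append(
                {"patch_id": pid, "landscape": ls, "estimate": est, "se": se,
                 "ci_low": lo, "ci_high": hi}
            )
    fit_obj.phi_table = pd.DataFrame(rows_phi)
    fit_obj.lambda_table = pd.DataFrame(rows_lam)


def _attach_abundances(
    fit_obj: RDFit, data: RobustDesignDataset, prep: _PreparedData, pmap: _ParamMap
) -> None:
    d = data.design
    K = d.n_secondary
    m_table = mt1_per_session(data)
    _, _, p, _ = pmap.unpack(fit_obj.params)
    cov = fit_obj.cov
    sl = pmap.slices["p"]
    ests = []
    for i, pid in enumerate(d.patch_ids):
        for t in range(d.n_primary):
            m = int(m_table.loc[pid, t + 1])
            if m == 0:
                continue
            pit = p[i, t]
            ps = 1.0 - (1.0 - pit) ** K
            var_ps = 0.0
            if cov is not None:
                # dp*/dtheta = K(1-p)^(K-1) * p(1-p) * x  on the p-block
                x = np.zeros(pmap.k)
                x[sl.start] = 1.0
                off = sl.start + 1
                if "patch" in pmap.structure.p_factors:
                    if i > 0:
                        x[off + i - 1] = 1.0
                    off += d.n_patches - 1
                if "session" in pmap.structure.p_factors and t > 0:
                    x[off + t - 1] = 1.0
                g = K * (1.0 - pit) ** (K - 1) * pit * (1.0 - pit) * x
                var_ps = float(g @ cov @ g)
                var_ps = max(var_ps, 0.0)
            ests.append(
                huggins_abundance(m, ps, var_ps, patch_id=pid, session=t + 1)
            )
    fit_obj.abundances = ests


# ---------------------------------------------------------------------------
# multi-structure selection and model averaging
# ---------------------------------------------------------------------------

def fit_all(
    data: RobustDesignDataset,
    structures: dict[str, RDParameterStructure] | None = None,
    n_random_starts: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, RDFit]]:
    """Fit a set of structures and rank them by AICc.

    Non-converged fits and fits with undefined AICc are dropped from the
    table (with a warning) before weights are normalised; the returned dict
    holds every attempted fit.  The table carries model, K, loglik, AICc,
    delta, weight and deviance (-2 logL).
    """
    if structures is None:
        structures = table1_structures()
    fits: dict[str, RDFit] = {}
    for name, structure in structures.items():
        fits[name] = fit(data, structure, n_random_starts=n_random_starts, seed=seed)
    usable = {
        n: f for n, f in fits.items() if f.converged and f.aicc is not None
    }
    dropped = set(fits) - set(usable)
    if dropped:
        warnings.warn(f"structures dropped from selection: {sorted(dropped)}")
    if not usable:
        raise RuntimeError("no structure converged")
    names = list(usable)
    tab = model_selection.selection_table(
        names,
        [usable[n].loglik for n in names],
        [usable[n].k for n in names],
        usable[names[0]].n_individuals,
    )
    tab["deviance"] = [usable[m].deviance for m in tab["model"]]
    for _, row in tab.iterrows():
        usable[row["model"]].delta = row["delta"]
        usable[row["model"]].weight = row["weight"]
    return tab, fits


@dataclass
class ModelAveragedDemography:
    """AICc-weighted averages across fitted structures (Tables 2/3 shape)."""

    phi: pd.DataFrame        # patch_id, landscape, estimate, se, ci_low, ci_high
    lam: pd.DataFrame
    abundance: pd.DataFrame  # patch_id, session, m_t1, n_hat, se, ci_low, ci_high


def model_average_demography(
    table: pd.DataFrame, fits: dict[str, RDFit]
) -> ModelAveragedDemography:
    """Model-average phi, lambda and N across the ranked structures.

    Uses the Akaike weights from ``table`` and unconditional SEs; abundance
    CIs are lognormal on f0 with the observed count as hard lower bound.
    """
    models = list(table["model"])
    weights = np.asarray(table["weight"], dtype=float)
    first = fits[models[0]]
    d = first.design

    def avg_param(attr: str) -> pd.DataFrame:
        rows = []
        for i, (pid, ls) in enumerate(d.patches):
            ests, vars_ = [], []
            for m in models:
                t = getattr(fits[m], attr).iloc[i]
                ests.append(t["estimate"])
                vars_.append(t["se"] ** 2 if np.isfinite(t["se"]) else 0.0)
            avg = model_selection.model_average(ests, vars_, weights)
            if attr == "phi_table":
                lo = float(np.clip(avg.value - _Z95 * avg.se, 0.0, 1.0))
                hi = float(np.clip(avg.value + _Z95 * avg.se, 0.0, 1.0))
            else:
                lo = max(avg.value - _Z95 * avg.se, 0.0)
                hi = avg.value + _Z95 * avg.se
            rows.append(
                {"patch_id": pid, "landscape": ls, "estimate": avg.value,
                 "se": avg.se, "ci_low": lo, "ci_high": hi}
            )
        return pd.DataFrame(rows)

    ab_rows = []
    keys = {(a.patch_id, a.session) for m in models for a in fits[m].abundances}
    for pid, sess in sorted(keys):
        ests, vars_, m_obs = [], [], 0
        present = []
        for m in models:
            match = [a for a in fits[m].abundances
                     if a.patch_id == pid and a.session == sess]
            if match:
                ests.append(match[0].n_hat)
                vars_.append(match[0].se ** 2)
                m_obs = match[0].m_t1
                present.append(True)
            else:
                present.append(False)
        if not all(present):
            continue
        avg = model_selection.model_average(ests, vars_, weights)
        f0 = max(avg.value - m_obs, 0.0)
        if f0 < 1e-12 or avg.se < 1e-12:
            lo, hi = float(m_obs), float(avg.value)
        else:
            cfac = np.exp(_Z95 * np.sqrt(np.log1p(avg.se**2 / f0**2)))
            lo, hi = m_obs + f0 / cfac, m_obs + f0 * cfac
        ab_rows.append(
            {"patch_id": pid, "session": sess, "m_t1": m_obs,
             "n_hat": avg.value, "se": avg.se, "ci_low": lo, "ci_high": hi}
        )
    return ModelAveragedDemography(
        phi=avg_param("phi_table"),
        lam=avg_param("lambda_table"),
        abundance=pd.DataFrame(ab_rows),
    )
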