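"""Liability-threshold model for binary twin traits.

The model assumes a latent standard-normal "liability" per individual;
disease occurs when liability exceeds a threshold ``t`` fixed by the
population prevalence ``K`` through ``P(Z > t) = K``.  Cotwin liabilities
are bivariate normal with a zygosity-specific correlation (the tetrachoric
correlation), so a pair's affection table is a censored observation of that
correlation.  Variance-component (ACE-family) models constrain the
correlations through

    rho_MZ = a2 + c2 + d2        rho_DZ = a2/2 + c2 + d2/4

where a2, c2, d2, e2 are the additive-genetic, shared-environment,
dominance and unique-environment proportions of liability variance
(a2 + c2 + d2 + e2 = 1).  C and D are never free simultaneously: with only
MZ and DZ correlations available the two are not jointly identified.

Everything here works on symmetric three-cell pair tables
(both / exactly one / neither affected): cotwin order is meaningless, so
the ordered four-cell table carries no extra information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.special import owens_t
from scipy.stats import chi2, norm

from .twin_data import Sex, TwinPairRecord, Zygosity

__all__ = [
    "PairContingencyTable",
    "TetrachoricEstimate",
    "VarianceModelFit",
    "ModelComparison",
    "threshold_from_prevalence",
    "bivariate_normal_cdf",
    "orthant_probabilities",
    "contingency_from_records",
    "tetrachoric_mle",
    "tetrachoric_grid_search",
    "fit_variance_model",
    "compare_models",
    "MODEL_STRUCTURES",
]


# ---------------------------------------------------------------------------
# types

@dataclass(frozen=True)
class PairContingencyTable:
    """Symmetric affection table for one group of twin pairs."""

    zygosity: Zygosity
    n_both: int
    n_one: int
    n_neither: int
    sex_pair: Optional[tuple[Sex, Sex]] = None

    def __post_init__(self) -> None:
        for name in ("n_both", "n_one", "n_neither"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_total < 1:
            raise ValueError("contingency table must contain at least one pair")

    @property
    def n_total(self) -> int:
        return self.n_both + self.n_one + self.n_neither


@dataclass(frozen=True)
class TetrachoricEstimate:
    """Maximum-likelihood correlation of liability for one group."""

    rho: float
    threshold: float
    ci_low: float
    ci_high: float
    loglik: float
    level: float = 0.95


@dataclass(frozen=True)
class VarianceModelFit:
    """A fitted ACE-family variance decomposition of liability."""

    structure: str
    a2: float
    c2: float
    d2: float
    e2: float
    thresholds: dict
    loglik: float
    aic: float
    n_free_params: int
    component_ci: dict = field(default_factory=dict)

    @property
    def rho_mz(self) -> float:
        return self.a2 + self.c2 + self.d2

    @property
    def rho_dz(self) -> float:
        return 0.5 * self.a2 + self.c2 + 0.25 * self.d2

    def components(self) -> dict:
        return {"a2": self.a2, "c2": self.c2, "d2": self.d2, "e2": self.e2}


@dataclass(frozen=True)
class ModelComparison:
    fits: tuple
    delta_aic: dict
    lrt: dict
    selected: str


#: free variance components per model structure (E is always the residual).
MODEL_STRUCTURES: dict[str, tuple[str, ...]] = {
    "ACE": ("a2", "c2"),
    "ADE": ("a2", "d2"),
    "AE": ("a2",),
    "CE": ("c2",),
    "E": (),
}

#: nested pairs (full, reduced) admissible for likelihood-ratio tests.
NESTED_PAIRS: dict[tuple[str, str], int] = {
    ("ACE", "AE"): 1,
    ("ACE", "CE"): 1,
    ("ACE", "E"): 2,
    ("ADE", "AE"): 1,
    ("ADE", "E"): 2,
    ("AE", "E"): 1,
    ("CE", "E"): 1,
}


# ---------------------------------------------------------------------------
# normal orthants

def threshold_from_prevalence(K: float) -> float:
    """Liability threshold t with upper-tail mass K: ``P(Z > t) = K``."""
    if not 0.0 < K < 1.0:
        raise ValueError(f"prevalence must be in (0, 1), got {K}")
    return float(norm.isf(K))


def bivariate_normal_cdf(h, k, rho):
    """``P(X <= h, Y <= k)`` for standard bivariate normal X, Y, vectorized.

    Computed from Owen's T function,

        Phi2(h, k, rho) = (Phi(h) + Phi(k))/2 - T(h, a_h) - T(k, a_k) - delta

    with ``a_h = (k - rho h) / (h sqrt(1 - rho^2))`` (symmetrically for k)
    and ``delta = 1/2`` iff h and k lie on opposite sides of zero.  Exact
    zeros of h or k are nudged by 1e-13, a perturbation far below the
    accuracy of the T evaluation itself.  |rho| = 1 is handled by the
    comonotone / antithetic limits.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = np.asarray(rho, dtype=float)
    h, k, rho = np.broadcast_arrays(h, k, rho)

    out = np.empty(h.shape, dtype=float)
    hi = rho >= 1.0 - 1e-14
    lo = rho <= -1.0 + 1e-14
    mid = ~(hi | lo)

    if hi.any():
        out[hi] = norm.cdf(np.minimum(h[hi], k[hi]))
    if lo.any():
        out[lo] = np.clip(norm.cdf(h[lo]) + norm.cdf(k[lo]) - 1.0, 0.0, None)
    if mid.any():
        hm = np.where(h[mid] == 0.0, 1e-13, h[mid])
        km = np.where(k[mid] == 0.0, 1e-13, k[mid])
        r = rho[mid]
        denom = np.sqrt(1.0 - r * r)
        ah = (km - r * hm) / (hm * denom)
        ak = (hm - r * km) / (km * denom)
        delta = np.where(hm * km < 0.0, 0.5, 0.0)
        val = 0.5 * (norm.cdf(hm) + norm.cdf(km)) - owens_t(hm, ah) - owens_t(km, ak) - delta
        out[mid] = np.clip(val, 0.0, 1.0)
    if out.ndim == 0:
        return float(out)
    return out


def orthant_probabilities(t1: float, t2: float, rho: float):
    """Probabilities of the four affection outcomes of a twin pair.

    Returns ``(p_both, p_only1, p_only2, p_neither)`` for liabilities that
    are standard bivariate normal with correlation ``rho`` and thresholds
    ``t1``, ``t2``.  The four values sum to 1 to within 1e-10.
    """
    if np.any(np.abs(rho) > 1):
        raise ValueError("correlation must lie in [-1, 1]")
    p_neither = bivariate_normal_cdf(t1, t2, rho)
    s1 = norm.sf(t1)
    s2 = norm.sf(t2)
    p_both = np.clip(1.0 - norm.cdf(t1) - norm.cdf(t2) + p_neither, 0.0, 1.0)
    p_only1 = np.clip(s1 - p_both, 0.0, 1.0)
    p_only2 = np.clip(s2 - p_both, 0.0, 1.0)
    return p_both, p_only1, p_only2, p_neither


def contingency_from_records(
    records: Sequence[TwinPairRecord],
    zygosity: Zygosity,
    subset=None,
    by_sex: bool = False,
) -> list[PairContingencyTable]:
    """Collapse records of one zygosity into symmetric affection tables.

    With ``by_sex=True`` one table is produced per sex composition
    (FF / MM / FM) so that per-sex thresholds can be fitted; otherwise a
    single table is returned (in a one-element list).
    """
    groups: dict[Optional[tuple[Sex, Sex]], list[int]] = {}
    for r in records:
        if r.zygosity is not zygosity:
            continue
        if subset is not None and not subset(r):
            continue
        key: Optional[tuple[Sex, Sex]]
        if by_sex:
            key = tuple(sorted(r.sex, key=lambda s: s.value))  # type: ignore[assignment]
        else:
            key = None
        cells = groups.setdefault(key, [0, 0, 0])
        cells[{2: 0, 1: 1, 0: 2}[r.n_affected]] += 1
    return [
        PairContingencyTable(
            zygosity=zygosity, n_both=c[0], n_one=c[1], n_neither=c[2], sex_pair=key
        )
        for key, c in sorted(groups.items(), key=lambda kv: str(kv[0]))
    ]


# ---------------------------------------------------------------------------
# tetrachoric MLE

_TINY = 1e-300


def _cell_probabilities(t: float, rho: float):
    """(p_both, p_one, p_neither) for a symmetric pair with threshold t."""
    p_both, p_only1, p_only2, p_neither = orthant_probabilities(t, t, rho)
    return p_both, p_only1 + p_only2, p_neither


def _table_loglik(table: PairContingencyTable, rho: float, t: float) -> float:
    pb, po, pn = _cell_probabilities(t, rho)
    return (
        table.n_both * np.log(max(pb, _TINY))
        + table.n_one * np.log(max(po, _TINY))
        + table.n_neither * np.log(max(pn, _TINY))
    )


def _profile_loglik_t(table: PairContingencyTable, rho: float) -> float:
    """Maximize the table log-likelihood over the threshold at fixed rho."""
    res = optimize.minimize_scalar(
        lambda t: -_table_loglik(table, rho, t),
        bounds=(-6.0, 6.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return -res.fun


def tetrachoric_mle(
    table: PairContingencyTable,
    level: float = 0.95,
    prevalence: Optional[float] = None,
) -> TetrachoricEstimate:
    """Maximum-likelihood tetrachoric correlation from a 3-cell pair table.

    Maximizes the multinomial likelihood of (n_both, n_one, n_neither) over
    the correlation and the liability threshold; with ``prevalence`` given
    the threshold is fixed at ``threshold_from_prevalence(prevalence)``
    instead (required when ``n_neither == 0``).  The CI is the profile
    likelihood interval at the chi-square(1) cutoff.

    Degenerate tables with all mass in the concordant (or discordant) cell
    return a boundary estimate at rho = +1 (or -1) with a warning.
    """
    n = table.n_total
    if prevalence is None and table.n_neither == 0 and table.n_one == 0:
        warnings.warn("degenerate table: all pairs concordant-affected; rho at +1")
        return TetrachoricEstimate(rho=1.0, threshold=0.0, ci_low=np.nan, ci_high=1.0, loglik=0.0, level=level)
    if prevalence is None and table.n_neither == 0:
        raise ValueError("threshold not estimable with n_neither == 0; supply a prevalence")

    k_hat = (2 * table.n_both + table.n_one) / (2 * n)
    k_hat = min(max(k_hat, 1e-8), 1 - 1e-8)
    if prevalence is not None:
        t_fixed = threshold_from_prevalence(prevalence)

        def neg_ll(z):
            return -_table_loglik(table, np.tanh(z[0]), t_fixed)

        starts = [np.array([np.arctanh(r0)]) for r0 in (-0.5, 0.0, 0.5, 0.9)]
    else:
        t0 = threshold_from_prevalence(k_hat)

        def neg_ll(z):
            return -_table_loglik(table, np.tanh(z[0]), z[1])

        starts = [np.array([np.arctanh(r0), t0]) for r0 in (-0.5, 0.0, 0.5, 0.9)]

    best = None
    for x0 in starts:
        res = optimize.minimize(neg_ll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    rho_hat = float(np.tanh(best.x[0]))
    t_hat = t_fixed if prevalence is not None else float(best.x[1])
    ll_hat = -float(best.fun)

    # profile-likelihood CI on rho
    cut = chi2.ppf(level, df=1)

    def profile_dev(r: float) -> float:
        if prevalence is not None:
            ll_r = _table_loglik(table, r, t_fixed)
        else:
            ll_r = _profile_loglik_t(table, r)
        return 2.0 * (ll_hat - ll_r) - cut

    lo_bound, hi_bound = -1.0 + 1e-9, 1.0 - 1e-9
    ci_low = lo_bound if profile_dev(lo_bound) <= 0 else float(
        optimize.brentq(profile_dev, lo_bound, rho_hat, xtol=1e-8)
    ) if rho_hat > lo_bound else lo_bound
    ci_high = hi_bound if profile_dev(hi_bound) <= 0 else float(
        optimize.brentq(profile_dev, rho_hat, hi_bound, xtol=1e-8)
    ) if rho_hat < hi_bound else hi_bound
    ci_low = max(ci_low, -1.0)
    ci_high = min(ci_high, 1.0)

    return TetrachoricEstimate(
        rho=rho_hat, threshold=t_hat, ci_low=ci_low, ci_high=ci_high,
        loglik=ll_hat, level=level,
    )


def tetrachoric_grid_search(
    table: PairContingencyTable,
    prevalence: Optional[float] = None,
    n_rho: int = 201,
    n_t: int = 101,
    refinements: int = 5,
) -> tuple[float, float, float]:
    """Brute-force (rho, t) grid maximizer of the same likelihood.

    Iteratively refined grid search, independent of the derivative-free
    optimizer used by :func:`tetrachoric_mle`; serves as its oracle.
    Returns ``(rho, t, loglik)``.
    """
    rho_lo, rho_hi = -0.999, 0.999
    if prevalence is not None:
        t_fixed = threshold_from_prevalence(prevalence)
        t_lo = t_hi = t_fixed
    else:
        t_lo, t_hi = -5.0, 5.0

    best_rho, best_t = 0.0, 0.0
    for _ in range(refinements):
        rhos = np.linspace(rho_lo, rho_hi, n_rho)
        ts = np.array([t_lo]) if t_lo == t_hi else np.linspace(t_lo, t_hi, n_t)
        R, T = np.meshgrid(rhos, ts, indexing="ij")
        pb, po1, po2, pn = orthant_probabilities(T, T, R)
        po = po1 + po2
        ll = (
            table.n_both * np.log(np.maximum(pb, _TINY))
            + table.n_one * np.log(np.maximum(po, _TINY))
            + table.n_neither * np.log(np.maximum(pn, _TINY))
        )
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        best_rho, best_t = float(rhos[i]), float(ts[j])
        drho = (rho_hi - rho_lo) / (n_rho - 1)
        rho_lo = max(-0.999, best_rho - 4 * drho)
        rho_hi = min(0.999, best_rho + 4 * drho)
        if t_lo != t_hi:
            dt = (t_hi - t_lo) / (n_t - 1)
            t_lo, t_hi = best_t - 4 * dt, best_t + 4 * dt
    return best_rho, best_t, _table_loglik(table, best_rho, best_t)


# ---------------------------------------------------------------------------
# variance-component models

def _components_from_free(structure: str, x: np.ndarray) -> dict[str, float]:
    """Map unconstrained reals to simplex components (E is the residual).

    Each free component gets weight x_i**2 and E weight 1, then weights are
    normalized; E is therefore always positive, and boundary optima at a
    component of 0 are reachable at x_i = 0.
    """
    free = MODEL_STRUCTURES[structure]
    w = np.concatenate([np.square(x), [1.0]])
    w = w / w.sum()
    comps = {"a2": 0.0, "c2": 0.0, "d2": 0.0}
    for name, wi in zip(free, w[:-1]):
        comps[name] = float(wi)
    comps["e2"] = float(w[-1])
    return comps


def _rho_for(comps: Mapping[str, float], zygosity: Zygosity) -> float:
    if zygosity is Zygosity.MZ:
        return comps["a2"] + comps["c2"] + comps["d2"]
    return 0.5 * comps["a2"] + comps["c2"] + 0.25 * comps["d2"]


def _thresholds_for_table(
    table: PairContingencyTable, thresholds: Mapping[str, float], sex_layout: str
) -> tuple[float, float]:
    if sex_layout == "common":
        t = thresholds["common"]
        return t, t
    if table.sex_pair is None:
        raise ValueError("per-sex thresholds require sex-stratified tables")
    return thresholds[table.sex_pair[0].value], thresholds[table.sex_pair[1].value]


def _joint_loglik(
    tables: Sequence[PairContingencyTable],
    comps: Mapping[str, float],
    thresholds: Mapping[str, float],
    sex_layout: str,
) -> float:
    total = 0.0
    for table in tables:
        rho = _rho_for(comps, table.zygosity)
        t1, t2 = _thresholds_for_table(table, thresholds, sex_layout)
        pb, po1, po2, pn = orthant_probabilities(t1, t2, rho)
        po = po1 + po2
        total += (
            table.n_both * np.log(max(pb, _TINY))
            + table.n_one * np.log(max(po, _TINY))
            + table.n_neither * np.log(max(pn, _TINY))
        )
    return total


def _threshold_names(sex_layout: str) -> tuple[str, ...]:
    return ("common",) if sex_layout == "common" else ("F", "M")


def _check_tables(tables: Sequence[PairContingencyTable]) -> None:
    zygs = {t.zygosity for t in tables}
    if Zygosity.MZ not in zygs:
        raise ValueError("variance models need at least one MZ table")
    if not zygs & {Zygosity.DZss, Zygosity.DZos}:
        raise ValueError("variance models need at least one DZ table")


def fit_variance_model(
    tables: Sequence[PairContingencyTable],
    structure: str = "ACE",
    sex_layout: str = "common",
    level: float = 0.95,
    compute_ci: bool = True,
) -> VarianceModelFit:
    """Fit one ACE-family structure by joint multinomial maximum likelihood.

    All zygosity groups share the components; DZss and DZos share rho_DZ.
    Free parameters are the structure's free components (squared path
    weights normalized to the simplex) plus the threshold(s): one common
    liability threshold, or one per sex with ``sex_layout="per-sex"``.
    The optimizer is Nelder-Mead restarted from 5 deterministic points;
    AIC is ``-2 loglik + 2 k``.  Component CIs are profile-likelihood
    intervals truncated to [0, 1].
    """
    if structure not in MODEL_STRUCTURES:
        raise ValueError(f"unknown model structure {structure!r}; choose from {sorted(MODEL_STRUCTURES)}")
    if sex_layout not in ("common", "per-sex"):
        raise ValueError("sex_layout must be 'common' or 'per-sex'")
    _check_tables(tables)

    free = MODEL_STRUCTURES[structure]
    t_names = _threshold_names(sex_layout)
    n_free = len(free) + len(t_names)

    # moment start for the threshold from the pooled affection rate
    n_aff = sum(2 * t.n_both + t.n_one for t in tables)
    n_ind = sum(2 * t.n_total for t in tables)
    k_hat = min(max(n_aff / n_ind, 1e-8), 1 - 1e-8)
    t0 = threshold_from_prevalence(k_hat)

    def unpack(z: np.ndarray):
        comps = _components_from_free(structure, z[: len(free)])
        thresholds = dict(zip(t_names, z[len(free):]))
        return comps, thresholds

    def neg_ll(z: np.ndarray) -> float:
        comps, thresholds = unpack(z)
        return -_joint_loglik(tables, comps, thresholds, sex_layout)

    starts = []
    for mag in (0.1, 0.4, 0.8, 1.2, 2.0):
        starts.append(np.concatenate([np.full(len(free), mag), np.full(len(t_names), t0)]))

    best = None
    for x0 in starts:
        res = optimize.minimize(
            neg_ll, x0, method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-9, "maxiter": 20000, "maxfev": 20000},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    assert best is not None
    if not best.success and best.fun == np.inf:
        raise RuntimeError(f"variance-model fit failed for {structure}: {best.message}")

    comps, thresholds = unpack(best.x)
    ll = -float(best.fun)
    fit = VarianceModelFit(
        structure=structure,
        a2=comps["a2"], c2=comps["c2"], d2=comps["d2"], e2=comps["e2"],
        thresholds={k: float(v) for k, v in thresholds.items()},
        loglik=ll,
        aic=-2.0 * ll + 2.0 * n_free,
        n_free_params=n_free,
    )
    if compute_ci:
        cis = {
            name: _profile_component_ci(tables, structure, sex_layout, name, comps[name], ll, level, t0)
            for name in (*free, "e2")
        }
        fit = VarianceModelFit(**{**fit.__dict__, "component_ci": cis})
    return fit


def _profile_component_neg_ll(
    tables, structure, sex_layout, comp_name, value, t0
) -> float:
    """-max loglik with one component fixed at ``value``."""
    free = [f for f in MODEL_STRUCTURES[structure] if f != comp_name]
    other_free_comp = comp_name != "e2"
    t_names = _threshold_names(sex_layout)

    def build(z: np.ndarray):
        comps = {"a2": 0.0, "c2": 0.0, "d2": 0.0, "e2": 0.0}
        rest = 1.0 - value
        if comp_name == "e2":
            # split the remaining mass among the structure's free components
            names = MODEL_STRUCTURES[structure]
            if len(names) == 0:
                pass
            elif len(names) == 1:
                comps[names[0]] = rest
            else:
                s = 1.0 / (1.0 + np.exp(-z[0]))
                comps[names[0]] = rest * s
                comps[names[1]] = rest * (1.0 - s)
            comps["e2"] = value
        else:
            comps[comp_name] = value
            if free:
                s = 1.0 / (1.0 + np.exp(-z[0]))
                comps[free[0]] = rest * s
                comps["e2"] = rest * (1.0 - s)
            else:
                comps["e2"] = rest
        thresholds = dict(zip(t_names, z[-len(t_names):]))
        return comps, thresholds

    if comp_name == "e2":
        has_mix = len(MODEL_STRUCTURES[structure]) > 1
    else:
        has_mix = bool(free)

    def neg_ll(z: np.ndarray) -> float:
        comps, thresholds = build(z)
        return -_joint_loglik(tables, comps, thresholds, sex_layout)

    mix_starts = [(-2.0,), (0.0,), (2.0,)] if has_mix else [()]
    best = None
    for mix in mix_starts:
        x0 = np.concatenate([np.asarray(mix, dtype=float), np.full(len(t_names), t0)])
        res = optimize.minimize(
            neg_ll, x0, method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-9, "maxiter": 10000},
        )
        if best is None or res.fun < best.fun:
            best = res
    return float(best.fun)


def _profile_component_ci(
    tables, structure, sex_layout, comp_name, mle_value, ll_hat, level, t0
) -> tuple[float, float]:
    """Profile-likelihood CI for one variance component, clipped to [0, 1]."""
    cut = chi2.ppf(level, df=1)

    def dev(v: float) -> float:
        nll = _profile_component_neg_ll(tables, structure, sex_layout, comp_name, v, t0)
        return 2.0 * (ll_hat + nll) - cut

    eps = 1e-9
    lo_edge = eps if comp_name != "e2" else eps  # components live in (0,1)
    hi_edge = 1.0 - eps

    if mle_value <= lo_edge or dev(lo_edge) <= 0:
        lo = 0.0
    else:
        lo = float(optimize.brentq(dev, lo_edge, mle_value, xtol=1e-6))
    if mle_value >= hi_edge or dev(hi_edge) <= 0:
        hi = 1.0
    else:
        hi = float(optimize.brentq(dev, mle_value, hi_edge, xtol=1e-6))
    return lo, hi


def compare_models(fits: Sequence[VarianceModelFit]) -> ModelComparison:
    """AIC ranking and likelihood-ratio tests across fits of the same data.

    Reports delta AIC against the minimum, and for every admissible nested
    pair among the supplied fits both the naive chi-square p-value and the
    boundary-corrected p-value: a dropped variance component sits on the
    boundary of its parameter space, so the LRT statistic is asymptotically
    a 50:50 mixture of chi2(df) and chi2(df-1) (a point mass at zero when
    df = 1).  The selected structure is the one with minimal AIC.
    """
    by_structure = {f.structure: f for f in fits}
    if len(by_structure) != len(fits):
        raise ValueError("duplicate model structures in comparison")
    aics = {s: f.aic for s, f in by_structure.items()}
    best_aic = min(aics.values())
    delta = {s: a - best_aic for s, a in aics.items()}

    lrt: dict[tuple[str, str], dict] = {}
    for (full, red), df in NESTED_PAIRS.items():
        if full in by_structure and red in by_structure:
            stat = 2.0 * (by_structure[full].loglik - by_structure[red].loglik)
            stat = max(stat, 0.0)
            naive = float(chi2.sf(stat, df))
            if df == 1:
                mixture = 1.0 if stat == 0.0 else 0.5 * float(chi2.sf(stat, 1))
            else:
                mixture = (
                    0.25 * float(chi2.sf(stat, 2))
                    + 0.5 * float(chi2.sf(stat, 1))
                    + (0.25 if stat == 0.0 else 0.0)
                )
            lrt[(full, red)] = {"stat": stat, "df": df, "p_naive": naive, "p_boundary": mixture}

    selected = min(aics, key=lambda s: (aics[s], s))
    return ModelComparison(fits=tuple(fits), delta_aic=delta, lrt=lrt, selected=selected)
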