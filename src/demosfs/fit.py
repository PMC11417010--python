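"""Poisson composite-likelihood fitting, model ranking, and unit conversion.

Each SFS entry is treated as an independent Poisson count with mean given
by the model's expected spectrum; the product over unmasked entries is the
composite likelihood.  The overall scale ``theta`` enters every entry
linearly, so its maximum-likelihood value has the closed form
``sum(obs) / sum(expected at theta=1)`` and is profiled out of the
numerical search.  The remaining parameters are fitted by multi-start
Nelder-Mead in log-transformed coordinates within box bounds.

Model selection follows the bootstrap-median protocol: every candidate is
fitted to each contig-bootstrap replicate of the observed SFS, models are
ranked by median AIC (``2k - 2 log L``, ``k`` counting theta), and ranking
statistics are ``delta AIC``, relative likelihood ``exp(-delta/2)``, and
AIC weights.  Fitted parameters convert to physical units through
``Ne_anc = theta / (4 mu L)``, sizes ``nu * Ne_anc``, times
``2 T Ne_anc G`` years, and migrant fractions ``m = M / (2 Ne_anc)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln

from .engine import expected_sfs
from .models import CATALOG, CatalogEntry
from .sfs import SpectrumGrid

__all__ = [
    "FitResult",
    "PhysicalScale",
    "PhysicalParams",
    "composite_loglik",
    "profile_theta",
    "fit_model",
    "rank_models",
    "to_physical",
    "bootstrap_uncertainty",
]

_EXPECTED_FLOOR = 1e-30


def _check_compatible(observed: SpectrumGrid, expected: SpectrumGrid) -> None:
    if observed.values.shape != expected.values.shape:
        raise ValueError(
            f"shape mismatch: {observed.values.shape} vs {expected.values.shape}"
        )
    if observed.folded != expected.folded:
        raise ValueError("folded/unfolded mismatch between observed and expected")


def composite_loglik(observed: SpectrumGrid, expected: SpectrumGrid) -> float:
    """Poisson composite log-likelihood over unmasked entries.

    ``sum S_obs ln(S_exp) - S_exp - ln Gamma(S_obs + 1)``; expected values
    are floored at a tiny positive constant (with a warning) so zero-mean
    entries with observed counts do not yield ``-inf``.
    """
    _check_compatible(observed, expected)
    mask = observed.mask | expected.mask
    obs = observed.values[~mask]
    exp = expected.values[~mask]
    if np.any((exp < _EXPECTED_FLOOR) & (obs > 0)):
        warnings.warn("expected SFS has (near-)zero entries; flooring", stacklevel=2)
    exp = np.maximum(exp, _EXPECTED_FLOOR)
    return float(np.sum(obs * np.log(exp) - exp - gammaln(obs + 1.0)))


def profile_theta(observed: SpectrumGrid, expected_shape: SpectrumGrid) -> float:
    """Analytic Poisson maximizer of the scale: ``sum(obs) / sum(shape)``.

    ``expected_shape`` must be computed at ``theta = 1``.
    """
    _check_compatible(observed, expected_shape)
    mask = observed.mask | expected_shape.mask
    denom = float(expected_shape.values[~mask].sum())
    if denom <= 0:
        raise ValueError("expected shape has zero unmasked mass")
    return float(observed.values[~mask].sum()) / denom


@dataclass
class FitResult:
    """Best fit of one catalog model to one observed spectrum."""

    model: str
    params: np.ndarray
    theta_hat: float
    log_likelihood: float
    n_restarts: int
    restart_loglik: list = field(default_factory=list)
    converged: bool = True

    @property
    def k(self) -> int:
        """Free parameters counted for AIC (theta included)."""
        return CATALOG[self.model].k_free

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.log_likelihood


# -- parameter transforms --------------------------------------------------
# nu and T are searched in log space; migration rates may be exactly zero,
# so they are searched as log(M + eps) with a small offset.

_M_OFFSET = 1e-3


def _to_search(params: np.ndarray, names: tuple[str, ...]) -> np.ndarray:
    x = np.empty(len(params))
    for i, (p, name) in enumerate(zip(params, names)):
        x[i] = np.log(p + _M_OFFSET) if name.startswith("M") else np.log(p)
    return x


def _from_search(x: np.ndarray, names: tuple[str, ...]) -> np.ndarray:
    p = np.empty(len(x))
    for i, name in enumerate(names):
        p[i] = max(np.exp(x[i]) - _M_OFFSET, 0.0) if name.startswith("M") else np.exp(x[i])
    return p


def _search_bounds(entry: CatalogEntry) -> list[tuple[float, float]]:
    out = []
    for name, (lo, hi) in zip(entry.param_names, entry.bounds()):
        if name.startswith("M"):
            out.append((np.log(lo + _M_OFFSET), np.log(hi + _M_OFFSET)))
        else:
            out.append((np.log(lo), np.log(hi)))
    return out


def _model_loglik(
    observed: SpectrumGrid, name: str, params, guard: int, dt: float | None = None
) -> tuple[float, float]:
    """(log-likelihood, theta_hat) with theta profiled analytically."""
    shape = expected_sfs(
        CATALOG[name].build(params), observed.n1, observed.n2, 1.0, guard=guard, dt=dt
    )
    if observed.folded:
        shape = shape.fold()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        theta = profile_theta(observed, shape)
        scaled = SpectrumGrid(shape.values * theta, folded=shape.folded, mask=shape.mask)
        ll = composite_loglik(observed, scaled)
    return ll, theta


def fit_model(
    observed: SpectrumGrid,
    name: str,
    restarts: int = 6,
    seed: int = 0,
    guard: int = 2,
    start: np.ndarray | None = None,
    maxiter: int | None = None,
    dt: float | None = None,
) -> FitResult:
    """Multi-start Nelder-Mead fit of a named catalog model.

    Restart initial points are drawn log-uniformly within the default
    bounds from a generator seeded by ``seed``; with ``start`` given, the
    first restart begins there (warm start for bootstrap refits).  The best
    restart is returned.  Deterministic given ``seed``.
    """
    entry = CATALOG[name]
    n_par = len(entry.param_names)
    if n_par == 0:
        ll, theta = _model_loglik(observed, name, np.empty(0), guard, dt)
        return FitResult(name, np.empty(0), theta, ll, 0, [ll])

    rng = np.random.default_rng(seed)
    bounds = _search_bounds(entry)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def negll(x: np.ndarray) -> float:
        if np.any(x < lo) or np.any(x > hi):
            return 1e12 + 1e6 * float(np.sum(np.maximum(lo - x, 0) + np.maximum(x - hi, 0)))
        params = _from_search(x, entry.param_names)
        try:
            ll, _ = _model_loglik(observed, name, params, guard, dt)
        except (FloatingPointError, np.linalg.LinAlgError):
            return 1e12
        return -ll

    if maxiter is None:
        maxiter = 250 * n_par
    best = None
    restart_ll = []
    n_fail = 0
    for r in range(restarts):
        if r == 0 and start is not None:
            x0 = np.clip(_to_search(np.asarray(start, float), entry.param_names), lo, hi)
        else:
            x0 = rng.uniform(lo, hi)
        try:
            res = minimize(
                negll,
                x0,
                method="Nelder-Mead",
                options={
                    "maxfev": maxiter,
                    "xatol": 1e-4,
                    "fatol": 1e-6,
                },
            )
        except Exception:
            n_fail += 1
            continue
        restart_ll.append(-res.fun)
        if best is None or -res.fun > -best[1].fun:
            best = (r, res)
    if best is None:
        raise RuntimeError(f"all {restarts} restarts failed for model {name} ({n_fail} errors)")
    params = _from_search(best[1].x, entry.param_names)
    ll, theta = _model_loglik(observed, name, params, guard, dt)
    return FitResult(
        model=name,
        params=params,
        theta_hat=theta,
        log_likelihood=ll,
        n_restarts=restarts,
        restart_loglik=restart_ll,
        converged=bool(best[1].success),
    )


def rank_models(aic_table: pd.DataFrame) -> pd.DataFrame:
    """Rank models by median AIC across bootstrap replicates.

    ``aic_table`` has one column per model and one row per replicate (a
    single row is allowed).  Returns a DataFrame indexed by model with
    columns ``median_AIC``, ``delta_AIC``, ``rel_likelihood``,
    ``AIC_weight``, sorted by median AIC; weights sum to one.
    """
    if aic_table.empty:
        raise ValueError("empty AIC table")
    if aic_table.isna().any().any():
        raise ValueError("AIC table has missing entries")
    med = aic_table.median(axis=0)
    delta = med - med.min()
    rel = np.exp(-delta / 2.0)
    weight = rel / rel.sum()
    out = pd.DataFrame(
        {
            "median_AIC": med,
            "delta_AIC": delta,
            "rel_likelihood": rel,
            "AIC_weight": weight,
        }
    ).sort_values("median_AIC")
    out.index.name = "model"
    return out


@dataclass
class PhysicalScale:
    """Constants converting genetic units to physical ones."""

    mu: float = 3.92e-9
    G: float = 4.0
    L: float | None = None

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.G <= 0 or (self.L is not None and self.L <= 0):
            raise ValueError("mu, G, L must be positive")


@dataclass
class PhysicalParams:
    """Fitted parameters on natural scales."""

    model: str
    Ne_anc: float
    Ne_current: dict[str, float]
    split_years: float | None
    epoch_years: dict[str, float]
    migrant_fraction: dict[str, float]
    migrants_per_generation: dict[str, float]

    def as_series(self) -> pd.Series:
        flat: dict[str, float] = {"Ne_anc": self.Ne_anc}
        flat.update({f"Ne_{k}": v for k, v in self.Ne_current.items()})
        if self.split_years is not None:
            flat["split_years"] = self.split_years
        flat.update({f"T_years_{k}": v for k, v in self.epoch_years.items()})
        flat.update({f"m_{k}": v for k, v in self.migrant_fraction.items()})
        flat.update({f"migrants_{k}": v for k, v in self.migrants_per_generation.items()})
        return pd.Series(flat)


def to_physical(fit: FitResult, scale: PhysicalScale) -> PhysicalParams:
    """Convert a fit to physical units.

    ``Ne_anc = theta / (4 mu L)``; current sizes ``nu * Ne_anc``; each
    epoch duration ``2 T Ne_anc G`` years (the split time is the youngest
    two-deme epoch's span); migrant fraction ``m = M / (2 Ne_anc)`` per
    direction, and migrants per generation ``m * Ne_current`` of the source
    deme.
    """
    if scale.L is None:
        raise ValueError("PhysicalScale.L is required to interpret theta")
    entry = CATALOG[fit.model]
    names = entry.param_names
    p = dict(zip(names, fit.params))
    Ne = fit.theta_hat / (4.0 * scale.mu * scale.L)
    model = entry.build(fit.params)

    ne_current: dict[str, float] = {}
    if model.epochs:
        last = model.epochs[-1].sizes
        if len(last) == 2:
            ne_current = {"deme1": last[0] * Ne, "deme2": last[1] * Ne}
        else:
            ne_current = {"deme1": last[0] * Ne}
    else:
        ne_current = {"deme1": Ne}

    epoch_years = {
        name: p[name] * 2.0 * Ne * scale.G for name in names if name.startswith("T")
    }
    split_years = None
    if model.has_split:
        split_years = model.epochs[-1].duration * 2.0 * Ne * scale.G

    mig_frac: dict[str, float] = {}
    migrants: dict[str, float] = {}
    if model.has_split and model.epochs:
        M = model.epochs[-1].migration
        for (src, dst), key in (((0, 1), "1to2"), ((1, 0), "2to1")):
            m = M[src, dst] / (2.0 * Ne)
            mig_frac[key] = m
            src_ne = model.epochs[-1].sizes[src] * Ne
            migrants[key] = m * src_ne
    return PhysicalParams(
        model=fit.model,
        Ne_anc=Ne,
        Ne_current=ne_current,
        split_years=split_years,
        epoch_years=epoch_years,
        migrant_fraction=mig_frac,
        migrants_per_generation=migrants,
    )


def bootstrap_uncertainty(
    name: str,
    replicates: list[SpectrumGrid],
    scale: PhysicalScale,
    seed: int = 0,
    guard: int = 2,
    restarts: int = 2,
    start: np.ndarray | None = None,
    max_failures: float = 0.2,
) -> pd.DataFrame:
    """Percentile intervals of physical parameters over bootstrap refits.

    The named model is refitted to every replicate spectrum (warm-started
    from ``start`` when given) and each fit is converted to physical units;
    rows are parameters, columns the 2.5/50/97.5 percentiles.  More than
    ``max_failures`` of failed refits is an error.
    """
    if len(replicates) < 2:
        raise ValueError("need at least two bootstrap replicates")
    rows = []
    failures = []
    for b, rep in enumerate(replicates):
        try:
            fit = fit_model(
                rep, name, restarts=restarts, seed=seed + 1000 * b, guard=guard, start=start
            )
            rows.append(to_physical(fit, scale).as_series())
        except Exception as err:  # noqa: BLE001 - collected into the failure log
            failures.append((b, repr(err)))
    if len(failures) > max_failures * len(replicates):
        raise RuntimeError(f"{len(failures)} bootstrap refits failed: {failures[:5]}")
    table = pd.DataFrame(rows)
    out = table.quantile([0.025, 0.5, 0.975]).T
    out.columns = ["q2.5", "q50", "q97.5"]
    out.index.name = "parameter"
    return out
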