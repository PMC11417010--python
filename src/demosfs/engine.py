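"""Deterministic expected joint SFS under two-deme demographic models.

The engine integrates the closed system of ordinary differential equations
satisfied by the entries of the expected sample SFS (the moments of the
allele-frequency distribution in a sample of fixed size).  Under pure drift
and mutation the system is exactly closed at the sample size: with time in
units of ``2 * Ne_anc`` generations and a relative deme size ``nu``,

    dPhi_i/dt = (1 / (2 nu)) * [ (i-1)(n-i+1) Phi_{i-1}
                                 - 2 i (n-i)   Phi_i
                                 + (i+1)(n-i-1) Phi_{i+1} ]

per deme axis, with an infinite-sites mutation influx ``theta * n / 2`` into
the singleton class.  Its equilibrium is the standard neutral spectrum
``Phi_i = theta * nu / i``.

Migration couples the demes and is not closed at the sample size: moving a
sampled genome between demes requires the spectrum with one extra genome in
the source deme.  The engine closes that hierarchy with a *ladder*: it
integrates the spectra at sizes ``(n1+k, n2+k)`` for ``k = 0..guard``
simultaneously, computing each level's shifted spectrum exactly from the
level above by lineage-drop projection, and closing only the top level with
a moment-matching (jackknife) extrapolation.  The truncation error made at
the top is damped by a factor of order ``(M t)^guard / guard!`` before it
reaches the level-0 output.  This is the only approximation in the engine;
accuracy is checked against structured-coalescent Monte Carlo in the test
suite.

Histories are integrated oldest-to-newest from the single-deme equilibrium;
at a split the one-deme spectrum of ``n1 + n2`` genomes is distributed
exactly over the two-deme grid (sampled lineages are exchangeable), and the
two-deme system is then advanced with drift, mutation, and migration.
Integration uses the trapezoidal (Crank-Nicolson) rule with a fixed step
budget per epoch.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.linalg import lu_factor, lu_solve
from scipy.special import betaln, gammaln

from .models import CATALOG, DemographicModel, Epoch
from .sfs import SpectrumGrid

__all__ = ["expected_sfs", "expected_sfs_1d", "equilibrium_1d", "split_to_grid"]

# Integration defaults: time step in genetic units.  Small enough that the
# second-order trapezoidal error is well below the jackknife error.
DT_MAX = 0.005
MIN_STEPS = 4
MAX_STEPS = 4000
# moment-matching stencil width of the jackknife closure
_JK_POINTS = 6


def _n_steps(duration: float, dt: float | None = None) -> int:
    return int(np.clip(np.ceil(duration / (dt or DT_MAX)), MIN_STEPS, MAX_STEPS))


@lru_cache(maxsize=None)
def drift_matrix(n: int) -> np.ndarray:
    """Tridiagonal drift operator on the size-``n`` sample spectrum."""
    D = np.zeros((n + 1, n + 1))
    for i in range(n + 1):
        D[i, i] = -2.0 * i * (n - i)
        if i > 0:
            D[i, i - 1] = (i - 1) * (n - i + 1)
        if i < n:
            D[i, i + 1] = (i + 1) * (n - i - 1)
    return D


@lru_cache(maxsize=None)
def jackknife_matrix(n: int) -> np.ndarray:
    """Estimate the size ``n+1`` spectrum from the size ``n`` spectrum.

    Row ``ip`` of the returned ``(n+2, n+1)`` matrix expresses
    ``Phi^{n+1}_{ip}`` as a combination of ``_JK_POINTS`` neighbouring
    entries of ``Phi^{n}``.  Coefficients solve a moment-matching system
    that is exact whenever the underlying allele-frequency density is a
    polynomial of degree ``_JK_POINTS - 1``: the moments of ``x^p`` against
    the binomial sampling kernels are Beta functions.  The stencil order is
    set where agreement with structured-coalescent Monte Carlo plateaus;
    accuracy is limited by steep boundary layers of the allele-frequency
    density near fixation, which no polynomial fit captures exactly.
    """
    npts = min(_JK_POINTS, n + 1)
    if n < 4:
        raise ValueError("jackknife extrapolation requires n >= 4")

    def functional(nn: int, i: int, p: int) -> float:
        # integral of C(nn,i) x^(i+p) (1-x)^(nn-i) dx
        logc = gammaln(nn + 1) - gammaln(i + 1) - gammaln(nn - i + 1)
        return float(np.exp(logc + betaln(i + p + 1, nn - i + 1)))

    J = np.zeros((n + 2, n + 1))
    for ip in range(n + 2):
        k = int(round(ip * n / (n + 1)))
        k = min(max(k, 1), n - (npts - 2))
        cols = list(range(k - 1, k - 1 + npts))
        A = np.array([[functional(n, c, p) for c in cols] for p in range(npts)])
        b = np.array([functional(n + 1, ip, p) for p in range(npts)])
        J[ip, cols] = np.linalg.solve(A, b)
    return J


@lru_cache(maxsize=None)
def _lineage_drop_matrix(n: int) -> np.ndarray:
    """Exact projection from ``n`` to ``n - 1`` genomes (drop one lineage)."""
    P = np.zeros((n, n + 1))
    for i in range(n):
        P[i, i] = (n - i) / n
        P[i, i + 1] = (i + 1) / n
    return P


@lru_cache(maxsize=None)
def _migration_pieces(n1: int, n2: int, into: int) -> tuple[np.ndarray, np.ndarray]:
    """Migration term split into a closed part and a higher-order coupling.

    ``into=0``: genes flow (forward) from deme 2 into deme 1.  In the
    allele-frequency diffusion this is the advection term
    ``M (x2 - x1) d/dx1``; taking moments against the binomial sampling
    kernels gives, per grid entry,

        dPhi[i, j]/dt = -i Phi[i, j] + (i+1) Phi[i+1, j]
                        + n1 (j+1)/(n2+1) (Psi[i-1, j+1] - Psi[i, j+1])

    where ``Psi`` is the spectrum at sample sizes ``(n1-1, n2+1)``: one
    fewer genome in the receiving deme, one more in the source deme.
    Out-of-range index terms vanish (their combinatorial coefficients are
    zero) and total grid mass is conserved.  Returns ``(local, R)``:
    ``local`` acts on the grid itself and ``R`` maps a flattened ``Psi`` of
    shape ``(n1, n2+2)`` (``into=0``) or ``(n1+2, n2)`` (``into=1``) onto
    the grid.
    """
    d1, d2 = n1 + 1, n2 + 1
    local = np.zeros((d1 * d2, d1 * d2))
    if into == 0:
        R = np.zeros((d1 * d2, n1 * (n2 + 2)))
        for i in range(d1):
            for j in range(d2):
                row = i * d2 + j
                local[row, row] += -i
                if i < n1:
                    local[row, (i + 1) * d2 + j] += i + 1
                w = n1 * (j + 1) / (n2 + 1)
                if i >= 1:
                    R[row, (i - 1) * (n2 + 2) + (j + 1)] += w
                if i <= n1 - 1:
                    R[row, i * (n2 + 2) + (j + 1)] -= w
        return local, R
    elif into == 1:
        R = np.zeros((d1 * d2, (n1 + 2) * n2))
        for i in range(d1):
            for j in range(d2):
                row = i * d2 + j
                local[row, row] += -j
                if j < n2:
                    local[row, i * d2 + (j + 1)] += j + 1
                w = n2 * (i + 1) / (n1 + 1)
                if j >= 1:
                    R[row, (i + 1) * n2 + (j - 1)] += w
                if j <= n2 - 1:
                    R[row, (i + 1) * n2 + j] -= w
        return local, R
    raise ValueError("into must be 0 or 1")


@lru_cache(maxsize=None)
def _psi_same_level(n1: int, n2: int, into: int) -> np.ndarray:
    """Jackknife closure: estimate ``Psi`` from the grid itself."""
    if into == 0:
        # axis-2 one genome up (jackknife), axis-1 one lineage down (exact)
        return np.kron(_lineage_drop_matrix(n1), jackknife_matrix(n2))
    return np.kron(jackknife_matrix(n1), _lineage_drop_matrix(n2))


@lru_cache(maxsize=None)
def _psi_from_above(n1: int, n2: int, into: int) -> np.ndarray:
    """Exact ``Psi`` from the next ladder level ``(n1+1, n2+1)``.

    ``Psi`` for ``into=0`` has sizes ``(n1-1, n2+1)``: two exact
    one-lineage drops on the receiving axis of the level-above grid.
    """
    if into == 0:
        drop2 = _lineage_drop_matrix(n1) @ _lineage_drop_matrix(n1 + 1)
        return np.kron(drop2, np.eye(n2 + 2))
    drop2 = _lineage_drop_matrix(n2) @ _lineage_drop_matrix(n2 + 1)
    return np.kron(np.eye(n1 + 2), drop2)


@lru_cache(maxsize=None)
def migration_operator(n1: int, n2: int, into: int) -> np.ndarray:
    """Single-grid migration operator (jackknife-closed), unit rate."""
    local, R = _migration_pieces(n1, n2, into)
    return local + R @ _psi_same_level(n1, n2, into)


def equilibrium_1d(n: int, theta: float = 1.0) -> np.ndarray:
    """Standard neutral sample spectrum ``theta / i`` (corners zero)."""
    phi = np.zeros(n + 1)
    phi[1:n] = theta / np.arange(1, n)
    return phi


def _size_trajectory(nu_start: float, nu_end: float, dynamics: str, frac: np.ndarray) -> np.ndarray:
    if dynamics == "sudden":
        return np.full_like(frac, nu_end)
    if dynamics == "linear":
        return nu_start + (nu_end - nu_start) * frac
    if dynamics == "exponential":
        return nu_start * (nu_end / nu_start) ** frac
    raise ValueError(f"unknown dynamics {dynamics!r}")


def _integrate_linear(
    phi: np.ndarray, A_of_t, B: np.ndarray, duration: float, constant: bool,
    dt: float | None = None,
):
    """Crank-Nicolson integration of ``dphi/dt = A(t) phi + B``."""
    steps = _n_steps(duration, dt)
    dt = duration / steps
    if constant:
        A = A_of_t(0.5 * dt)
        I = np.eye(A.shape[0])
        lu = lu_factor(I - 0.5 * dt * A, check_finite=False)
        fwd = I + 0.5 * dt * A
        dtB = dt * B
        for _ in range(steps):
            phi = lu_solve(lu, fwd @ phi + dtB, check_finite=False)
        return phi
    I = np.eye(len(phi))
    t = 0.0
    for _ in range(steps):
        A = A_of_t(t + 0.5 * dt)
        phi = np.linalg.solve(I - 0.5 * dt * A, (I + 0.5 * dt * A) @ phi + dt * B)
        t += dt
    return phi


def _integrate_1d_epoch(
    phi: np.ndarray, epoch: Epoch, nu_start: float, theta: float, dt: float | None = None
) -> np.ndarray:
    n = len(phi) - 1
    D = drift_matrix(n)
    B = np.zeros(n + 1)
    B[1] = n * theta / 2.0
    nu_end = epoch.sizes[0]
    dyn = epoch.dynamics[0]
    constant = dyn == "sudden" or np.isclose(nu_start, nu_end)

    def A_of_t(t: float) -> np.ndarray:
        nu = _size_trajectory(nu_start, nu_end, dyn, np.asarray(t / epoch.duration))
        return D / (2.0 * float(nu))

    return _integrate_linear(phi, A_of_t, B, epoch.duration, constant, dt=dt)


@lru_cache(maxsize=None)
def _ladder_blocks(n1: int, n2: int, depth: int):
    """Constant matrices of the two-deme ladder system.

    Level ``k`` holds the spectrum at sizes ``(n1+k, n2+k)``; its migration
    term needs the spectrum with one genome shifted between demes, which is
    obtained *exactly* from level ``k+1`` by lineage-drop projections.
    Only the top level closes on itself through the jackknife, and that
    truncation error is damped by a factor of order ``(M t)^depth / depth!``
    before it reaches level 0 -- the returned answer.

    Returns per-level slices plus drift/migration blocks for assembling the
    time-dependent generator.
    """
    dims = [(n1 + k + 1) * (n2 + k + 1) for k in range(depth + 1)]
    offsets = np.concatenate([[0], np.cumsum(dims)])
    total = int(offsets[-1])
    drift1 = np.zeros((total, total))
    drift2 = np.zeros((total, total))
    mig = {0: np.zeros((total, total)), 1: np.zeros((total, total))}
    for k in range(depth + 1):
        a, b = offsets[k], offsets[k + 1]
        m1, m2 = n1 + k, n2 + k
        drift1[a:b, a:b] = np.kron(drift_matrix(m1), np.eye(m2 + 1))
        drift2[a:b, a:b] = np.kron(np.eye(m1 + 1), drift_matrix(m2))
        for into in (0, 1):
            local, R = _migration_pieces(m1, m2, into)
            mig[into][a:b, a:b] += local
            if k < depth:
                up = R @ _psi_from_above(m1, m2, into)
                mig[into][a:b, offsets[k + 1] : offsets[k + 2]] += up
            else:
                mig[into][a:b, a:b] += R @ _psi_same_level(m1, m2, into)
    return dims, offsets, drift1, drift2, mig[0], mig[1]


def _integrate_2d_epoch(
    stack: np.ndarray,
    epoch: Epoch,
    start_sizes: tuple[float, float],
    n1: int,
    n2: int,
    theta: float,
    depth: int,
    dt: float | None = None,
) -> np.ndarray:
    dims, offsets, D1, D2, Mig1, Mig2 = _ladder_blocks(n1, n2, depth)
    B = np.zeros(int(offsets[-1]))
    for k in range(depth + 1):
        a = offsets[k]
        m1, m2 = n1 + k, n2 + k
        B[a + 1 * (m2 + 1) + 0] = m1 * theta / 2.0  # entry (1, 0)
        B[a + 0 * (m2 + 1) + 1] = m2 * theta / 2.0  # entry (0, 1)
    M_into1 = float(epoch.migration[1, 0])  # forward flow 2 -> 1
    M_into2 = float(epoch.migration[0, 1])  # forward flow 1 -> 2
    Mig = M_into1 * Mig1 + M_into2 * Mig2

    nu1_end, nu2_end = epoch.sizes
    dyn1, dyn2 = epoch.dynamics
    constant = (dyn1 == "sudden" or np.isclose(start_sizes[0], nu1_end)) and (
        dyn2 == "sudden" or np.isclose(start_sizes[1], nu2_end)
    )

    def A_of_t(t: float) -> np.ndarray:
        frac = np.asarray(t / epoch.duration)
        nu1 = float(_size_trajectory(start_sizes[0], nu1_end, dyn1, frac))
        nu2 = float(_size_trajectory(start_sizes[1], nu2_end, dyn2, frac))
        if not (np.isfinite(nu1) and np.isfinite(nu2)) or nu1 <= 0 or nu2 <= 0:
            raise FloatingPointError(f"non-finite deme size in epoch (nu1={nu1}, nu2={nu2})")
        return D1 / (2.0 * nu1) + D2 / (2.0 * nu2) + Mig

    return _integrate_linear(stack, A_of_t, B, epoch.duration, constant, dt=dt)


@lru_cache(maxsize=None)
def _split_matrix(n1: int, n2: int) -> np.ndarray:
    """Linear map from the pooled 1D spectrum onto the two-deme grid.

    ``k`` derived copies among ``n1 + n2`` exchangeable genomes land as
    ``(i, k - i)`` with hypergeometric probability
    ``C(n1, i) C(n2, k-i) / C(n1+n2, k)``.
    """
    n = n1 + n2

    def logc(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    S = np.zeros(((n1 + 1) * (n2 + 1), n + 1))
    for k in range(n + 1):
        i = np.arange(max(0, k - n2), min(n1, k) + 1)
        w = np.exp(logc(n1, i) + logc(n2, k - i) - logc(n, k))
        S[i * (n2 + 1) + (k - i), k] = w
    return S


def split_to_grid(phi1d: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """Distribute a one-deme spectrum over a two-deme grid exactly."""
    n = len(phi1d) - 1
    if n != n1 + n2:
        raise ValueError("1D spectrum size must equal n1 + n2")
    return (_split_matrix(n1, n2) @ phi1d).reshape(n1 + 1, n2 + 1)


def expected_sfs_1d(
    model: DemographicModel, n: int, theta: float = 1.0, dt: float | None = None
) -> np.ndarray:
    """Expected one-deme sample SFS for a no-split model."""
    if model.has_split:
        raise ValueError("model has a split; use expected_sfs")
    phi = equilibrium_1d(n, theta)
    sizes = (1.0,)
    for k, ep in enumerate(model.epochs):
        phi = _integrate_1d_epoch(phi, ep, sizes[0], theta, dt=dt)
        sizes = ep.sizes
    return phi


def _project_1d(phi: np.ndarray, m: int) -> np.ndarray:
    """Exact hypergeometric down-projection of a one-deme spectrum."""
    from .sfs import projection_matrix

    n = len(phi) - 1
    if m == n:
        return phi
    return projection_matrix(n, m) @ phi


def expected_sfs(
    model: DemographicModel,
    n1: int,
    n2: int,
    theta: float = 1.0,
    guard: int = 4,
    dt: float | None = None,
) -> SpectrumGrid:
    """Expected unfolded joint SFS (counts scaled by ``theta``).

    For no-split models the two samples are exchangeable subsamples of one
    deme: the one-deme spectrum of ``n1 + n2`` genomes is computed and
    redistributed over the grid.  Entries are linear in ``theta``.

    ``guard`` is the ladder depth used for models with migration (the only
    approximate case): the jackknife truncation error enters ``guard``
    exact-coupling levels above the output grid and is damped on the way
    down.  ``guard=0`` closes on the output grid directly (fastest); the
    default favours accuracy.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n1, n2 >= 2")
    n = n1 + n2
    if not model.has_split:
        phi = expected_sfs_1d(model, n, theta, dt=dt)
        return SpectrumGrid(np.maximum(split_to_grid(phi, n1, n2), 0.0), folded=False)

    has_migration = any(np.any(ep.migration > 0) for ep in model.epochs)
    depth = int(guard) if has_migration else 0
    phi = equilibrium_1d(n + 2 * depth, theta)
    stack: np.ndarray | None = None
    for k, ep in enumerate(model.epochs):
        start = model.size_at_epoch_start(k)
        if k == model.split_epoch:
            stack = np.concatenate(
                [
                    split_to_grid(
                        _project_1d(phi, n1 + n2 + 2 * lev), n1 + lev, n2 + lev
                    ).ravel()
                    for lev in range(depth + 1)
                ]
            )
        if stack is None:
            phi = _integrate_1d_epoch(phi, ep, start[0], theta, dt=dt)
        else:
            stack = _integrate_2d_epoch(
                stack, ep, (start[0], start[1]), n1, n2, theta, depth, dt=dt
            )
    assert stack is not None
    grid = stack[: (n1 + 1) * (n2 + 1)].reshape(n1 + 1, n2 + 1)
    return SpectrumGrid(np.maximum(grid, 0.0), folded=False)


def expected_sfs_catalog(
    name: str,
    params,
    n1: int,
    n2: int,
    theta: float = 1.0,
    guard: int = 4,
    dt: float | None = None,
) -> SpectrumGrid:
    """Convenience wrapper: expected SFS for a named catalog model."""
    entry = CATALOG[name]
    if len(params) != len(entry.param_names):
        raise ValueError(
            f"{name} expects parameters {entry.param_names}, got {len(params)}"
        )
    return expected_sfs(entry.build(params), n1, n2, theta, guard=guard, dt=dt)
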