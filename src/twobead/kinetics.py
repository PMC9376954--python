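"""Aggregation-fragmentation kinetics: mean-field ODEs, exact stochastic
simulation, a small-system master-equation oracle, and the global fitter.

Model
-----
Clusters of i chains (i = 1..N, closed finite system) interconvert through

    C_i + C_j  <->  C_{i+j}

with size-dependent rate constants derived from three parameters:

    k+_{i,j} = q k+  and  k-_{i,j} = q k-   when i = 1 or j = 1,
    k+_{i,j} =   k+  and  k-_{i,j} =   k-   otherwise,

i.e. monomers attach and detach faster than larger clusters by the common
factor q.  Because every channel shares the same forward/backward ratio
k+/k-, the model satisfies detailed balance.

Conventions (symmetric 1/2 on both sides, which is what exact detailed
balance requires together with the pair-counting argument): the aggregation
flux of an (i, j) channel is k+_{ij} c_i c_j for i != j and
k+_{ii} c_i^2 / 2 for i = j (the number of (i,i) pairs is ~ c_i^2/2); the
fragmentation event rate of the unordered channel (j, k) is k-_{jk} c_{j+k}
for j != k and k-_{jj} c_{2j} / 2 for the equal split.  The stochastic
propensities use the exact pair counts m_i m_j / V and m_i (m_i - 1) / (2V).

Mean-field rate equations (size truncated at N; sums run over feasible
sizes only):

    dc_i/dt = 1/2 sum_{j+k=i} k+_{jk} c_j c_k  -  c_i sum_{j<=N-i} k+_{ij} c_j
              - 1/2 sum_{j+k=i} k-_{jk} c_i    +  sum_{k<=N-i} k-_{ik} c_{i+k}

(all sums over ordered (j, k); the j = i aggregation loss term then counts
k+ c_i^2, i.e. two i-clusters consumed per i+i event, and the equal-split
factors work out as above).  Mass sum_i i c_i is conserved exactly by
construction.

Units: k+ in nm^3/ns, k- in ns^-1, volume V in nm^3, time in ns,
concentrations in nm^-3; cluster numbers n_i = c_i V.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize as scipy_minimize
from scipy.optimize import root

from .clustering import KineticCurves

#: Default reaction volume: the (35 nm)^3 simulation box.
DEFAULT_VOLUME = 35.0 ** 3


@dataclass(frozen=True)
class KineticParameters:
    """Three-parameter rate model for a closed system of N chains in volume V."""

    k_plus: float          # nm^3 / ns
    k_minus: float         # ns^-1
    q: float               # dimensionless monomer rate ratio
    N: int = 72            # total number of chains
    V: float = DEFAULT_VOLUME  # nm^3

    def __post_init__(self) -> None:
        if self.k_plus < 0 or self.k_minus < 0:
            raise ValueError("rate constants must be non-negative")
        if self.q <= 0:
            raise ValueError("q must be positive")
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.V <= 0:
            raise ValueError("V must be positive")

    def rate_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """(K+, K-) as (N+1, N+1) arrays indexed by cluster sizes 1..N.

        Symmetric in (i, j); row/column 0 is unused padding.
        """
        n = self.N
        kp = np.full((n + 1, n + 1), self.k_plus)
        km = np.full((n + 1, n + 1), self.k_minus)
        kp[1, :] = kp[:, 1] = self.q * self.k_plus
        km[1, :] = km[:, 1] = self.q * self.k_minus
        kp[0, :] = kp[:, 0] = 0.0
        km[0, :] = km[:, 0] = 0.0
        return kp, km


def monomer_start(N: int) -> np.ndarray:
    """Initial counts: N free monomers.  Index i holds the number of i-clusters."""
    m = np.zeros(N + 1, dtype=int)
    m[1] = N
    return m


# ---------------------------------------------------------------------------
# mean-field rate equations
# ---------------------------------------------------------------------------

class _RHS:
    """Precomputed operators for the mean-field right-hand side."""

    def __init__(self, params: KineticParameters):
        self.params = params
        n = params.N
        kp, km = params.rate_matrices()
        self.kp = kp[1:, 1:]                     # (n, n), sizes 1..n
        sizes = np.arange(1, n + 1)
        self.sizes = sizes
        # feasibility mask: i + j <= n
        self.feasible = (sizes[:, None] + sizes[None, :]) <= n
        self.kp_feas = self.kp * self.feasible
        self.sum_idx = (sizes[:, None] + sizes[None, :] - 1)  # target index of (i, j)
        self.sum_idx_flat = np.where(self.feasible, self.sum_idx, n).ravel()
        # fragmentation loss coefficient: S_i = 1/2 sum_{j=1}^{i-1} k-_{j, i-j}
        S = np.zeros(n)
        for i in range(2, n + 1):
            j = np.arange(1, i)
            S[i - 1] = 0.5 * km[j, i - j].sum()
        self.frag_loss = S
        # fragmentation gain operator: (A c)_j = sum_k k-_{j,k} c_{j+k}
        A = np.zeros((n, n))
        for j in range(1, n + 1):
            for k in range(1, n - j + 1):
                A[j - 1, j + k - 1] += km[j, k]
        self.frag_gain = A

    def __call__(self, t: float, c: np.ndarray) -> np.ndarray:
        outer = self.kp * (c[:, None] * c[None, :])
        gain = 0.5 * np.bincount(self.sum_idx_flat,
                                 weights=(outer * self.feasible).ravel(),
                                 minlength=self.params.N + 1)[: self.params.N]
        loss = c * (self.kp_feas @ c)
        return gain - loss - self.frag_loss * c + self.frag_gain @ c


def smoluchowski_rhs(concentrations: np.ndarray, params: KineticParameters) -> np.ndarray:
    """dc/dt for concentrations c_1..c_N (nm^-3), validating the state."""
    c = np.asarray(concentrations, dtype=float)
    if len(c) != params.N:
        raise ValueError(f"state length {len(c)} != N = {params.N}")
    if np.any(c < 0):
        raise ValueError("negative concentrations")
    return _RHS(params)(0.0, c)


def solve_kinetics(params: KineticParameters, initial_counts: np.ndarray,
                   t_grid: np.ndarray, rtol: float = 1e-8, atol: float = 1e-13,
                   return_full: bool = False):
    """Integrate the rate equations; returns cluster numbers n_i(t) = c_i V.

    ``initial_counts`` is indexed by cluster size (entry 0 ignored).  Mass
    is conserved to solver tolerance.  Returns a :class:`KineticCurves`
    (n1, n2, n3, nc), plus the full (T, N) number matrix when
    ``return_full`` is set.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    m0 = np.asarray(initial_counts, dtype=float)
    if len(m0) == params.N + 1:
        m0 = m0[1:]
    if len(m0) != params.N:
        raise ValueError("initial counts must have length N (or N+1 with padding)")
    c0 = m0 / params.V
    rhs = _RHS(params)
    t0, t1 = float(t_grid[0]), float(t_grid[-1])
    sol = solve_ivp(rhs, (t0, t1), c0, t_eval=t_grid, method="LSODA",
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"kinetics ODE solver failed: {sol.message}")
    n = sol.y.T * params.V                      # (T, N)
    curves = KineticCurves(
        time_ns=t_grid,
        mean={"n1": n[:, 0], "n2": n[:, 1], "n3": n[:, 2], "nc": n.sum(axis=1)},
        sem={}, n_repeats=1)
    if return_full:
        return curves, n
    return curves


def find_stationary_state(params: KineticParameters, mass: float | None = None,
                          t_relax: float = None) -> np.ndarray:
    """Stationary concentrations c* with sum_i i c_i V = mass (default N).

    Relaxes the ODE to long times, then polishes with a Newton solve of
    rhs = 0 under the mass constraint (c_1 eliminated).
    """
    if params.k_minus <= 0:
        raise ValueError("no coexistence stationary state without fragmentation")
    mass = params.N if mass is None else mass
    if t_relax is None:
        t_relax = 50.0 / min(params.k_minus, params.q * params.k_minus)
    rhs = _RHS(params)
    c0 = np.zeros(params.N)
    c0[0] = mass / params.V
    sol = solve_ivp(rhs, (0.0, t_relax), c0, method="LSODA", rtol=1e-10, atol=1e-16)
    c_end = sol.y[:, -1]
    sizes = np.arange(1, params.N + 1)

    def residual(c_tail):
        c1 = (mass / params.V - sizes[1:] @ c_tail) / 1.0
        c = np.concatenate(([c1], c_tail))
        return rhs(0.0, c)[1:]

    out = root(residual, c_end[1:], method="hybr", tol=1e-14)
    c_tail = out.x
    c1 = mass / params.V - sizes[1:] @ c_tail
    c = np.concatenate(([c1], c_tail))
    if np.any(c < -1e-15):
        raise RuntimeError("stationary solve produced negative concentrations")
    return np.maximum(c, 0.0)


def detailed_balance_residuals(params: KineticParameters, stationary: np.ndarray,
                               stationarity_tol: float = 1e-6) -> dict:
    """Per-channel forward-minus-backward fluxes in a stationary state.

    For each unordered channel (j, k): forward flux k+_{jk} c_j c_k (halved
    for j = k), backward flux k-_{jk} c_{j+k} (halved for j = k).  Returns
    the channel list, raw residuals, and the maximum residual relative to
    the largest channel flux.  Raises if the input state is not stationary,
    or reports non-equilibrium when fragmentation is absent.
    """
    c = np.asarray(stationary, dtype=float)
    if len(c) != params.N:
        raise ValueError("stationary state must have length N")
    if params.k_minus == 0:
        return {"equilibrium": False, "channels": [], "residuals": np.array([]),
                "max_relative": np.inf,
                "note": "irreversible limit: no stationary coexistence state"}
    r = _RHS(params)(0.0, c)
    scale = max(np.abs(c).max(), 1e-300)
    if np.abs(r).max() > stationarity_tol * scale * max(params.k_plus / params.V, params.k_minus):
        raise ValueError("input state is not stationary")
    kp, km = params.rate_matrices()
    channels = []
    res = []
    flux = []
    for j in range(1, params.N + 1):
        for k in range(j, params.N - j + 1):
            half = 0.5 if j == k else 1.0
            fwd = half * kp[j, k] * c[j - 1] * c[k - 1]
            bwd = half * km[j, k] * c[j + k - 1]
            channels.append((j, k))
            res.append(fwd - bwd)
            flux.append(max(fwd, bwd))
    res = np.array(res)
    flux = np.array(flux)
    fmax = flux.max() if len(flux) else 1.0
    return {"equilibrium": True, "channels": channels, "residuals": res,
            "max_relative": float(np.abs(res).max() / fmax)}


# ---------------------------------------------------------------------------
# Gillespie stochastic simulation
# ---------------------------------------------------------------------------

class _Channels:
    """Flat channel tables for the SSA and the master equation."""

    def __init__(self, params: KineticParameters):
        n = params.N
        kp, km = params.rate_matrices()
        agg = [(i, j) for i in range(1, n + 1) for j in range(i, n + 1) if i + j <= n]
        self.agg_i = np.array([a for a, _ in agg], dtype=int)
        self.agg_j = np.array([b for _, b in agg], dtype=int)
        eq = self.agg_i == self.agg_j
        self.agg_coeff = kp[self.agg_i, self.agg_j] / params.V * np.where(eq, 0.5, 1.0)
        self.agg_eq = eq.astype(int)
        # fragmentation channels: parent s -> (j, s - j), j <= s - j
        frag = [(j, s) for s in range(2, n + 1) for j in range(1, s // 2 + 1)]
        self.frag_j = np.array([j for j, _ in frag], dtype=int)
        self.frag_s = np.array([s for _, s in frag], dtype=int)
        self.frag_k = self.frag_s - self.frag_j
        eqf = self.frag_j == self.frag_k
        self.frag_coeff = km[self.frag_j, self.frag_k] * np.where(eqf, 0.5, 1.0)

    def propensities(self, m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pa = self.agg_coeff * m[self.agg_i] * (m[self.agg_j] - self.agg_eq)
        pf = self.frag_coeff * m[self.frag_s]
        return pa, pf


def gillespie_run(params: KineticParameters, initial_counts: np.ndarray,
                  sample_times: np.ndarray, seed: int,
                  channels: _Channels | None = None) -> np.ndarray:
    """One exact SSA realization sampled on a fixed time grid.

    Returns an (len(sample_times), N+1) integer array of cluster counts
    (column i = number of i-clusters; column 0 unused).  Mass
    sum_i i m_i is conserved exactly at every event.
    """
    m = np.asarray(initial_counts, dtype=int).copy()
    if len(m) == params.N:
        m = np.concatenate(([0], m))
    if len(m) != params.N + 1:
        raise ValueError("initial counts must have length N or N+1")
    if int(np.arange(len(m)) @ m) != params.N:
        raise ValueError("initial counts must carry total mass N")
    ch = channels if channels is not None else _Channels(params)
    rng = np.random.default_rng(seed)
    sample_times = np.asarray(sample_times, dtype=float)
    out = np.empty((len(sample_times), params.N + 1), dtype=int)
    t = 0.0
    ptr = 0
    while True:
        pa, pf = ch.propensities(m)
        total = pa.sum() + pf.sum()
        t_next = t + rng.exponential(1.0 / total) if total > 0.0 else np.inf
        while ptr < len(sample_times) and sample_times[ptr] < t_next:
            out[ptr] = m
            ptr += 1
        if ptr >= len(sample_times):
            break
        t = t_next
        u = rng.random() * total
        ca = np.cumsum(pa)
        if u < (ca[-1] if len(ca) else 0.0):
            k = int(np.searchsorted(ca, u, side="right"))
            i, j = int(ch.agg_i[k]), int(ch.agg_j[k])
            m[i] -= 1
            m[j] -= 1
            m[i + j] += 1
        else:
            u -= ca[-1] if len(ca) else 0.0
            cf = np.cumsum(pf)
            k = int(np.searchsorted(cf, u, side="right"))
            j, s = int(ch.frag_j[k]), int(ch.frag_s[k])
            m[s] -= 1
            m[j] += 1
            m[s - j] += 1
    return out


def gillespie_ensemble(params: KineticParameters, initial_counts: np.ndarray,
                       sample_times: np.ndarray, n_reps: int, seed: int,
                       return_counts: bool = False):
    """Ensemble of SSA realizations; returns averaged KineticCurves.

    The SEM is the across-realization standard deviation of the mean.  With
    ``return_counts`` also returns the (n_reps, T, N+1) raw count array.
    """
    ch = _Channels(params)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n_reps)]
    sample_times = np.asarray(sample_times, dtype=float)
    counts = np.empty((n_reps, len(sample_times), params.N + 1), dtype=int)
    for r in range(n_reps):
        counts[r] = gillespie_run(params, initial_counts, sample_times,
                                  seeds[r], channels=ch)
    mean = {}
    sem = {}
    series = {
        "n1": counts[:, :, 1].astype(float),
        "n2": counts[:, :, 2].astype(float),
        "n3": counts[:, :, 3].astype(float),
        "nc": counts[:, :, 1:].sum(axis=2).astype(float),
    }
    for name, arr in series.items():
        mean[name] = arr.mean(axis=0)
        sem[name] = (arr.std(axis=0, ddof=1) / np.sqrt(n_reps)
                     if n_reps > 1 else np.zeros(arr.shape[1]))
    curves = KineticCurves(time_ns=sample_times, mean=mean, sem=sem, n_repeats=n_reps)
    if return_counts:
        return curves, counts
    return curves


# ---------------------------------------------------------------------------
# exact master equation (small N)
# ---------------------------------------------------------------------------

def _partitions(n: int):
    """Integer partitions of n as count vectors m[0..n] (m[i] = #i-clusters)."""
    def gen(remaining, max_part, current):
        if remaining == 0:
            yield list(current)
            return
        for p in range(min(max_part, remaining), 0, -1):
            current.append(p)
            yield from gen(remaining - p, p, current)
            current.pop()
    for parts in gen(n, n, []):
        m = np.zeros(n + 1, dtype=int)
        for p in parts:
            m[p] += 1
        yield m


MASTER_EQUATION_MAX_N = 10


def master_equation_solve(params: KineticParameters, initial_counts: np.ndarray,
                          t_grid: np.ndarray,
                          return_distribution: bool = False):
    """Exact ensemble means E[m_i(t)] over the partition state space.

    The state space is all integer partitions of N; only practical for
    N <= 10 (42 states at N = 10).  Uses the same channel rates as the SSA,
    so it is the exact oracle for the stochastic means.
    """
    n = params.N
    if n > MASTER_EQUATION_MAX_N:
        raise ValueError(
            f"N = {n} too large for exact enumeration (limit {MASTER_EQUATION_MAX_N}; "
            f"partition count grows super-polynomially)")
    states = list(_partitions(n))
    index = {tuple(s): a for a, s in enumerate(states)}
    ns = len(states)
    ch = _Channels(params)
    Q = np.zeros((ns, ns))  # generator: Q[a, b] = rate a -> b
    for a, m in enumerate(states):
        pa, pf = ch.propensities(m)
        for k in np.flatnonzero(pa > 0):
            m2 = m.copy()
            i, j = int(ch.agg_i[k]), int(ch.agg_j[k])
            m2[i] -= 1
            m2[j] -= 1
            m2[i + j] += 1
            Q[a, index[tuple(m2)]] += pa[k]
        for k in np.flatnonzero(pf > 0):
            m2 = m.copy()
            j, s = int(ch.frag_j[k]), int(ch.frag_s[k])
            m2[s] -= 1
            m2[j] += 1
            m2[s - j] += 1
            Q[a, index[tuple(m2)]] += pf[k]
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))

    m0 = np.asarray(initial_counts, dtype=int)
    if len(m0) == n:
        m0 = np.concatenate(([0], m0))
    p0 = np.zeros(ns)
    p0[index[tuple(m0)]] = 1.0

    t_grid = np.asarray(t_grid, dtype=float)
    sol = solve_ivp(lambda t, p: Q.T @ p, (float(t_grid[0]), float(t_grid[-1])),
                    p0, t_eval=t_grid, method="LSODA", rtol=1e-10, atol=1e-14)
    if not sol.success:
        raise RuntimeError(f"master equation solver failed: {sol.message}")
    P = sol.y.T                                   # (T, ns)
    M = np.array(states, dtype=float)             # (ns, n+1)
    means = P @ M                                 # (T, n+1)
    if return_distribution:
        return means, P, states, Q
    return means


def master_equation_stationary(params: KineticParameters) -> tuple[np.ndarray, list]:
    """Stationary distribution of the partition-state master equation."""
    _, _, states, Q = master_equation_solve(
        params, monomer_start(params.N), np.array([0.0, 1.0]),
        return_distribution=True)
    w, v = np.linalg.eig(Q.T)
    k = int(np.argmin(np.abs(w)))
    pi = np.real(v[:, k])
    pi = np.abs(pi) / np.abs(pi).sum()
    return pi, states


# ---------------------------------------------------------------------------
# global fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    params: KineticParameters
    cost: float
    success: bool
    n_evaluations: int
    message: str = ""
    start_costs: list = field(default_factory=list)


def fit_cost(params: KineticParameters, observed: KineticCurves,
             weights: dict[str, float] | None = None,
             rtol: float = 1e-7) -> float:
    """Sum of squared differences over the four curves and all time points."""
    w = weights or {}
    model = solve_kinetics(params, monomer_start(params.N),
                           observed.time_ns, rtol=rtol, atol=1e-12)
    cost = 0.0
    for name in KineticCurves.NAMES:
        diff = model.mean[name] - observed.mean[name]
        cost += w.get(name, 1.0) * float(diff @ diff)
    return cost


def fit_kinetics(observed: KineticCurves, guess: KineticParameters,
                 V: float | None = None, N: int | None = None,
                 weights: dict[str, float] | None = None,
                 n_starts: int = 5, seed: int = 0,
                 rtol: float = 1e-7) -> FitResult:
    """Globally fit (k+, k-, q) to observed n1/n2/n3/nc curves.

    Derivative-free simplex (Nelder-Mead) on log-parameters enforces
    positivity; ``n_starts`` runs start from the supplied guess and from
    seeded log-normal perturbations of it, and the best final cost wins.
    The fitted model starts from N free monomers.
    """
    V = guess.V if V is None else V
    N = guess.N if N is None else N
    rng = np.random.default_rng(seed)
    evaluations = 0

    def objective(x):
        nonlocal evaluations
        evaluations += 1
        p = KineticParameters(k_plus=float(np.exp(x[0])),
                              k_minus=float(np.exp(x[1])),
                              q=float(np.exp(x[2])), N=N, V=V)
        try:
            return fit_cost(p, observed, weights, rtol=rtol)
        except RuntimeError:
            return 1e30

    x0 = np.log([guess.k_plus, guess.k_minus, guess.q])
    best = None
    start_costs = []
    for s in range(n_starts):
        start = x0 if s == 0 else x0 + rng.normal(scale=0.3, size=3)
        res = scipy_minimize(objective, start, method="Nelder-Mead",
                             options={"xatol": 1e-6, "fatol": 1e-10,
                                      "maxiter": 2000})
        start_costs.append(float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
    fitted = KineticParameters(k_plus=float(np.exp(best.x[0])),
                               k_minus=float(np.exp(best.x[1])),
                               q=float(np.exp(best.x[2])), N=N, V=V)
    final_cost = fit_cost(fitted, observed, weights, rtol=rtol)
    return FitResult(params=fitted, cost=final_cost,
                     success=bool(best.success), n_evaluations=evaluations,
                     message=str(best.message), start_costs=start_costs)
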