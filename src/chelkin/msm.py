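"""Markov state model kinetics of coordination-state trajectories.

Pipeline: short unbiased replicas recording the (ligand, water)
coordination pair -> k-means++ microstates -> lagged transition-matrix
estimation (maximum likelihood, optionally detailed-balance constrained)
-> validation by implied timescales and the Chapman-Kolmogorov test ->
PCCA+ coarse-graining onto the chemically meaningful ML_i macrostates ->
mean first passage times -> molar formation/dissociation rate constants
with Bayesian (Dirichlet-posterior) credible intervals.

Rate-constant conversion. With gamma = N_Av * V (particle count per unit
molar concentration) and n_lig_eq = [L] * gamma the unbound ligand count
at equilibrium, a per-box forward hopping rate nu (s^-1) converts to the
bimolecular molar constant k_i = nu * gamma / n_lig_eq = nu / [L]
(L mol^-1 s^-1), while a backward hopping rate is already the
unimolecular k_-i (s^-1). This convention makes the ratio reproduce the
stepwise association constant, k_i / k_-i = K_i, and recovers the input
rates of a continuous-time Markov chain ground truth.

For chains with more than one binding step the inverse first-passage
time between adjacent macrostates folds in dwell times of the states
behind the source (for a birth-death chain 1/MFPT(i-1 -> i) =
a_i^+ * pi_{i-1} / sum_{j<=i-1} pi_j), so ``rates_from_msm`` also offers
a generator-based estimate (matrix logarithm of the coarse transition
matrix) that returns the elementary per-step rates; see the methods
note. Both routes give identical numbers for a single binding step.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import scipy.linalg
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .equilibrium import EquilibriumResult, SolutionComposition

__all__ = [
    "CoordTrajectory",
    "MicrostateModel",
    "MacrostateModel",
    "RateEstimate",
    "assign_microstates",
    "count_transitions",
    "estimate_transition_matrix",
    "stationary_distribution",
    "implied_timescales",
    "chapman_kolmogorov",
    "pcca_memberships",
    "pcca_coarse_grain",
    "mfpt",
    "rates_from_msm",
    "bayesian_rate_errors",
    "pk_from_rates",
]


@dataclass
class CoordTrajectory:
    """One replica's coordination-number time series.

    ``frames`` has shape (n_frames, 2): ligand (donor-atom) coordination
    then water coordination; ``dt`` is the saving interval in ps.
    """

    dt: float
    frames: np.ndarray
    replica_id: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.frames.ndim != 2 or self.frames.shape[1] != 2:
            raise ValueError("frames must have shape (n_frames, 2)")
        if self.frames.shape[0] < 2:
            raise ValueError("a trajectory needs at least 2 frames")
        if (self.frames < -0.5).any():
            raise ValueError("coordination numbers must be non-negative")


@dataclass
class MicrostateModel:
    """Discretized dynamics: cluster centers, assignments and, once
    estimated, the lagged count and transition matrices on the active
    (largest strongly connected) set."""

    centers: np.ndarray
    dtrajs: list[np.ndarray]
    dt: float
    lag: int | None = None
    count_matrix: np.ndarray | None = None
    transition_matrix: np.ndarray | None = None
    active_set: np.ndarray | None = None
    reversible: bool = True

    @property
    def n_states(self) -> int:
        return self.centers.shape[0]

    @property
    def lag_time(self) -> float:
        """Lag time in ps."""
        if self.lag is None:
            raise ValueError("model has no estimated lag")
        return self.lag * self.dt

    def active_dtrajs(self) -> list[np.ndarray]:
        """Assignments re-indexed to the active set; off-set frames -> -1."""
        if self.active_set is None:
            return self.dtrajs
        mapping = -np.ones(self.n_states, dtype=np.int64)
        mapping[self.active_set] = np.arange(self.active_set.size)
        return [mapping[d] for d in self.dtrajs]


@dataclass
class MacrostateModel:
    """PCCA+ coarse-graining of a microstate model onto ML_i macrostates.

    ``membership[m, a]`` is the fuzzy weight of microstate m in macrostate
    a; macrostates are ordered by increasing mean ligand coordination of
    their member centers, so index a maps onto species ML_a when the
    model resolves every step.
    """

    membership: np.ndarray
    macro_of_micro: np.ndarray
    macro_lig: np.ndarray
    transition_matrix: np.ndarray
    count_matrix: np.ndarray
    lag: int
    dt: float
    labels: list[str] = field(default_factory=list)

    @property
    def n_macrostates(self) -> int:
        return self.membership.shape[1]

    @property
    def lag_time(self) -> float:
        return self.lag * self.dt


@dataclass
class RateEstimate:
    """Molar formation/dissociation rate constants per binding step.

    ``forward[i]`` is k_{i+1} in L mol^-1 s^-1 (step ML_i + L -> ML_{i+1}),
    ``backward[i]`` the matching k_-(i+1) in s^-1. ``flags`` collects
    per-step annotations such as unobserved transitions.
    """

    forward: np.ndarray
    backward: np.ndarray
    gamma: float
    n_lig_eq: float
    forward_interval: np.ndarray | None = None
    backward_interval: np.ndarray | None = None
    flags: dict[int, str] = field(default_factory=dict)
    seed: int | None = None

    @property
    def n_steps(self) -> int:
        return self.forward.size


# ---------------------------------------------------------------------------
# discretization


def assign_microstates(
    trajs: Sequence[CoordTrajectory],
    k: int,
    seed: int = 0,
    max_fit_points: int = 200_000,
) -> MicrostateModel:
    """Cluster frames in (ligand, water) coordination space with k-means++.

    Lloyd iterations run to tolerance 1e-6 or 500 sweeps; when the pooled
    data exceeds ``max_fit_points`` the centers are fitted on a random
    subsample and all frames assigned by nearest center afterwards.
    """
    from sklearn.cluster import KMeans

    if not trajs:
        raise ValueError("no trajectories given")
    if k < 1:
        raise ValueError("k must be >= 1")
    dts = {t.dt for t in trajs}
    if len(dts) > 1:
        raise ValueError(f"replicas disagree on dt: {sorted(dts)}")
    data = np.vstack([t.frames for t in trajs])
    rng = np.random.default_rng(seed)
    fit_data = data
    if data.shape[0] > max_fit_points:
        idx = rng.choice(data.shape[0], size=max_fit_points, replace=False)
        fit_data = data[idx]
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=1,
        max_iter=500,
        tol=1e-6,
        random_state=int(rng.integers(2**31 - 1)),
    ).fit(fit_data)
    labels = km.predict(data)
    dtrajs = []
    ofs = 0
    for t in trajs:
        n = t.frames.shape[0]
        dtrajs.append(labels[ofs : ofs + n].astype(np.int64))
        ofs += n
    return MicrostateModel(centers=km.cluster_centers_, dtrajs=dtrajs, dt=trajs[0].dt)


# ---------------------------------------------------------------------------
# estimation


def count_transitions(
    dtrajs: Sequence[np.ndarray], lag: int, n_states: int
) -> np.ndarray:
    """Sliding-window transition counts at the given lag (frames)."""
    if lag < 1:
        raise ValueError("lag must be >= 1 frame")
    C = np.zeros((n_states, n_states), dtype=np.float64)
    for d in dtrajs:
        if d.size <= lag:
            continue
        a, b = d[:-lag], d[lag:]
        ok = (a >= 0) & (b >= 0)
        np.add.at(C, (a[ok], b[ok]), 1.0)
    return C


def _largest_scc(C: np.ndarray) -> np.ndarray:
    n, labels = connected_components(
        csr_matrix(C > 0), directed=True, connection="strong"
    )
    if n == 1:
        return np.arange(C.shape[0])
    weights = np.array([C[labels == i][:, labels == i].sum() for i in range(n)])
    return np.flatnonzero(labels == int(np.argmax(weights)))


def _reversible_mle(C: np.ndarray, tol: float = 1e-12, max_iter: int = 10_000) -> np.ndarray:
    """Detailed-balance-constrained maximum likelihood transition matrix.

    Self-consistent iteration on the symmetric edge weights x_ij
    (x_ij <- (c_ij + c_ji) / (c_i/x_i + c_j/x_j)).
    """
    Cs = C + C.T
    x = Cs.copy()
    x[Cs == 0] = 0.0
    ci = C.sum(axis=1)
    for _ in range(max_iter):
        xi = x.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            denom = ci[:, None] / xi[:, None] + ci[None, :] / xi[None, :]
            x_new = np.where(Cs > 0, Cs / denom, 0.0)
        delta = np.abs(x_new - x).max()
        x = x_new
        if delta < tol * max(1.0, x.max()):
            break
    T = x / x.sum(axis=1, keepdims=True)
    return T


def estimate_transition_matrix(
    model: MicrostateModel,
    lag: int,
    reversible: bool = True,
    require_states: Sequence[int] | None = None,
) -> MicrostateModel:
    """Estimate the row-stochastic transition matrix at ``lag`` frames.

    Estimation is restricted to the largest strongly connected component
    of the count graph. ``require_states`` raises if any listed
    microstate falls outside that active set.
    """
    C_full = count_transitions(model.dtrajs, lag, model.n_states)
    active = _largest_scc(C_full)
    if require_states is not None:
        missing = sorted(set(int(s) for s in require_states) - set(active.tolist()))
        if missing:
            raise ValueError(
                f"requested states {missing} are not in the connected set at lag {lag}"
            )
    C = C_full[np.ix_(active, active)]
    if reversible:
        T = _reversible_mle(C)
    else:
        rows = C.sum(axis=1, keepdims=True)
        T = C / rows
    assert np.allclose(T.sum(axis=1), 1.0, atol=1e-10)
    return MicrostateModel(
        centers=model.centers,
        dtrajs=model.dtrajs,
        dt=model.dt,
        lag=lag,
        count_matrix=C,
        transition_matrix=T,
        active_set=active,
        reversible=reversible,
    )


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Stationary distribution (leading left eigenvector, normalized)."""
    vals, vecs = scipy.linalg.eig(T, left=True, right=False)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# validation


def _sorted_eigenvalues(T: np.ndarray, reversible: bool) -> np.ndarray:
    vals = scipy.linalg.eigvals(T)
    if reversible:
        imag = np.abs(vals.imag).max()
        if imag > 1e-8:
            raise ValueError(
                f"reversible transition matrix has complex eigenvalues (|Im| = {imag:.2e})"
            )
        vals = vals.real
        return np.sort(vals)[::-1]
    order = np.argsort(-np.abs(vals))
    return vals[order]


def timescales_from_matrix(
    T: np.ndarray, lag_time: float, n_its: int = 3, reversible: bool = True
) -> np.ndarray:
    """Relaxation timescales of one transition matrix; eigenvalues at or
    above 1 map to infinity (non-decaying processes)."""
    vals = _sorted_eigenvalues(T, reversible)
    sub = np.asarray(vals[1 : n_its + 1], dtype=complex)
    mag = np.abs(sub)
    with np.errstate(divide="ignore"):
        t = -lag_time / np.log(mag)
    t[mag >= 1.0] = np.inf
    out = np.full(n_its, np.nan)
    out[: sub.size] = t
    return out


def implied_timescales(
    model: MicrostateModel,
    lags: Sequence[int],
    n_its: int = 3,
    reversible: bool = True,
    plateau_rtol: float = 0.10,
) -> dict:
    """Relaxation timescales t_i(tau) = -tau*dt / ln lambda_i(tau).

    Returns the timescale curves (ps) per lag plus the smallest lag at
    which every requested curve is flat within ``plateau_rtol`` relative
    to the next lag (None if no plateau is reached). Eigenvalues >= 1 map
    to infinite timescales.
    """
    lags = [int(l) for l in lags]
    if any(b <= a for a, b in zip(lags, lags[1:])):
        raise ValueError("lags must be strictly increasing")
    its = np.full((len(lags), n_its), np.nan)
    for r, lag in enumerate(lags):
        m = estimate_transition_matrix(model, lag, reversible=reversible)
        its[r] = timescales_from_matrix(
            m.transition_matrix, lag * model.dt, n_its, reversible
        )
    plateau = None
    for r in range(len(lags) - 1):
        a, b = its[r], its[r + 1]
        ok = np.isfinite(a) & np.isfinite(b)
        rel = np.abs(b[ok] - a[ok]) / np.maximum(np.abs(a[ok]), 1e-300)
        if (np.isinf(a) == np.isinf(b)).all() and (rel < plateau_rtol).all():
            plateau = lags[r]
            break
    return {"lags": np.array(lags), "timescales": its, "plateau_lag": plateau}


def chapman_kolmogorov(
    model: MicrostateModel,
    n_steps: int,
    sets: Sequence[Sequence[int]] | None = None,
    threshold: float = 0.10,
) -> dict:
    """Chapman-Kolmogorov self-consistency test.

    Compares the propagated model T(tau)^n against a re-estimated
    T(n*tau), through the probability of remaining in each (macro)state
    set when started from the stationary distribution restricted to it.
    """
    if model.transition_matrix is None or model.lag is None:
        raise ValueError("estimate a transition matrix first")
    lag = model.lag
    long_lag = lag * n_steps
    if all(d.size <= long_lag for d in model.dtrajs):
        raise ValueError(f"no trajectory long enough for lag {long_lag} frames")
    active = model.active_set
    n_active = active.size
    if sets is None:
        sets = [[i] for i in range(n_active)]
    # re-index sets to active-set coordinates
    pos = -np.ones(model.n_states, dtype=int)
    pos[active] = np.arange(n_active)
    sets_a = []
    for s in sets:
        sa = [int(pos[i]) for i in s if pos[i] >= 0]
        if not sa:
            raise ValueError("a requested set has no states in the active set")
        sets_a.append(sa)
    T = model.transition_matrix
    Tn = np.linalg.matrix_power(T, n_steps)
    m_long = estimate_transition_matrix(model, long_lag, reversible=model.reversible)
    pos_long = -np.ones(model.n_states, dtype=int)
    pos_long[m_long.active_set] = np.arange(m_long.active_set.size)
    pi = stationary_distribution(T)
    divergences = []
    for s in sets_a:
        w = np.zeros(n_active)
        w[s] = pi[s]
        w /= w.sum()
        p_model = float(w @ Tn[:, s].sum(axis=1))
        orig = active[s]
        s_long = [int(pos_long[i]) for i in orig if pos_long[i] >= 0]
        w_long = np.zeros(m_long.active_set.size)
        if not s_long:
            raise ValueError("insufficient data: set unsampled at the long lag")
        for i, p in zip(orig, pi[s]):
            if pos_long[i] >= 0:
                w_long[pos_long[i]] = p
        w_long /= w_long.sum()
        p_est = float(w_long @ m_long.transition_matrix[:, s_long].sum(axis=1))
        divergences.append(abs(p_model - p_est))
    div = np.array(divergences)
    return {
        "divergence": div,
        "max_divergence": float(div.max()),
        "passed": bool(div.max() <= threshold),
        "threshold": threshold,
        "n_steps": n_steps,
    }


# ---------------------------------------------------------------------------
# PCCA+ coarse-graining


def pcca_memberships(T: np.ndarray, n_macro: int) -> np.ndarray:
    """PCCA+ fuzzy memberships from the dominant invariant subspace.

    Uses the inner-simplex vertex construction on the first ``n_macro``
    (pi-orthonormal) eigenvectors of a reversible transition matrix:
    the most spread-out states are taken as simplex vertices and every
    state expressed in barycentric coordinates, clipped to [0, 1] and
    row-normalized.
    """
    n = T.shape[0]
    if not 1 < n_macro <= n:
        raise ValueError("need 1 < n_macro <= n_microstates")
    pi = stationary_distribution(T)
    # symmetrized eigenproblem; requires detailed balance to be real
    D = np.sqrt(pi)
    S = (T * D[None, :]) / D[:, None]
    S = 0.5 * (S + S.T)
    vals, vecs = scipy.linalg.eigh(S)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    gap_vals = vals[:n_macro]
    if gap_vals[-1] <= 0:
        raise ValueError(
            f"only {int((vals > 0).sum())} positive dominant eigenvalues; "
            f"choose a smaller n_macro than {n_macro}"
        )
    X = vecs[:, :n_macro] / D[:, None]
    X[:, 0] = 1.0  # exact constant eigenvector
    # inner simplex algorithm: pick spanning vertex states
    idx = np.zeros(n_macro, dtype=int)
    ortho = X.copy()
    norms = np.linalg.norm(ortho, axis=1)
    idx[0] = int(np.argmax(norms))
    ortho -= ortho[idx[0]]
    for k in range(1, n_macro):
        norms = np.linalg.norm(ortho, axis=1)
        idx[k] = int(np.argmax(norms))
        v = ortho[idx[k]].copy()
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            raise ValueError(
                "PCCA+ simplex construction failed (degenerate vertex); "
                "try a different n_macro"
            )
        v /= nv
        ortho -= np.outer(ortho @ v, v)
    A = X[idx]
    try:
        chi = X @ np.linalg.inv(A)
    except np.linalg.LinAlgError as e:
        raise ValueError(
            "PCCA+ membership optimization failed (singular vertex matrix); "
            "try a different n_macro"
        ) from e
    chi = np.clip(chi, 0.0, 1.0)
    rows = chi.sum(axis=1)
    if (rows < 1e-12).any():
        raise ValueError("PCCA+ produced an empty membership row; try a different n_macro")
    return chi / rows[:, None]


def pcca_coarse_grain(
    model: MicrostateModel,
    n_macro: int,
    labels: Sequence[str] | None = None,
) -> MacrostateModel:
    """Coarse-grain the microstate model onto metastable macrostates.

    Crisp assignment is by largest membership (ties resolved toward the
    macrostate with lower ligand coordination); macrostates are relabeled
    in order of increasing mean ligand coordination so that index a
    corresponds to the species ML_a ladder. The coarse transition matrix
    is re-estimated from the macrostate-mapped trajectories at the model
    lag.
    """
    if model.transition_matrix is None:
        raise ValueError("estimate a transition matrix first")
    chi = pcca_memberships(model.transition_matrix, n_macro)
    pi = stationary_distribution(model.transition_matrix)
    lig = model.centers[model.active_set, 0]
    # provisional macrostate means, used to order and to break ties
    provisional = np.array(
        [np.average(lig, weights=np.maximum(chi[:, a] * pi, 1e-300)) for a in range(n_macro)]
    )
    order = np.argsort(provisional)
    chi = chi[:, order]
    macro_lig_mean = provisional[order]
    best = chi.max(axis=1)
    crisp = np.empty(chi.shape[0], dtype=np.int64)
    for m in range(chi.shape[0]):
        tied = np.flatnonzero(chi[m] >= best[m] - 1e-12)
        crisp[m] = tied[0]  # lowest ligand-coordination macrostate wins ties
    if len(np.unique(crisp)) < n_macro:
        raise ValueError("a macrostate received no microstates; reduce n_macro")
    # macrostate trajectories and coarse count/transition matrices
    micro_to_macro = -np.ones(model.n_states, dtype=np.int64)
    micro_to_macro[model.active_set] = crisp
    macro_dtrajs = [micro_to_macro[d] for d in model.dtrajs]
    C = count_transitions(macro_dtrajs, model.lag, n_macro)
    if (C.sum(axis=1) == 0).any():
        raise ValueError("a macrostate has no outgoing counts at the model lag")
    if model.reversible:
        Tm = _reversible_mle(C)
    else:
        Tm = C / C.sum(axis=1, keepdims=True)
    if labels is None:
        labels = [f"ML{a}" for a in range(n_macro)]
    return MacrostateModel(
        membership=chi,
        macro_of_micro=crisp,
        macro_lig=macro_lig_mean,
        transition_matrix=Tm,
        count_matrix=C,
        lag=model.lag,
        dt=model.dt,
        labels=list(labels),
    )


# ---------------------------------------------------------------------------
# first-passage times and rates


def mfpt(
    T: np.ndarray,
    source: int | Sequence[int],
    target: int | Sequence[int],
    lag_time: float = 1.0,
) -> float:
    """Mean first passage time from ``source`` to the ``target`` set.

    Solves the first-passage linear system (I - T_QQ) m_Q = lag_time * 1
    on the non-target states Q; ``lag_time`` carries the physical units
    (e.g. ps per step). Raises if the target is unreachable from the
    source.
    """
    n = T.shape[0]
    targets = np.atleast_1d(np.asarray(target, dtype=int))
    sources = np.atleast_1d(np.asarray(source, dtype=int))
    if np.intersect1d(targets, sources).size:
        return 0.0
    keep = np.setdiff1d(np.arange(n), targets)
    Q = T[np.ix_(keep, keep)]
    A = np.eye(keep.size) - Q
    try:
        m = np.linalg.solve(A, np.full(keep.size, float(lag_time)))
    except np.linalg.LinAlgError as e:
        raise ValueError("target is unreachable (absorbing complement)") from e
    if not np.all(np.isfinite(m)) or (m < -1e-9).any():
        raise ValueError("target is unreachable from part of the chain")
    pos = {int(s): i for i, s in enumerate(keep)}
    vals = [m[pos[int(s)]] for s in sources]
    return float(np.mean(vals))


def _generator_from_transition_matrix(T: np.ndarray, lag_time: float) -> np.ndarray:
    """Rate matrix Q = log(T)/tau, projected onto valid generators."""
    Q = scipy.linalg.logm(T) / lag_time
    Q = np.real(Q)
    np.fill_diagonal(Q, 0.0)
    Q = np.maximum(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def rates_from_msm(
    model: MacrostateModel,
    comp: SolutionComposition,
    equilibrium: EquilibriumResult,
    method: Literal["mfpt", "generator"] = "mfpt",
) -> RateEstimate:
    """Convert the coarse model into molar rate constants per binding step.

    ``method="mfpt"`` uses inverse mean first passage times between
    adjacent macrostates (exact for a single binding step);
    ``method="generator"`` uses the matrix logarithm of the coarse
    transition matrix and returns elementary per-step rates. Forward
    rates are scaled by gamma/n_lig_eq (= 1/[L]) into L mol^-1 s^-1;
    backward rates are reported as-is in s^-1. Steps with no observed
    transitions are flagged and reported as zero rates.
    """
    gamma = comp.gamma
    n_lig_eq = equilibrium.free_ligand * gamma
    if n_lig_eq <= 0:
        raise ValueError("equilibrium free-ligand count must be positive")
    n = model.n_macrostates
    lag_s = model.lag_time * 1e-12  # ps -> s
    nu_f = np.empty(n - 1)
    nu_b = np.empty(n - 1)
    flags: dict[int, str] = {}
    if method == "generator":
        Q = _generator_from_transition_matrix(model.transition_matrix, lag_s)
        for i in range(n - 1):
            nu_f[i] = Q[i, i + 1]
            nu_b[i] = Q[i + 1, i]
    elif method == "mfpt":
        for i in range(n - 1):
            tf = mfpt(model.transition_matrix, i, i + 1, lag_s)
            tb = mfpt(model.transition_matrix, i + 1, i, lag_s)
            nu_f[i] = 1.0 / tf if tf > 0 and np.isfinite(tf) else np.inf
            nu_b[i] = 1.0 / tb if tb > 0 and np.isfinite(tb) else np.inf
    else:
        raise ValueError(f"unknown method {method!r}")
    for i in range(n - 1):
        if model.count_matrix[i, i + 1] == 0:
            nu_f[i] = 0.0
            flags[i] = flags.get(i, "") + "no forward events observed;"
        if model.count_matrix[i + 1, i] == 0:
            nu_b[i] = 0.0
            flags[i] = flags.get(i, "") + "no backward events observed;"
    forward = nu_f * gamma / n_lig_eq
    backward = nu_b.copy()
    return RateEstimate(
        forward=forward, backward=backward, gamma=gamma, n_lig_eq=n_lig_eq, flags=flags
    )


def bayesian_rate_errors(
    count_matrix: np.ndarray,
    n_samples: int,
    seed: int,
    rate_func: Callable[[np.ndarray], np.ndarray],
    level: float = 0.95,
) -> dict:
    """Credible intervals by sampling the per-row Dirichlet posterior.

    Each posterior sample draws every row of the transition matrix from
    Dirichlet(counts_row) and maps it through ``rate_func`` (e.g. the
    MFPT-to-rate conversion); interval bounds are the matching
    percentiles. Rows need at least one count on every transition that
    the rates depend on.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    C = np.asarray(count_matrix, dtype=float)
    if (C.sum(axis=1) <= 0).any():
        raise ValueError("every state needs at least one outgoing count")
    rng = np.random.default_rng(seed)
    samples = []
    for _ in range(n_samples):
        T = np.vstack(
            [
                rng.dirichlet(np.where(row > 0, row, 1e-8))
                for row in C
            ]
        )
        # zero out transitions never observed, keeping rows stochastic
        T = np.where(C + C.T > 0, T, 0.0)
        T /= T.sum(axis=1, keepdims=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                samples.append(np.asarray(rate_func(T), dtype=float))
            except (ValueError, np.linalg.LinAlgError):
                continue
    if len(samples) < 2:
        raise ValueError("posterior sampling produced fewer than 2 valid samples")
    arr = np.array(samples)
    alpha = (1.0 - level) / 2.0
    return {
        "lower": np.nanpercentile(arr, 100 * alpha, axis=0),
        "upper": np.nanpercentile(arr, 100 * (1 - alpha), axis=0),
        "median": np.nanpercentile(arr, 50, axis=0),
        "n_valid": len(samples),
        "level": level,
        "seed": seed,
    }


def pk_from_rates(
    forward: Sequence[float] | RateEstimate, backward: Sequence[float] | None = None
) -> np.ndarray:
    """Kinetic stability constants pK_i = log10(k_i / k_-i)."""
    if isinstance(forward, RateEstimate):
        f, b = forward.forward, forward.backward
    else:
        if backward is None:
            raise ValueError("backward rates missing")
        f, b = np.asarray(forward, float), np.asarray(backward, float)
    if f.size != b.size:
        raise ValueError(f"unpaired rates: {f.size} forward vs {b.size} backward")
    if (f <= 0).any() or (b <= 0).any():
        raise ValueError("rates must be positive to form pK")
    return np.log10(f / b)
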