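"""Equilibrium thermodynamics of metal-ligand coordination species.

Turns free-energy information over the two coordination coordinates
(ligand donor atoms bound, first-shell waters) into species populations,
stepwise association constants K_i with Monte Carlo uncertainties,
chelate-effect metrics, enthalpy/entropy bookkeeping, and minimum
free-energy pathways across the 2D surface.

Model: species ML_i (i = 0..N ligands bound) at a fixed solution
composition. Populations follow Boltzmann weights of the species-level
free energies DeltaG_i (relative to the free metal, i = 0),

    n_i / n_j = exp(-(DeltaG_i - DeltaG_j) / k_B T),

normalized so that the total metal concentration is conserved. The free
ligand concentration follows from ligand mass conservation,
[L] = L0 - sum_i s_i [ML_i], and stepwise constants from

    K_i = [ML_i] / ([ML_{i-1}] [L]),      pK_i = log10 K_i.

The DeltaG_i are interpreted as box-equilibrium free energies at the
simulated composition (the convention of surfaces reweighted from
enhanced sampling at that composition), so no self-consistent iteration
over [L] is performed; mass conservation only back-computes [L].
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .constants import DEFAULT_TEMPERATURE, LN10, kt

Cell = tuple[int, int]

__all__ = [
    "FreeEnergySurface",
    "SpeciesLevels",
    "SolutionComposition",
    "EquilibriumResult",
    "ThermoRecord",
    "PkUncertainty",
    "MinimumEnergyPath",
    "project_surface_to_levels",
    "integer_basin_map",
    "solve_equilibrium",
    "pk_uncertainty_mc",
    "cumulative_beta",
    "chelate_metric",
    "thermo_decompose",
    "delta_delta_entropy",
    "enthalpy_from_ensembles",
    "min_free_energy_path",
]


@dataclass
class FreeEnergySurface:
    """Gridded free energy over (ligand coordination, water coordination).

    ``values[i, j]`` is the free energy (kJ/mol) at ``axis_lig[i]``,
    ``axis_wat[j]``; unvisited cells carry ``+inf``. Any constant offset
    is immaterial: derived pK values are offset-invariant.
    """

    values: np.ndarray
    axis_lig: np.ndarray
    axis_wat: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.axis_lig = np.asarray(self.axis_lig, dtype=float)
        self.axis_wat = np.asarray(self.axis_wat, dtype=float)
        if self.values.shape != (self.axis_lig.size, self.axis_wat.size):
            raise ValueError(
                f"grid shape {self.values.shape} does not match axes "
                f"({self.axis_lig.size}, {self.axis_wat.size})"
            )
        if np.isnan(self.values).any():
            raise ValueError("grid contains NaN; encode unvisited cells as inf")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def visited(self) -> np.ndarray:
        return np.isfinite(self.values)

    def shifted(self) -> "FreeEnergySurface":
        """Copy with the visited minimum shifted to zero."""
        vis = self.visited
        if not vis.any():
            raise ValueError("no visited cells on the surface")
        return FreeEnergySurface(
            self.values - self.values[vis].min(),
            self.axis_lig.copy(),
            self.axis_wat.copy(),
            self.temperature,
        )


@dataclass
class SpeciesLevels:
    """Species-resolved free energies relative to the free metal.

    ``delta_g[0]`` is zero by convention (free metal reference); ``sigma``
    holds one-standard-deviation level errors used by the Monte Carlo
    uncertainty analysis.
    """

    labels: list[str]
    delta_g: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.delta_g = np.asarray(self.delta_g, dtype=float)
        if self.sigma is None:
            self.sigma = np.zeros_like(self.delta_g)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if len(self.labels) != self.delta_g.size or self.sigma.size != self.delta_g.size:
            raise ValueError("labels, delta_g and sigma must have equal length")
        if (self.sigma < 0).any():
            raise ValueError("sigma must be non-negative")
        if abs(self.delta_g[0]) > 1e-12:
            raise ValueError("delta_g[0] (free metal) must be 0; shift the levels")

    @property
    def n_species(self) -> int:
        return self.delta_g.size


@dataclass
class SolutionComposition:
    """Total concentrations, stoichiometry and (optionally) the box.

    ``s[i]`` is the number of ligand molecules bound in species i
    (s[0] = 0 for the free metal). ``box_volume`` (liters) is only needed
    by the kinetic stage, where gamma = N_Av * V converts per-box counts
    to molar concentrations.
    """

    total_metal: float
    total_ligand: float
    s: Sequence[int]
    denticity: int = 1
    temperature: float = DEFAULT_TEMPERATURE
    box_volume: float | None = None

    def __post_init__(self) -> None:
        if self.total_metal <= 0:
            raise ValueError("total metal concentration must be positive")
        if self.total_ligand < 0:
            raise ValueError("total ligand concentration must be non-negative")
        self.s = tuple(int(x) for x in self.s)
        if any(x < 0 for x in self.s) or self.s[0] != 0:
            raise ValueError("stoichiometric coefficients must be non-negative with s[0] = 0")
        if self.denticity < 1:
            raise ValueError("denticity must be >= 1")

    @property
    def gamma(self) -> float:
        """N_Avogadro * V: particle count per unit molar concentration."""
        from .constants import N_AVOGADRO

        if self.box_volume is None:
            raise ValueError("box_volume is not set on this composition")
        return N_AVOGADRO * self.box_volume


@dataclass
class EquilibriumResult:
    """Solved coordination equilibrium.

    ``concentrations[i]`` is [ML_i] in mol/L (index 0 = free metal),
    ``stepwise_k[i-1]`` is K_i in L/mol, ``beta`` the cumulative products
    beta_i = K_1...K_i. ``pk_sigma`` is filled by the Monte Carlo error
    analysis when requested.
    """

    concentrations: np.ndarray
    free_ligand: float
    stepwise_k: np.ndarray
    beta: np.ndarray
    labels: list[str] = field(default_factory=list)
    pk_sigma: np.ndarray | None = None

    @property
    def free_metal(self) -> float:
        return float(self.concentrations[0])

    @property
    def pk(self) -> np.ndarray:
        return np.log10(self.stepwise_k)

    @property
    def pbeta(self) -> np.ndarray:
        return np.log10(self.beta)


@dataclass
class ThermoRecord:
    """One row of enthalpy/entropy bookkeeping for a complex species.

    -TdS = dG - dH; per-denticity columns are the raw ones divided by the
    number of bound donor groups n.
    """

    label: str
    n: int
    delta_g: float
    delta_h: float
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("denticity n must be >= 1")
        for v in (self.delta_g, self.delta_h):
            if not math.isfinite(v):
                raise ValueError("delta_g and delta_h must be finite")

    @property
    def minus_t_delta_s(self) -> float:
        return self.delta_g - self.delta_h

    @property
    def delta_h_per_n(self) -> float:
        return self.delta_h / self.n

    @property
    def minus_t_delta_s_per_n(self) -> float:
        return self.minus_t_delta_s / self.n


@dataclass
class PkUncertainty:
    """Monte Carlo spread of the stepwise pK values."""

    mean: np.ndarray
    std: np.ndarray
    rejection_fraction: float
    n_accepted: int
    seed: int


@dataclass
class MinimumEnergyPath:
    cells: list[Cell]
    barrier: float


# ---------------------------------------------------------------------------
# surface -> species levels


def integer_basin_map(
    fes: FreeEnergySurface,
    species: Mapping[str, tuple[float, float] | float],
) -> dict[str, list[Cell]]:
    """Default basin assignment: each species owns the visited cells whose
    rounded (ligand, water) coordinates match its coordination pair.

    ``species`` maps a label to either a (lig, wat) pair or a bare ligand
    coordination number (then any water coordination is accepted).
    """
    lig_round = np.round(fes.axis_lig).astype(int)
    wat_round = np.round(fes.axis_wat).astype(int)
    vis = fes.visited
    basins: dict[str, list[Cell]] = {}
    for label, target in species.items():
        if isinstance(target, tuple):
            t_lig, t_wat = int(round(target[0])), int(round(target[1]))
            mask = (lig_round[:, None] == t_lig) & (wat_round[None, :] == t_wat)
        else:
            mask = np.broadcast_to(
                (lig_round == int(round(target)))[:, None], fes.values.shape
            )
        cells = [tuple(map(int, c)) for c in np.argwhere(mask & vis)]
        basins[label] = cells
    return basins


def project_surface_to_levels(
    fes: FreeEnergySurface,
    basins: Mapping[str, Sequence[Cell]],
    mode: Literal["boltzmann", "minimum"] = "boltzmann",
    sigma: Mapping[str, float] | float | None = None,
) -> SpeciesLevels:
    """Aggregate basin cells into per-species free-energy levels.

    In ``boltzmann`` mode the basin free energy is the Boltzmann-integrated
    value -k_B T ln sum_cells exp(-F/k_B T); in ``minimum`` mode it is the
    basin minimum. Levels are shifted so the first species (free metal) is
    at zero; this removes any surface offset.
    """
    beta = 1.0 / kt(fes.temperature)
    labels = list(basins.keys())
    levels = np.empty(len(labels))
    for k, label in enumerate(labels):
        cells = list(basins[label])
        if not cells:
            raise ValueError(f"basin for species {label!r} is empty")
        vals = np.array([fes.values[c] for c in cells])
        finite = vals[np.isfinite(vals)]
        if finite.size == 0:
            raise ValueError(f"basin for species {label!r} contains only unvisited cells")
        if mode == "minimum":
            levels[k] = finite.min()
        elif mode == "boltzmann":
            # log-sum-exp, stable against deep basins
            m = finite.min()
            levels[k] = m - math.log(np.exp(-beta * (finite - m)).sum()) / beta
        else:
            raise ValueError(f"unknown mode {mode!r}")
    levels -= levels[0]
    if sigma is None:
        sig = None
    elif isinstance(sigma, Mapping):
        sig = np.array([sigma[lbl] for lbl in labels])
    else:
        sig = np.full(len(labels), float(sigma))
    return SpeciesLevels(labels, levels, sig)


# ---------------------------------------------------------------------------
# equilibrium solve


def solve_equilibrium(
    levels: SpeciesLevels, comp: SolutionComposition
) -> EquilibriumResult:
    """Populate species from Boltzmann weights and close the mass balance.

    Raises if the implied bound ligand exceeds the total ligand
    concentration (levels inconsistent with the composition).
    """
    if len(comp.s) != levels.n_species:
        raise ValueError(
            f"composition lists {len(comp.s)} species, levels {levels.n_species}"
        )
    beta_t = 1.0 / kt(comp.temperature)
    w = np.exp(-beta_t * (levels.delta_g - levels.delta_g.min()))
    conc = comp.total_metal * w / w.sum()
    s = np.asarray(comp.s, dtype=float)
    bound = float(s @ conc)
    free_ligand = comp.total_ligand - bound
    if free_ligand <= 0:
        raise ValueError(
            "mass conservation gives non-positive free ligand "
            f"(deficit {-free_ligand:.3e} mol/L): levels inconsistent with composition"
        )
    stepwise = conc[1:] / (conc[:-1] * free_ligand)
    return EquilibriumResult(
        concentrations=conc,
        free_ligand=free_ligand,
        stepwise_k=stepwise,
        beta=np.cumprod(stepwise),
        labels=list(levels.labels),
    )


def pk_uncertainty_mc(
    levels: SpeciesLevels,
    comp: SolutionComposition,
    n_samples: int = 2000,
    seed: int = 0,
    max_rejection_fraction: float = 0.5,
) -> PkUncertainty:
    """Monte Carlo propagation of level errors into the pK_i.

    Each draw samples DeltaG_i ~ Normal(DeltaG_i, sigma_i) independently
    (the free-metal reference stays pinned via its own sigma, normally 0)
    and re-solves the equilibrium. Draws whose mass balance yields
    [L] <= 0 are rejected and counted; a rejection fraction above
    ``max_rejection_fraction`` raises.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng(seed)
    draws = rng.normal(
        levels.delta_g, levels.sigma, size=(n_samples, levels.n_species)
    )
    draws[:, 0] = levels.delta_g[0] + rng.normal(0.0, levels.sigma[0], n_samples)
    pks = []
    rejected = 0
    for dg in draws:
        trial = SpeciesLevels(levels.labels, dg - dg[0], None)
        try:
            res = solve_equilibrium(trial, comp)
        except ValueError:
            rejected += 1
            continue
        pks.append(res.pk)
    frac = rejected / n_samples
    if frac > max_rejection_fraction:
        raise ValueError(
            f"{frac:.0%} of Monte Carlo draws violate the ligand balance; "
            "composition incompatible with the sampled levels"
        )
    arr = np.array(pks)
    return PkUncertainty(
        mean=arr.mean(axis=0),
        std=arr.std(axis=0, ddof=1),
        rejection_fraction=frac,
        n_accepted=arr.shape[0],
        seed=seed,
    )


def cumulative_beta(stepwise_k: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative formation constants beta_i = K_1...K_i and their logs."""
    k = np.asarray(stepwise_k, dtype=float)
    if (k <= 0).any() or not np.isfinite(k).all():
        raise ValueError("stepwise constants must be positive and finite")
    beta = np.cumprod(k)
    return beta, np.log10(beta)


def chelate_metric(
    pk_multi: float, pbeta_mono: float, pbeta_mono_lower: float | None = None
) -> float:
    """Schwarzenbach-style chelate-effect difference on the log scale.

    Two arguments give pK(multidentate) - pbeta(monodentate at equal
    donor count). The three-argument form compares a *second* chelate
    binding step against the matching monodentate window:
    pK_2(bi) - pbeta_4(mono) + pbeta_2(mono).
    """
    vals = [pk_multi, pbeta_mono] + ([] if pbeta_mono_lower is None else [pbeta_mono_lower])
    if not all(math.isfinite(v) for v in vals):
        raise ValueError("chelate_metric requires finite inputs")
    out = pk_multi - pbeta_mono
    if pbeta_mono_lower is not None:
        out += pbeta_mono_lower
    return out


def thermo_decompose(
    delta_g: float,
    delta_h: float,
    n: int,
    temperature: float = DEFAULT_TEMPERATURE,
    label: str = "",
) -> ThermoRecord:
    """Split a binding free energy into enthalpy and entropy columns."""
    return ThermoRecord(label, n, delta_g, delta_h, temperature)


def delta_delta_entropy(
    rec_a: ThermoRecord, rec_b: ThermoRecord, temperature: float | None = None
) -> float:
    """Entropy difference DeltaDeltaS between two records, J mol^-1 K^-1.

    Computed as [(-TdS)_A - (-TdS)_B] / T * 1000; positive when B binds
    with a smaller entropic penalty than A (e.g. a chelate vs the
    equivalent monodentate pair).
    """
    T = temperature if temperature is not None else rec_a.temperature
    return (rec_a.minus_t_delta_s - rec_b.minus_t_delta_s) / T * 1000.0


def enthalpy_from_ensembles(
    h_bound: float,
    h_unbound: float,
    se_bound: float | None = None,
    se_unbound: float | None = None,
) -> tuple[float, float | None]:
    """Binding enthalpy as the bound/unbound mean-energy difference.

    Standard errors, when given, propagate in quadrature.
    """
    if not (math.isfinite(h_bound) and math.isfinite(h_unbound)):
        raise ValueError("ensemble means must be finite")
    dh = h_bound - h_unbound
    if se_bound is None and se_unbound is None:
        return dh, None
    se = math.hypot(se_bound or 0.0, se_unbound or 0.0)
    return dh, se


# ---------------------------------------------------------------------------
# minimum free-energy path


def min_free_energy_path(
    fes: FreeEnergySurface, start: Cell, end: Cell
) -> MinimumEnergyPath:
    """Lowest-barrier (minimax) path between two grid cells.

    Over 4-connected moves through visited cells, returns the path that
    minimizes the maximum free energy encountered, together with that
    barrier value. Dijkstra with max-composition is exact for the minimax
    objective.
    """
    F = fes.values
    n_i, n_j = F.shape
    for name, (ci, cj) in (("start", start), ("end", end)):
        if not (0 <= ci < n_i and 0 <= cj < n_j):
            raise ValueError(f"{name} cell {ci, cj} outside the grid")
        if not np.isfinite(F[ci, cj]):
            raise ValueError(f"{name} cell {ci, cj} is unvisited")
    start = (int(start[0]), int(start[1]))
    end = (int(end[0]), int(end[1]))
    best = np.full(F.shape, np.inf)
    best[start] = F[start]
    prev: dict[Cell, Cell] = {}
    heap: list[tuple[float, Cell]] = [(F[start], start)]
    while heap:
        b, cell = heapq.heappop(heap)
        if b > best[cell]:
            continue
        if cell == end:
            break
        i, j = cell
        for ni, nj in ((i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)):
            if not (0 <= ni < n_i and 0 <= nj < n_j):
                continue
            f = F[ni, nj]
            if not np.isfinite(f):
                continue
            nb = max(b, f)
            if nb < best[ni, nj]:
                best[ni, nj] = nb
                prev[(ni, nj)] = cell
                heapq.heappush(heap, (nb, (ni, nj)))
    if not np.isfinite(best[end]):
        raise ValueError(f"no connected path of visited cells from {start} to {end}")
    path = [end]
    while path[-1] != start:
        path.append(prev[path[-1]])
    path.reverse()
    return MinimumEnergyPath(cells=path, barrier=float(best[end]))
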