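import numpy as np
import pytest

from chelkin import SolutionComposition, SpeciesLevels
from chelkin.constants import N_AVOGADRO


@pytest.fixture
def cd_en_levels() -> SpeciesLevels:
    """Bookkeeping-table free energies of the Cd(II)-ethylenediamine ladder."""
    return SpeciesLevels(
        ["ML0", "ML1", "ML2", "ML3"], [0.0, -29.3, -51.9, -62.7], [0.0, 2.0, 2.0, 2.0]
    )


@pytest.fixture
def cd_en_comp() -> SolutionComposition:
    """0.05 M metal, 0.15 M bidentate ligand (1:3)."""
    return SolutionComposition(0.05, 0.15, (0, 1, 2, 3), denticity=2)


@pytest.fixture
def small_box_comp() -> SolutionComposition:
    """Single metal ion, 30 ligands, gamma = 200 per molar."""
    gamma = 200.0
    return SolutionComposition(
        1.0 / gamma, 30.0 / gamma, (0, 1), box_volume=gamma / N_AVOGADRO
    )


def mass_action_oracle(stepwise_k: np.ndarray, m0: float, l0: float) -> tuple[np.ndarray, float]:
    """Independent root-find of the full mass-action system.

    Given stepwise constants K_i, solves for the free ligand [L] from
    ligand conservation with [ML_i] = [M] beta_i [L]^i and metal
    conservation, by bisection on a bracketed monotone residual.
    """
    from scipy.optimize import brentq

    beta = np.concatenate([[1.0], np.cumprod(stepwise_k)])
    i = np.arange(beta.size)

    def residual(free_l: float) -> float:
        poly = beta * free_l**i
        m = m0 / poly.sum()
        return free_l + m * (i * poly).sum() - l0

    lo, hi = 1e-300, l0
    free_l = brentq(residual, lo, hi, xtol=1e-300, rtol=1e-15)
    poly = beta * free_l**i
    m = m0 / poly.sum()
    return m * poly, free_l
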