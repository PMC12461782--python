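"""Reference parameter catalog for the Cd(II)/Ni(II) amine systems.

These numbers are the published working inputs of the analysis: the
enthalpy/entropy bookkeeping table for the Cd(II) complexes, the
open-ring/closed-ring association constants, the printed rate constants,
and the solution compositions (metal:donor-group ratio fixed at 1:6
across ligands). Values not published anywhere (e.g. most elementary
rate constants of the synthetic scenarios) are filled thermoconsistently
by the synthetic-data module and marked as such there.

Ligands: nme = methylamine (monodentate), en = ethylenediamine
(bidentate), dien = diethylenetriamine (tridentate), put = putrescine
(1,4-diaminobutane, bidentate).
"""

from __future__ import annotations

from .equilibrium import SolutionComposition

#: (label, denticity n = bound donor groups, DeltaG, DeltaH) in kJ/mol;
#: -T*DeltaS follows as DeltaG - DeltaH at 300 K.
THERMO_TABLE: list[tuple[str, int, float, float]] = [
    ("nme_1", 1, -14.2, -23.0),
    ("nme_2", 2, -26.8, -46.9),
    ("nme_3", 3, -32.6, -63.2),
    ("nme_4", 4, -33.1, -81.6),
    ("nme_6", 6, -15.9, -98.7),
    ("en_1", 2, -29.3, -43.5),
    ("en_2", 4, -51.9, -87.0),
    ("en_3", 6, -62.7, -119.2),
    ("dien_1", 3, -38.9, -53.4),
    ("dien_2", 6, -61.1, -100.4),
    ("put_1", 2, -18.0, -45.6),
    ("put_2", 4, -31.8, -89.1),
]

#: published -T*DeltaS column (kJ/mol), for cross-checking the identity
#: DeltaG = DeltaH + (-T*DeltaS) at table precision.
THERMO_TABLE_MINUS_TDS: dict[str, float] = {
    "nme_1": 8.8, "nme_2": 20.1, "nme_3": 30.5, "nme_4": 48.5, "nme_6": 82.8,
    "en_1": 14.2, "en_2": 35.1, "en_3": 56.4,
    "dien_1": 15.5, "dien_2": 39.3,
    "put_1": 27.6, "put_2": 57.3,
}

#: published per-denticity columns (DeltaH/n, -T*DeltaS/n) in kJ/mol.
THERMO_TABLE_PER_N: dict[str, tuple[float, float]] = {
    "nme_1": (-23.0, 8.8), "nme_2": (-23.5, 10.1), "nme_3": (-21.1, 10.2),
    "nme_4": (-20.4, 12.1), "nme_6": (-16.5, 13.8),
    "en_1": (-21.8, 7.1), "en_2": (-21.8, 8.8), "en_3": (-19.9, 9.4),
    "dien_1": (-17.8, 5.2), "dien_2": (-16.7, 6.6),
    "put_1": (-22.8, 13.8), "put_2": (-22.3, 14.3),
}

#: open-ring/closed-ring association constants (log10) per system:
#: (log K_or, log K_cr, log K_or*K_cr = pK_1).
RING_CONSTANTS: dict[str, tuple[float, float, float]] = {
    "cd-en": (0.6, 4.5, 5.1),
    "ni-en": (0.7, 6.4, 7.1),
    "cd-put": (1.9, 1.2, 3.1),
}

#: published elementary / overall rate constants (s^-1 unless noted).
PUBLISHED_RATES: dict[str, float] = {
    "ni-en k1 (L/mol/s)": 2.8e6,
    "ni-en k-1": 0.26,
    "ni-en k3 (L/mol/s)": 1.0e4,
    "ni-en k-3": 31.0,
    "cd-en k1 (L/mol/s)": 1.4e10,
    "cd-en k+cr": 6.8e9,
    "ni-en k+cr": 7.2e9,
    "ni-en k-cr": 2.9e3,
    "ni-en kd": 2.6e-1,
}

#: monodentate cumulative constant used in the chelate-effect metrics.
LOG_BETA2_NME = 4.5
#: published chelate-effect pK_1(en) - pbeta_2(nme).
CHELATE_EFFECT_EN_NME = 0.6

#: species-level free energies (kJ/mol) of the at-concentration surface,
#: relative to the free metal (figure convention, not the bookkeeping
#: table): ML1 and ML2 of Cd(II)-en.
FIG_LEVELS: dict[str, dict[str, float]] = {
    "cd-en": {"ML0": 0.0, "ML1": -17.2, "ML2": -30.5},
    "cd-put": {"ML0": 0.0, "ML2": -17.2},
    "cd-nme": {"ML0": 0.0, "ML4": -14.0},
}

#: level error of the free-energy surfaces, kJ/mol (one sigma).
LEVEL_SIGMA_KJ_MOL = 2.0


def composition(name: str, box_volume: float | None = None) -> SolutionComposition:
    """Solution composition of a named system (1:6 metal:donor groups)."""
    table = {
        # name: (M0, L0, denticity, n_binding_steps)
        "cd-en": (0.05, 0.15, 2, 3),
        "ni-en": (0.05, 0.15, 2, 3),
        "cd-nme": (0.05, 0.30, 1, 6),
        "cd-dien": (0.05, 0.10, 3, 2),
        "cd-put": (0.05, 0.15, 2, 2),
    }
    if name not in table:
        raise KeyError(f"unknown system {name!r}; known: {sorted(table)}")
    m0, l0, dent, n_steps = table[name]
    return SolutionComposition(
        total_metal=m0,
        total_ligand=l0,
        s=tuple(range(n_steps + 1)),
        denticity=dent,
        box_volume=box_volume,
    )
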