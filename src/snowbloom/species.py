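"""Canonical focal-species table.

Seventeen subalpine wildflower species are monitored across the two trails.
Four occur on both transects; Canby's licorice-root (LICA) was dropped as a
target after the 2015 season because of identification difficulty, so its
records end in 2015. Codes follow the genus(2) + epithet(2) convention
(e.g. CAPA = *Castilleja parviflora*).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class SpeciesInfo:
    """One focal species: code, names, trail membership, active years."""

    code: str
    botanical_name: str
    common_name: str
    trails: frozenset[str]  # subset of {"GB", "RL"}
    first_year: int = 2013
    last_year: int = 9999  # open-ended

    def active_in(self, year: int) -> bool:
        return self.first_year <= year <= self.last_year

    def on_trail(self, trail: str) -> bool:
        return trail in self.trails


GB = frozenset({"GB"})
RL = frozenset({"RL"})
BOTH = frozenset({"GB", "RL"})

#: Transect full names keyed by the two-letter prefix used in site codes.
TRANSECTS = {"GB": "Glacier Basin", "RL": "Reflection Lakes"}
TRANSECT_CODES = {v: k for k, v in TRANSECTS.items()}

SPECIES_TABLE: tuple[SpeciesInfo, ...] = (
    SpeciesInfo("ANAR", "Angelica arguta", "sharptooth angelica", GB),
    SpeciesInfo("ANOC", "Anemone occidentalis", "western anemone", RL),
    SpeciesInfo("ARLA", "Arnica latifolia", "broadleaf arnica", GB),
    SpeciesInfo("ASLE", "Aster ledophyllus", "cascade aster", GB),
    SpeciesInfo("CAMI", "Castilleja miniata", "scarlet paintbrush", GB),
    SpeciesInfo("CAPA", "Castilleja parviflora", "magenta paintbrush", RL),
    SpeciesInfo("ERGR", "Erythronium grandiflorum", "glacier lily", GB),
    SpeciesInfo("ERMO", "Erythronium montanum", "avalanche lily", RL),
    SpeciesInfo("ERPE", "Erigeron peregrinus", "mountain daisy", RL),
    SpeciesInfo("LICA", "Ligusticum canbyi", "Canby's licorice-root", RL, 2013, 2015),
    SpeciesInfo("LIGR", "Ligusticum grayi", "Gray's lovage", GB),
    SpeciesInfo("LUAR", "Lupinus arcticus", "subalpine lupine", BOTH),
    SpeciesInfo("MEPA", "Mertensia paniculata", "tall bluebell", GB),
    SpeciesInfo("MIAL", "Microseris alpestris", "northern microseris", RL),
    SpeciesInfo("PEBR", "Pedicularis bracteosa", "bracted lousewort", BOTH),
    SpeciesInfo("POBI", "Polygonum bistortoides", "American bistort", BOTH),
    SpeciesInfo("VASI", "Valeriana sitchensis", "sitka valerian", BOTH),
)

SPECIES_BY_CODE: dict[str, SpeciesInfo] = {s.code: s for s in SPECIES_TABLE}

PHENOPHASES = ("bud", "flower", "fruit", "disperse")


def species_for_trail(trail: str, year: int | None = None) -> list[SpeciesInfo]:
    """Focal species monitored on a trail ("GB" or "RL"), optionally in a year."""
    if trail not in TRANSECTS:
        raise ValueError(f"unknown trail {trail!r}; expected one of {sorted(TRANSECTS)}")
    out = [s for s in SPECIES_TABLE if s.on_trail(trail)]
    if year is not None:
        out = [s for s in out if s.active_in(year)]
    return out
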