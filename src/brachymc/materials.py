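"""Material compositions for the source hardware and phantom media.

The bundled library reproduces the published composition table for the
encapsulated Ir-192 source (pure-iridium core, AISI 316L capsule,
AISI 304 wire) and the slab-phantom media (tissues, PEEK, PMMA, water,
air, titanium alloy, stainless steel, vacuum).  See the data-file header
for the documented deviations (titanium balance, bone as printed,
rows renormalized to close to 100%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .constants import ATOMIC_NUMBERS

__all__ = ["Material", "material_library", "load_materials", "MATERIALS_FILE"]

MATERIALS_FILE = "materials.txt"

#: Materials treated as true voids by transport (no interactions).
VOID_MATERIALS = frozenset({"vacuum"})


@dataclass(frozen=True)
class Material:
    """An elemental mixture at a fixed mass density.

    Attributes
    ----------
    name
        Library label (lower case).
    fractions
        Element symbol -> mass fraction; non-negative, summing to 1
        within 1e-3 after load-time normalization.
    density
        Mass density in g/cm^3.
    """

    name: str
    fractions: dict[str, float] = field(hash=False)
    density: float

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError(f"{self.name}: density must be positive")
        total = sum(self.fractions.values())
        if not 0.999 <= total <= 1.001:
            raise ValueError(f"{self.name}: mass fractions sum to {total:.6f}")
        for el, w in self.fractions.items():
            if w < 0:
                raise ValueError(f"{self.name}: negative fraction for {el}")
            if el not in ATOMIC_NUMBERS:
                raise ValueError(f"{self.name}: unknown element {el!r}")

    @property
    def is_void(self) -> bool:
        return self.name in VOID_MATERIALS


def _parse_line(line: str, lineno: int) -> Material:
    try:
        name, density, comp = (part.strip() for part in line.split(";"))
        fracs = {}
        for token in comp.split():
            el, pct = token.split(":")
            fracs[el] = float(pct) / 100.0
        total = sum(fracs.values())
        fracs = {el: w / total for el, w in fracs.items()}
        return Material(name=name.lower(), fractions=fracs, density=float(density))
    except ValueError:
        raise
    except Exception as exc:  # malformed structure
        raise ValueError(f"materials file line {lineno}: cannot parse {line!r}") from exc


def load_materials(path: str | Path | None = None) -> dict[str, Material]:
    """Load a materials file (``name ; density ; El:pct ...`` per line).

    With no argument, loads the bundled library.
    """
    if path is None:
        text = resources.files("brachymc.data").joinpath(MATERIALS_FILE).read_text()
    else:
        text = Path(path).read_text()
    materials: dict[str, Material] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        mat = _parse_line(line, lineno)
        materials[mat.name] = mat
    return materials


def material_library() -> dict[str, Material]:
    """The bundled material library (published source + phantom media)."""
    return load_materials(None)
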