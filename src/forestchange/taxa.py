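"""Taxon groups and name binning.

Colonial surveyors and modern inventory crews name trees at different
resolutions (colloquial genus names vs. Latin binomials), so both eras are
collapsed onto a shared set of 24 broad taxon groups before any comparison.
Unknown names are flagged ``UNBINNED`` rather than silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

#: Sentinel code for names that resolve to no group.
UNBINNED = "UNBINNED"

#: The 24 taxon groups shared by both eras, in canonical order.
DEFAULT_CODES: tuple[str, ...] = (
    "ASHES", "BASSWOOD", "BEECH", "BIRCHES", "BLACKGUM", "CEDAR",
    "CHERRIES", "CHESTNUT", "CYPRESS", "ELMS", "FIR", "HEMLOCK",
    "HICKORIES", "HORNBEAM", "MAGNOLIAS", "MAPLE", "OAK", "PINES",
    "POPLARS", "SPRUCES", "SYCAMORE", "TAMARACK", "TULIP", "WALNUTS",
)

# Raw name -> group code. Keys are matched case- and whitespace-insensitively.
# Covers the genera behind each group plus the colloquial names colonial
# surveyors used; extend via TaxonSet(name_map={...}).
_DEFAULT_NAME_MAP: dict[str, str] = {
    # Latin genus / binomial names
    "fraxinus": "ASHES", "fraxinus americana": "ASHES",
    "fraxinus nigra": "ASHES", "fraxinus pennsylvanica": "ASHES",
    "tilia": "BASSWOOD", "tilia americana": "BASSWOOD",
    "fagus": "BEECH", "fagus grandifolia": "BEECH",
    "betula": "BIRCHES", "betula alleghaniensis": "BIRCHES",
    "betula lenta": "BIRCHES", "betula papyrifera": "BIRCHES",
    "betula populifolia": "BIRCHES", "betula nigra": "BIRCHES",
    "nyssa": "BLACKGUM", "nyssa sylvatica": "BLACKGUM",
    "thuja": "CEDAR", "thuja occidentalis": "CEDAR",
    "juniperus virginiana": "CEDAR", "chamaecyparis thyoides": "CEDAR",
    "prunus": "CHERRIES", "prunus serotina": "CHERRIES",
    "prunus pensylvanica": "CHERRIES", "prunus virginiana": "CHERRIES",
    "castanea": "CHESTNUT", "castanea dentata": "CHESTNUT",
    "taxodium": "CYPRESS", "taxodium distichum": "CYPRESS",
    "ulmus": "ELMS", "ulmus americana": "ELMS", "ulmus rubra": "ELMS",
    "abies": "FIR", "abies balsamea": "FIR",
    "tsuga": "HEMLOCK", "tsuga canadensis": "HEMLOCK",
    "carya": "HICKORIES", "carya ovata": "HICKORIES",
    "carya glabra": "HICKORIES", "carya cordiformis": "HICKORIES",
    "carpinus": "HORNBEAM", "carpinus caroliniana": "HORNBEAM",
    "ostrya": "HORNBEAM", "ostrya virginiana": "HORNBEAM",
    "magnolia": "MAGNOLIAS", "magnolia acuminata": "MAGNOLIAS",
    "liriodendron": "TULIP", "liriodendron tulipifera": "TULIP",
    "acer": "MAPLE", "acer rubrum": "MAPLE", "acer saccharum": "MAPLE",
    "acer saccharinum": "MAPLE", "acer pensylvanicum": "MAPLE",
    "quercus": "OAK", "quercus alba": "OAK", "quercus rubra": "OAK",
    "quercus velutina": "OAK", "quercus prinus": "OAK",
    "quercus coccinea": "OAK", "quercus palustris": "OAK",
    "pinus": "PINES", "pinus strobus": "PINES", "pinus resinosa": "PINES",
    "pinus rigida": "PINES", "pinus banksiana": "PINES",
    "populus": "POPLARS", "populus tremuloides": "POPLARS",
    "populus grandidentata": "POPLARS", "populus deltoides": "POPLARS",
    "picea": "SPRUCES", "picea rubens": "SPRUCES", "picea mariana": "SPRUCES",
    "picea glauca": "SPRUCES",
    "platanus": "SYCAMORE", "platanus occidentalis": "SYCAMORE",
    "larix": "TAMARACK", "larix laricina": "TAMARACK",
    "juglans": "WALNUTS", "juglans nigra": "WALNUTS",
    "juglans cinerea": "WALNUTS",
    # Colloquial names as surveyors wrote them
    "ash": "ASHES", "white ash": "ASHES", "black ash": "ASHES",
    "basswood": "BASSWOOD", "linden": "BASSWOOD", "lime": "BASSWOOD",
    "beech": "BEECH",
    "birch": "BIRCHES", "white birch": "BIRCHES", "black birch": "BIRCHES",
    "yellow birch": "BIRCHES", "gray birch": "BIRCHES",
    "blackgum": "BLACKGUM", "black gum": "BLACKGUM", "tupelo": "BLACKGUM",
    "gum": "BLACKGUM",
    "cedar": "CEDAR", "white cedar": "CEDAR", "red cedar": "CEDAR",
    "cherry": "CHERRIES", "black cherry": "CHERRIES",
    "pin cherry": "CHERRIES", "wild cherry": "CHERRIES",
    "chestnut": "CHESTNUT",
    "cypress": "CYPRESS", "bald cypress": "CYPRESS",
    "elm": "ELMS", "white elm": "ELMS", "slippery elm": "ELMS",
    "fir": "FIR", "balsam": "FIR", "balsam fir": "FIR",
    "hemlock": "HEMLOCK",
    "hickory": "HICKORIES", "shagbark hickory": "HICKORIES",
    "walnut hickory": "HICKORIES", "pignut": "HICKORIES",
    "hornbeam": "HORNBEAM", "ironwood": "HORNBEAM",
    "hop hornbeam": "HORNBEAM", "hop-hornbeam": "HORNBEAM",
    "magnolia": "MAGNOLIAS", "cucumber tree": "MAGNOLIAS",
    "maple": "MAPLE", "red maple": "MAPLE", "sugar maple": "MAPLE",
    "rock maple": "MAPLE", "white maple": "MAPLE", "swamp maple": "MAPLE",
    "oak": "OAK", "white oak": "OAK", "black oak": "OAK", "red oak": "OAK",
    "chestnut oak": "OAK", "scarlet oak": "OAK", "scrub oak": "OAK",
    "pine": "PINES", "white pine": "PINES", "pitch pine": "PINES",
    "red pine": "PINES", "yellow pine": "PINES", "norway pine": "PINES",
    "poplar": "POPLARS", "aspen": "POPLARS", "popple": "POPLARS",
    "quaking aspen": "POPLARS", "bigtooth aspen": "POPLARS",
    "spruce": "SPRUCES", "red spruce": "SPRUCES", "black spruce": "SPRUCES",
    "white spruce": "SPRUCES",
    "sycamore": "SYCAMORE", "buttonwood": "SYCAMORE",
    "tamarack": "TAMARACK", "larch": "TAMARACK", "hackmatack": "TAMARACK",
    "tulip": "TULIP", "tulip tree": "TULIP", "tulip poplar": "TULIP",
    "yellow poplar": "TULIP", "whitewood": "TULIP",
    "walnut": "WALNUTS", "black walnut": "WALNUTS", "butternut": "WALNUTS",
}


def _norm(name: str) -> str:
    return " ".join(name.strip().lower().split())


@dataclass(frozen=True)
class TaxonSet:
    """Ordered taxon group codes plus a raw-name lookup.

    Parameters
    ----------
    codes:
        Unique group identifiers in a fixed order; this order defines the
        column order of every composition matrix downstream.
    name_map:
        Extra ``raw name -> code`` entries layered over the built-in map.
    """

    codes: tuple[str, ...] = DEFAULT_CODES
    name_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.codes)) != len(self.codes):
            raise ValueError("taxon codes must be unique")
        merged = dict(_DEFAULT_NAME_MAP)
        merged.update({_norm(k): v for k, v in self.name_map.items()})
        bad = {k: v for k, v in merged.items() if v not in self.codes}
        if bad:
            raise ValueError(f"name_map targets unknown codes: {sorted(set(bad.values()))}")
        object.__setattr__(self, "_lookup", merged)

    def __len__(self) -> int:
        return len(self.codes)

    def index(self, code: str) -> int:
        return self.codes.index(code)

    def bin_name(self, raw_name: str) -> str:
        """Resolve a raw tree name to its group code, or :data:`UNBINNED`."""
        return self._lookup.get(_norm(raw_name), UNBINNED)


def bin_taxon(raw_name: str, taxon_set: TaxonSet) -> str:
    """Resolve ``raw_name`` to a taxon group code.

    Matching is case- and whitespace-insensitive. Names absent from the
    mapping return :data:`UNBINNED`; callers exclude such records downstream
    and log the count, they are never dropped silently here.
    """
    code = taxon_set.bin_name(raw_name)
    if code == UNBINNED:
        logger.debug("unbinned taxon name: %r", raw_name)
    return code
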