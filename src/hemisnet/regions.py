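"""Canonical cortical parcellation used throughout the package.

The Desikan-Killiany atlas defines 34 cortical regions per hemisphere.
Homotopic (left/right) regions share the same base name; every array in
this package that is indexed by region uses the fixed ordering below, so
left index ``i`` and right index ``i`` always denote the homotopic pair.
"""

from __future__ import annotations

#: Desikan-Killiany base names (FreeSurfer ``aparc`` order), 34 regions.
DK_REGIONS: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
)

N_REGIONS: int = len(DK_REGIONS)
#: Unordered node pairs in one 34-node hemispheric network.
N_EDGES: int = N_REGIONS * (N_REGIONS - 1) // 2

HEMISPHERES: tuple[str, str] = ("L", "R")


def region_column(region: str, hemisphere: str) -> str:
    """Column name for one region in one hemisphere, e.g. ``fusiform_L``."""
    if hemisphere not in HEMISPHERES:
        raise ValueError(f"hemisphere must be 'L' or 'R', got {hemisphere!r}")
    return f"{region}_{hemisphere}"


def hemisphere_columns(hemisphere: str) -> list[str]:
    """All 34 region columns of one hemisphere, in canonical order."""
    return [region_column(r, hemisphere) for r in DK_REGIONS]


def all_region_columns() -> list[str]:
    """The 68 thickness columns: 34 left then 34 right, canonical order."""
    return hemisphere_columns("L") + hemisphere_columns("R")


def region_index(region: str) -> int:
    """Canonical index of a region base name.

    Raises ``KeyError`` for unknown names, listing the valid ones.
    """
    try:
        return DK_REGIONS.index(region)
    except ValueError:
        raise KeyError(
            f"unknown region {region!r}; valid names are the 34 "
            "Desikan-Killiany base names (see hemisnet.regions.DK_REGIONS)"
        ) from None
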