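"""Class taxonomies and clinical category vocabularies.

The per-cell classifier emits one confidence value per morphological class
("CMD" values, by analogy with flow-cytometry CD markers).  Two taxonomies
are supported: the original 10-class set and the revised 11-class set that
adds navicular cells (glycogen-rich benign squamous cells that can mimic
LSIL morphology).
"""

from __future__ import annotations

# Morphological classes, grouped by their role in the gating hierarchy.
IRRELEVANT = "irrelevant"
LEUKOCYTE = "leukocyte"
LSIL = "lsil"
HSIL = "hsil"
ADENOCARCINOMA = "adenocarcinoma"

LESION_CLASSES: tuple[str, ...] = (LSIL, HSIL, ADENOCARCINOMA)

#: Severity order used to break exact CMD ties between crossed lesion gates
#: (most severe first).
LESION_SEVERITY: tuple[str, ...] = (ADENOCARCINOMA, HSIL, LSIL)

SUPERFICIAL = "superficial_intermediate"
PARABASAL = "parabasal"
METAPLASTIC = "metaplastic"
GLANDULAR = "glandular"
MISCELLANEOUS = "miscellaneous"
NAVICULAR = "navicular"

#: Normal (fallback) classes of the original 10-class model.
FALLBACK_10: tuple[str, ...] = (
    SUPERFICIAL,
    PARABASAL,
    METAPLASTIC,
    GLANDULAR,
    MISCELLANEOUS,
)

#: Normal (fallback) classes of the revised 11-class model: navicular cells
#: are a benign class and therefore live in the fallback group.
FALLBACK_11: tuple[str, ...] = FALLBACK_10 + (NAVICULAR,)

TAXONOMY_10: tuple[str, ...] = (
    (LEUKOCYTE,) + FALLBACK_10 + LESION_CLASSES + (IRRELEVANT,)
)
TAXONOMY_11: tuple[str, ...] = (
    (LEUKOCYTE,) + FALLBACK_11 + LESION_CLASSES + (IRRELEVANT,)
)

#: Bethesda reporting categories, in increasing severity order.
BETHESDA_CATEGORIES: tuple[str, ...] = (
    "NILM",
    "ASC-US",
    "LSIL",
    "ASC-H",
    "HSIL",
    "SCC",
)

HPV_LEVELS: tuple[str, ...] = ("negative", "positive", "missing")
PREP_METHODS: tuple[str, ...] = ("SurePath", "ThinPrep")


def fallback_classes(taxonomy: tuple[str, ...] | list[str]) -> tuple[str, ...]:
    """Return the normal (fallback) classes of a taxonomy in canonical order."""
    special = {IRRELEVANT, LEUKOCYTE, *LESION_CLASSES}
    return tuple(c for c in taxonomy if c not in special)


def validate_taxonomy(taxonomy: tuple[str, ...] | list[str]) -> None:
    """Check the structural requirements every taxonomy must satisfy."""
    if len(set(taxonomy)) != len(taxonomy):
        raise ValueError("taxonomy contains duplicate class names")
    for required in (IRRELEVANT, LEUKOCYTE):
        if required not in taxonomy:
            raise ValueError(f"taxonomy must contain the {required!r} class")
    if not any(c in taxonomy for c in LESION_CLASSES):
        raise ValueError("taxonomy must contain at least one lesion class")
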