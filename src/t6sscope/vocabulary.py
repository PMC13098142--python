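"""Controlled vocabulary for type VI secretion system (T6SS) components.

The canonical T6SS comprises 14 structural components organised into six
functional subcomplexes: the ClpV ATPase (TssH), the spike-and-tube module
(PAAR/EvpJ, VgrG/TssI, Hcp/TssD), the membrane complex (TssJ, TssL, TssM),
the baseplate (TssE, TssF, TssG, TssK), the contractile sheath (TssB, TssC)
and TssA.  Annotation tables may use either the systematic ``tss`` names or
the common protein names (hcp, vgrG, clpV, paar); labels are normalised here.
"""

from __future__ import annotations

CANONICAL_COMPONENTS: tuple[str, ...] = (
    "tssA", "tssB", "tssC", "tssD", "tssE", "tssF", "tssG",
    "tssH", "tssI", "tssJ", "tssK", "tssL", "tssM", "evpJ",
)

#: Common-name synonyms mapped to systematic component names.
SYNONYMS: dict[str, str] = {
    "hcp": "tssD",
    "vgrg": "tssI",
    "clpv": "tssH",
    "paar": "evpJ",
    "evpj": "evpJ",
}
SYNONYMS.update({c.lower(): c for c in CANONICAL_COMPONENTS})

SUBCOMPLEXES: dict[str, frozenset[str]] = {
    "ATPase": frozenset({"tssH"}),
    "spike_and_tube": frozenset({"evpJ", "tssI", "tssD"}),
    "membrane": frozenset({"tssJ", "tssL", "tssM"}),
    "baseplate": frozenset({"tssE", "tssF", "tssG", "tssK"}),
    "sheath": frozenset({"tssB", "tssC"}),
    "tssA": frozenset({"tssA"}),
}

#: Components whose isolated copies are inventoried (inner tube and spike tip).
TUBE_SPIKE_COMPONENTS: frozenset[str] = frozenset({"tssD", "tssI"})

#: Display names used for orphan-island typing.
ISLAND_DISPLAY: dict[str, str] = {"tssD": "hcp", "tssI": "vgrG", "evpJ": "PAAR"}

#: Distinct-component sets that qualify a sub-complete cluster as an orphan island.
ORPHAN_COMBINATIONS: tuple[frozenset[str], ...] = (
    frozenset({"tssD", "tssI"}),
    frozenset({"tssD", "evpJ"}),
    frozenset({"tssI", "evpJ"}),
    frozenset({"tssD", "tssI", "evpJ"}),
)


def normalize_component(label: str) -> str | None:
    """Map an annotation label to its canonical component name.

    Returns ``None`` for labels outside the T6SS vocabulary; callers decide
    whether that is an error or simply a non-T6SS gene.
    """
    key = label.strip().lower()
    # strip common prefixes like "t6ss_tssB" emitted by profile searches
    if key.startswith("t6ss_"):
        key = key[5:]
    return SYNONYMS.get(key)


def island_type_for(components: frozenset[str]) -> str:
    """Name an orphan-island by its tube/spike composition (e.g. ``hcp-vgrG``)."""
    order = ("tssD", "tssI", "evpJ")
    parts = [ISLAND_DISPLAY[c] for c in order if c in components]
    return "-".join(parts) if parts else "none"


def subcomplex_presence(components: frozenset[str]) -> dict[str, bool]:
    """Flag which of the six structural subcomplexes a cluster touches."""
    return {name: bool(members & components) for name, members in SUBCOMPLEXES.items()}
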