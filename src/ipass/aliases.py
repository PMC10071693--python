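"""Gene symbol canonicalisation.

Immunology literature freely mixes protein names (GITR, B7-H3, CD141,
DC-LAMP) with HGNC gene symbols (TNFRSF18, CD276, THBD, LAMP3).  Everything
downstream of input parsing works on canonical HGNC symbols, so the readers
apply a :class:`GeneAliasMap` up front.  A small default table covering the
protein-name usages common in tumour-immunology panels ships with the
package; users can extend or replace it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError

#: Protein-name / legacy aliases mapped to canonical HGNC symbols.
DEFAULT_ALIASES: dict[str, str] = {
    "GITR": "TNFRSF18",
    "CD141": "THBD",
    "BDCA-3": "THBD",
    "BDCA3": "THBD",
    "B7-H3": "CD276",
    "B7H3": "CD276",
    "C1INH": "SERPING1",
    "C1-INH": "SERPING1",
    "FRP2": "FPR2",
    "DC-LAMP": "LAMP3",
    "DCLAMP": "LAMP3",
    "CTLA-4": "CTLA4",
    "NFKB-1": "NFKB1",
    "NFkb1": "NFKB1",
    "PD-L1": "CD274",
    "PDL1": "CD274",
    "PD-L2": "PDCD1LG2",
    "CD137": "TNFRSF9",
    "4-1BB": "TNFRSF9",
    "TIM3": "HAVCR2",
    "TIM-3": "HAVCR2",
}


@dataclass(frozen=True)
class GeneAliasMap:
    """Mapping from alias symbols to canonical symbols.

    The mapping is resolved transitively at construction so that lookup is
    idempotent: ``canonical(canonical(x)) == canonical(x)``.  Cycles
    (``A -> B -> A``) are rejected.
    """

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        resolved: dict[str, str] = {}
        for alias in self.mapping:
            seen = [alias]
            target = self.mapping[alias]
            while target in self.mapping and self.mapping[target] != target:
                if target in seen:
                    raise ValidationError(f"alias cycle involving {target!r}")
                seen.append(target)
                target = self.mapping[target]
            resolved[alias] = target
        object.__setattr__(self, "mapping", resolved)

    def canonical(self, symbol: str) -> str:
        return self.mapping.get(symbol, symbol)

    def canonicalise(self, symbols: list[str]) -> list[str]:
        """Canonicalise a list of symbols, preserving order (duplicates allowed)."""
        return [self.canonical(s) for s in symbols]


def default_alias_map() -> GeneAliasMap:
    """The alias table shipped with the package."""
    return GeneAliasMap(dict(DEFAULT_ALIASES))
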