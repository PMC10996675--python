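"""Lipid shorthand nomenclature: parsing, class sets, chain-length profiles.

The parser accepts the compact shorthand used by common lipidomics searches:
a class token (optionally with a bracket qualifier, e.g. ``Cer[NS]``),
whitespace, then either a sum composition (``PC 34:1``) or an underscore- or
slash-separated chain list (``PC 16:0_18:1``). ``O-``/``P-`` prefixes mark
plasmanyl/plasmenyl ether lipids; ``d``/``t`` prefixes mark sphingoid
di-/tri-hydroxy bases. sn-position is not modelled: ``/`` and ``_`` are
treated identically.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import AnnotationSets, DifferentialMatrix, ParseError

__all__ = [
    "LipidDescriptor",
    "parse_lipid_name",
    "lipid_class_sets",
    "chain_length_profile",
    "format_descriptor",
]

# class token: letters/digits, optional [qualifier]; must start with a letter
_CLASS_RE = re.compile(r"^(?P<cls>[A-Za-z][A-Za-z0-9\-]*(?:\[[^\]]+\])?)\s+(?P<rest>\S.*)$")
# one chain: optional O-/P- ether prefix, optional d/t sphingoid prefix,
# carbons:double-bonds, optional ;qualifier suffix (preserved, not interpreted)
_CHAIN_RE = re.compile(
    r"^(?:(?P<ether>[OP])-)?(?P<sph>[dt])?(?P<c>\d+):(?P<d>\d+)(?P<suffix>;[^\s_/]*)?$"
)

_ETHER_NAME = {"O": "plasmanyl", "P": "plasmenyl"}
#: classes for which an ether prefix is structurally meaningful
_GLYCERO_CLASSES = {
    "PC", "PE", "PS", "PI", "PG", "PA", "LPC", "LPE", "LPS", "LPI", "LPG",
    "DG", "TG", "MG",
}


@dataclass(frozen=True)
class LipidDescriptor:
    """Structured view of one lipid shorthand name."""

    raw_name: str
    lipid_class: str
    total_carbons: int
    total_double_bonds: int
    ether_type: str = "none"       # none | plasmanyl | plasmenyl
    sphingoid_hydroxyls: str = "none"  # none | d | t
    resolution: str = "species"    # species (sum composition) | molecular

    def __post_init__(self) -> None:
        if self.total_carbons <= 0:
            raise ParseError(f"{self.raw_name!r}: total carbons must be positive")
        if self.total_double_bonds < 0:
            raise ParseError(f"{self.raw_name!r}: negative double-bond count")


def parse_lipid_name(name: str) -> LipidDescriptor:
    """Parse one shorthand lipid name into a :class:`LipidDescriptor`.

    Raises :class:`~crossome.io.ParseError` for names outside the grammar;
    callers doing bulk classification may catch it and bin the name as
    unclassified.
    """
    if not name or not name.strip():
        raise ParseError("empty lipid name")
    m = _CLASS_RE.match(name.strip())
    if m is None:
        raise ParseError(f"unrecognized lipid name {name!r}")
    cls, rest = m.group("cls"), m.group("rest")
    chains = re.split(r"[_/]", rest)
    carbons = dbs = 0
    ether = "none"
    sph = "none"
    for chain in chains:
        cm = _CHAIN_RE.match(chain)
        if cm is None:
            raise ParseError(f"unrecognized chain token {chain!r} in {name!r}")
        carbons += int(cm.group("c"))
        dbs += int(cm.group("d"))
        if cm.group("ether"):
            ether = _ETHER_NAME[cm.group("ether")]
        if cm.group("sph"):
            sph = cm.group("sph")
    if ether != "none" and cls.split("[")[0] not in _GLYCERO_CLASSES:
        raise ParseError(
            f"{name!r}: ether prefix on non-glycerolipid class {cls!r}"
        )
    resolution = "molecular" if len(chains) > 1 else "species"
    return LipidDescriptor(
        raw_name=name.strip(),
        lipid_class=cls,
        total_carbons=carbons,
        total_double_bonds=dbs,
        ether_type=ether,
        sphingoid_hydroxyls=sph,
        resolution=resolution,
    )


def format_descriptor(d: LipidDescriptor) -> str:
    """Canonical sum-composition rendering of a descriptor (re-parseable)."""
    prefix = {"plasmanyl": "O-", "plasmenyl": "P-"}.get(d.ether_type, "")
    sph = d.sphingoid_hydroxyls if d.sphingoid_hydroxyls != "none" else ""
    return f"{d.lipid_class} {prefix}{sph}{d.total_carbons}:{d.total_double_bonds}"


def lipid_class_sets(names: Iterable[str]) -> AnnotationSets:
    """Group lipid names by parsed class into one annotation term per class.

    Unparseable names are collected in an ``unclassified`` term rather than
    raised, so the function is safe on mixed-vendor exports.
    """
    groups: dict[str, list[str]] = {}
    for name in names:
        try:
            cls = parse_lipid_name(name).lipid_class
        except ParseError:
            cls = "unclassified"
        groups.setdefault(cls, []).append(name)
    if not groups:
        return AnnotationSets("lipid")
    desc = {c: ("unparseable lipid names" if c == "unclassified" else f"lipid class {c}")
            for c in groups}
    return AnnotationSets.from_dict("lipid", groups, desc)


def chain_length_profile(
    descriptors: Sequence[LipidDescriptor],
    diff: DifferentialMatrix,
    lipid_class: str,
    genotype: str,
    carbon_cutoff: int = 20,
) -> dict:
    """Mean log2FC of one lipid class split at a chain-length cutoff.

    Members of ``lipid_class`` are partitioned by ``total_carbons <
    carbon_cutoff`` versus ``>= carbon_cutoff``; each group's mean log2FC in
    ``genotype`` (missing cells excluded) and member count is returned. An
    empty group's mean is NaN.
    """
    if carbon_cutoff <= 0:
        raise ValueError("carbon_cutoff must be positive")
    members = [d for d in descriptors if d.lipid_class == lipid_class]
    if not members:
        raise ValueError(f"no descriptors with class {lipid_class!r}")
    if genotype not in diff.log2fc.columns:
        raise ValueError(f"genotype {genotype!r} not in differential matrix")
    col = diff.log2fc[genotype]
    below = [d.raw_name for d in members if d.total_carbons < carbon_cutoff]
    above = [d.raw_name for d in members if d.total_carbons >= carbon_cutoff]

    def _mean(ids: list[str]) -> float:
        vals = col.reindex(ids).dropna()
        return float(vals.mean()) if len(vals) else float("nan")

    return {
        "lipid_class": lipid_class,
        "genotype": genotype,
        "carbon_cutoff": int(carbon_cutoff),
        "mean_log2fc_below": _mean(below),
        "mean_log2fc_at_or_above": _mean(above),
        "n_below": len(below),
        "n_at_or_above": len(above),
    }
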