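"""Genetic grouping hypotheses for a two-parent reciprocal-hybrid design.

The experimental material is four lines: two selfed parents with contrasting
seed sizes and their two reciprocal F1 hybrids (identical nuclear genotype,
different maternal parent).  Five hypotheses about which lines share growth
parameters are encoded as partitions of the four lines into levels:

=======  ======  =====================================================
name     levels  partition
=======  ======  =====================================================
GEN4     4       every line its own level
GEN3     3       each parent its own level; the two F1s share one
MAPHE    2       by maternal seed-size class (large vs small)
MAHY     3       parents share one level; each F1 its own
UNI      1       all lines identical
=======  ======  =====================================================

A model fitted under a scheme estimates one set of curve parameters per
level, so the schemes translate directly into degrees-of-freedom budgets
for information-criterion comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .curves import family_info

__all__ = [
    "LineDefinition",
    "GroupingScheme",
    "SCHEME_NAMES",
    "default_lines",
    "make_scheme",
    "all_schemes",
    "param_count",
    "is_coarsening",
]

SCHEME_NAMES = ("GEN4", "GEN3", "MAPHE", "MAHY", "UNI")


@dataclass(frozen=True)
class LineDefinition:
    """One of the four lines: a selfed parent or a reciprocal F1."""

    line_id: str
    maternal_parent: str
    paternal_parent: str
    seed_size_class: str  # "large" | "small"

    def __post_init__(self):
        if self.seed_size_class not in ("large", "small"):
            raise ValueError("seed_size_class must be 'large' or 'small'")

    @property
    def is_selfed(self) -> bool:
        return self.maternal_parent == self.paternal_parent


@dataclass(frozen=True)
class GroupingScheme:
    """A named partition of the lines into parameter levels."""

    name: str
    level_of: Mapping[str, str]

    @property
    def levels(self) -> tuple:
        return tuple(sorted(set(self.level_of.values())))

    @property
    def n_levels(self) -> int:
        return len(set(self.level_of.values()))

    def lines_in(self, level: str) -> frozenset:
        return frozenset(l for l, v in self.level_of.items() if v == level)


def default_lines() -> list[LineDefinition]:
    """The study pedigree: Andean landrace G19833 (large-seeded), wild
    accession G23419 (small-seeded) and their reciprocal F1s (maternal
    parent written first)."""
    return [
        LineDefinition("G19833", "G19833", "G19833", "large"),
        LineDefinition("G23419", "G23419", "G23419", "small"),
        LineDefinition("G19833xG23419", "G19833", "G23419", "large"),
        LineDefinition("G23419xG19833", "G23419", "G19833", "small"),
    ]


def _validate_pedigree(lines: Iterable[LineDefinition]) -> tuple:
    lines = list(lines)
    if len(lines) != 4:
        raise ValueError(f"expected exactly 4 lines, got {len(lines)}")
    by_id = {l.line_id: l for l in lines}
    if len(by_id) != 4:
        raise ValueError("duplicate line_id in pedigree")
    parents = [l for l in lines if l.is_selfed]
    hybrids = [l for l in lines if not l.is_selfed]
    if len(parents) != 2 or len(hybrids) != 2:
        raise ValueError("pedigree must contain 2 selfed parents "
                         "and 2 reciprocal F1 hybrids")
    parent_ids = {p.line_id for p in parents}
    crosses = {(h.maternal_parent, h.paternal_parent) for h in hybrids}
    p1, p2 = sorted(parent_ids)
    if crosses != {(p1, p2), (p2, p1)}:
        raise ValueError("the two hybrids must be reciprocal crosses "
                         "of the two parents")
    if len({p.seed_size_class for p in parents}) != 2:
        raise ValueError("the two parents must have contrasting "
                         "seed size classes")
    for h in hybrids:
        if h.seed_size_class != by_id[h.maternal_parent].seed_size_class:
            raise ValueError(
                f"line {h.line_id}: seed_size_class must equal the "
                f"maternal parent's class")
    return parents, hybrids


def make_scheme(name: str, lines: Iterable[LineDefinition]) -> GroupingScheme:
    """Build a named grouping scheme over a validated four-line pedigree."""
    if name not in SCHEME_NAMES:
        raise ValueError(f"unknown scheme {name!r}; expected one of "
                         f"{SCHEME_NAMES}")
    parents, hybrids = _validate_pedigree(lines)
    all_lines = parents + hybrids
    if name == "GEN4":
        level_of = {l.line_id: l.line_id for l in all_lines}
    elif name == "GEN3":
        level_of = {p.line_id: p.line_id for p in parents}
        level_of.update({h.line_id: "F1" for h in hybrids})
    elif name == "MAPHE":
        level_of = {l.line_id: l.seed_size_class for l in all_lines}
    elif name == "MAHY":
        level_of = {p.line_id: "parental" for p in parents}
        level_of.update({h.line_id: h.line_id for h in hybrids})
    else:  # UNI
        level_of = {l.line_id: "all" for l in all_lines}
    return GroupingScheme(name, level_of)


def all_schemes(lines: Iterable[LineDefinition]) -> dict:
    """All five hypotheses keyed by name."""
    lines = list(lines)
    return {name: make_scheme(name, lines) for name in SCHEME_NAMES}


def param_count(scheme: GroupingScheme, family: str,
                n_variance_terms: int) -> int:
    """Total estimated parameters: 3 mean parameters per level plus the
    nuisance (variance/correlation) terms supplied by the fitting layer."""
    family_info(family)  # validates the name
    return 3 * scheme.n_levels + int(n_variance_terms)


def is_coarsening(coarse: GroupingScheme, fine: GroupingScheme) -> bool:
    """True if every level of ``fine`` maps inside a single level of
    ``coarse`` (i.e. ``coarse`` merges levels of ``fine``)."""
    if set(coarse.level_of) != set(fine.level_of):
        return False
    for level in fine.levels:
        block = fine.lines_in(level)
        coarse_levels = {coarse.level_of[l] for l in block}
        if len(coarse_levels) != 1:
            return False
    return True
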