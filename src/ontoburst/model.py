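"""Tree data model and code grammars for positional ontology identifiers.

Two real-world grammars are supported:

* **ATC** -- Anatomical Therapeutic Chemical codes. Five levels encoded in
  the code length: 1 character (anatomical main group), 3 (therapeutic
  subgroup), 4 (pharmacological subgroup), 5 (chemical subgroup) and
  7 (substance). The parent is obtained by truncating to the next shorter
  valid length.
* **MeSH** -- dot-separated tree numbers such as ``C01.925.782``; the level
  is the number of segments and the parent drops the last segment.

A **GENERIC** grammar (dot-separated alphanumeric segments) backs OBO
unfolding and synthetic test fixtures.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Optional, Sequence

from .errors import DuplicateCodeError, MalformedCodeError

__all__ = [
    "OntologyKind",
    "TermRecord",
    "OntologyNode",
    "OntologyForest",
    "parse_atc_code",
    "parse_mesh_tree_number",
    "parse_generic_code",
    "parse_code",
    "build_forest",
    "HEX_COLOR_RE",
]

HEX_COLOR_RE = re.compile(r"#[0-9A-Fa-f]{6}\Z")

_ATC_LEVEL_BY_LEN = {1: 1, 3: 2, 4: 3, 5: 4, 7: 5}
_ATC_PARENT_LEN = {3: 1, 4: 3, 5: 4, 7: 5}

_MESH_FIRST_SEG_RE = re.compile(r"[A-Za-z][0-9]+\Z")
_MESH_SEG_RE = re.compile(r"[0-9]+\Z")
_GENERIC_SEG_RE = re.compile(r"[A-Za-z0-9]+\Z")


class OntologyKind(str, Enum):
    """Which code grammar a forest (or record collection) follows."""

    ATC = "atc"
    MESH = "mesh"
    OBO = "obo"
    GENERIC = "generic"


def parse_atc_code(code: str) -> tuple[int, Optional[str]]:
    """Return ``(level, parent_code)`` for an ATC code.

    Level is determined purely by code length (1, 3, 4, 5 or 7 characters);
    the parent is the code truncated to the next shorter valid length.
    Level-1 codes have no parent.

    Raises
    ------
    MalformedCodeError
        If the code is empty, not uppercase alphanumeric, or of invalid
        length.
    """
    if not code:
        raise MalformedCodeError(code, "empty code")
    if not code.isalnum() or code != code.upper():
        raise MalformedCodeError(code, "must be uppercase alphanumeric")
    level = _ATC_LEVEL_BY_LEN.get(len(code))
    if level is None:
        raise MalformedCodeError(
            code, f"length {len(code)} not in {{1, 3, 4, 5, 7}}"
        )
    parent = code[: _ATC_PARENT_LEN[len(code)]] if level > 1 else None
    return level, parent


def parse_mesh_tree_number(tree_number: str) -> tuple[int, Optional[str]]:
    """Return ``(level, parent_code)`` for a MeSH tree number.

    The level equals the number of dot-separated segments; the parent drops
    the final segment. Single-segment numbers (category roots such as
    ``C01``) have no parent.
    """
    if not tree_number:
        raise MalformedCodeError(tree_number, "empty code")
    segments = tree_number.split(".")
    if not _MESH_FIRST_SEG_RE.match(segments[0]):
        raise MalformedCodeError(
            tree_number, f"first segment {segments[0]!r} must be a letter followed by digits"
        )
    for seg in segments[1:]:
        if not _MESH_SEG_RE.match(seg):
            raise MalformedCodeError(
                tree_number, f"segment {seg!r} must be all digits"
            )
    parent = ".".join(segments[:-1]) if len(segments) > 1 else None
    return len(segments), parent


def parse_generic_code(code: str) -> tuple[int, Optional[str]]:
    """Return ``(level, parent_code)`` for a generic dot-separated code."""
    if not code:
        raise MalformedCodeError(code, "empty code")
    segments = code.split(".")
    for seg in segments:
        if not _GENERIC_SEG_RE.match(seg):
            raise MalformedCodeError(code, f"segment {seg!r} must be alphanumeric")
    parent = ".".join(segments[:-1]) if len(segments) > 1 else None
    return len(segments), parent


_PARSERS = {
    OntologyKind.ATC: parse_atc_code,
    OntologyKind.MESH: parse_mesh_tree_number,
    OntologyKind.OBO: parse_generic_code,
    OntologyKind.GENERIC: parse_generic_code,
}


def parse_code(code: str, kind: OntologyKind) -> tuple[int, Optional[str]]:
    """Dispatch to the grammar of ``kind``."""
    return _PARSERS[OntologyKind(kind)](code)


@dataclass(frozen=True)
class TermRecord:
    """One input row: a positional code plus its annotation.

    ``count`` defaults to 0 and must be non-negative; ``color``, if given,
    must be a ``#RRGGBB`` hex string.
    """

    code: str
    label: str = ""
    count: float = 0.0
    color: Optional[str] = None
    description: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.code:
            raise MalformedCodeError(self.code, "empty code")
        if self.count < 0:
            raise ValueError(f"count must be >= 0, got {self.count}")
        if self.color is not None and not HEX_COLOR_RE.match(self.color):
            raise ValueError(f"invalid hex color {self.color!r}")


@dataclass
class OntologyNode:
    """A position in the hierarchy with raw and propagated annotation counts.

    ``synthetic`` marks ancestors that were not present in the input and were
    created to complete the tree; their label equals their code.
    """

    code: str
    label: str
    level: int
    raw_count: float = 0.0
    propagated_count: float = 0.0
    color: Optional[str] = None
    description: Optional[str] = None
    synthetic: bool = False
    children: list["OntologyNode"] = field(default_factory=list)

    def iter_subtree(self) -> Iterator["OntologyNode"]:
        """Depth-first pre-order traversal, children in stored order."""
        yield self
        for child in self.children:
            yield from child.iter_subtree()

    def subtree_size(self) -> int:
        return sum(1 for _ in self.iter_subtree())


@dataclass
class OntologyForest:
    """One tree per level-1 category, roots ordered by code."""

    kind: OntologyKind
    roots: list[OntologyNode] = field(default_factory=list)

    @property
    def max_depth(self) -> int:
        return max((n.level for n in self.iter_nodes()), default=0)

    def iter_nodes(self) -> Iterator[OntologyNode]:
        for root in self.roots:
            yield from root.iter_subtree()

    def find(self, code: str) -> Optional[OntologyNode]:
        for node in self.iter_nodes():
            if node.code == code:
                return node
        return None

    def flatten(self) -> list[tuple[str, float]]:
        """All ``(code, raw_count)`` pairs in traversal order."""
        return [(n.code, n.raw_count) for n in self.iter_nodes()]

    def size(self) -> int:
        return sum(1 for _ in self.iter_nodes())


def build_forest(
    records: Iterable[TermRecord] | Sequence[TermRecord],
    kind: OntologyKind,
) -> OntologyForest:
    """Assemble an :class:`OntologyForest` from term records.

    Every record becomes a node at the level its code dictates. Missing
    intermediate ancestors are synthesized with ``raw_count`` 0 and their
    code as placeholder label. Children are sorted ascending by code;
    ``propagated_count`` is initialized to ``raw_count``.

    ATC codes are uppercased on ingest; MeSH tree numbers and generic codes
    are taken verbatim.

    Raises
    ------
    DuplicateCodeError
        If the same code occurs in more than one record.
    MalformedCodeError
        If any code fails the grammar of ``kind``.
    """
    kind = OntologyKind(kind)
    normalized: list[TermRecord] = []
    for rec in records:
        code = rec.code.upper() if kind is OntologyKind.ATC else rec.code
        parse_code(code, kind)  # raises on malformed input
        if code != rec.code:
            rec = TermRecord(code, rec.label, rec.count, rec.color, rec.description)
        normalized.append(rec)

    seen: dict[str, int] = {}
    for rec in normalized:
        seen[rec.code] = seen.get(rec.code, 0) + 1
    dups = [c for c, n in seen.items() if n > 1]
    if dups:
        raise DuplicateCodeError(dups)

    nodes: dict[str, OntologyNode] = {}
    for rec in normalized:
        level, _ = parse_code(rec.code, kind)
        nodes[rec.code] = OntologyNode(
            code=rec.code,
            label=rec.label or rec.code,
            level=level,
            raw_count=float(rec.count),
            propagated_count=float(rec.count),
            color=rec.color,
            description=rec.description,
        )

    # Synthesize missing ancestors by walking each parent chain upwards.
    for code in list(nodes):
        level, parent = parse_code(code, kind)
        while parent is not None and parent not in nodes:
            plevel, grandparent = parse_code(parent, kind)
            nodes[parent] = OntologyNode(
                code=parent, label=parent, level=plevel, synthetic=True
            )
            parent = grandparent

    roots: list[OntologyNode] = []
    for code in sorted(nodes):
        node = nodes[code]
        _, parent = parse_code(code, kind)
        if parent is None:
            roots.append(node)
        else:
            nodes[parent].children.append(node)

    # Sorted insertion order above already yields children sorted by code,
    # but make the invariant explicit.
    for node in nodes.values():
        node.children.sort(key=lambda n: n.code)
    roots.sort(key=lambda n: n.code)
    return OntologyForest(kind=kind, roots=roots)
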