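"""Pure transforms on an :class:`~ontoburst.model.OntologyForest`.

Canonical pipeline order is propagate -> drop_empty -> assign_colors:
up-propagation changes the effective counts, which in turn drive both
pruning and automatic color coding.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass

from .errors import ConfigError
from .model import HEX_COLOR_RE, OntologyForest, OntologyNode

__all__ = [
    "ColorScale",
    "PropagationConfig",
    "propagate_counts",
    "drop_empty",
    "interpolate_color",
    "assign_colors",
]


@dataclass(frozen=True)
class ColorScale:
    """Ordered stops ``(position in [0, 1], '#RRGGBB')`` for value coloring.

    Positions must be strictly increasing, starting at 0.0 and ending at
    1.0; at least two stops are required.
    """

    stops: tuple[tuple[float, str], ...]

    def __post_init__(self) -> None:
        stops = tuple((float(p), c) for p, c in self.stops)
        object.__setattr__(self, "stops", stops)
        if len(stops) < 2:
            raise ConfigError("color scale needs at least 2 stops")
        positions = [p for p, _ in stops]
        if positions[0] != 0.0 or positions[-1] != 1.0:
            raise ConfigError("color scale must start at 0.0 and end at 1.0")
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ConfigError("color scale positions must be strictly increasing")
        for _, color in stops:
            if not HEX_COLOR_RE.match(color):
                raise ConfigError(f"invalid hex color {color!r} in scale")

    @classmethod
    def from_string(cls, text: str) -> "ColorScale":
        """Parse the CLI mini-grammar ``"pos:hex,pos:hex,..."``."""
        stops = []
        for part in text.split(","):
            part = part.strip()
            if not part:
                continue
            pos, _, color = part.partition(":")
            try:
                stops.append((float(pos), color.strip()))
            except ValueError as exc:
                raise ConfigError(f"bad color-scale stop {part!r}") from exc
        return cls(tuple(stops))

    @classmethod
    def white_to_red(cls) -> "ColorScale":
        return cls(((0.0, "#FFFFFF"), (1.0, "#FF0000")))


@dataclass(frozen=True)
class PropagationConfig:
    """Controls bottom-up count propagation.

    ``max_level`` is the shallowest level that still receives propagated
    sums (level 1 = category roots, i.e. propagate all the way up).
    ``include_self`` adds a node's own raw count to its children's sums so
    annotations on interior terms are not lost; disabling it makes interior
    nodes report the pure child sum.
    """

    enabled: bool = True
    max_level: int = 1
    include_self: bool = True

    def __post_init__(self) -> None:
        if self.max_level < 1:
            raise ConfigError(f"max_level must be >= 1, got {self.max_level}")


def propagate_counts(
    forest: OntologyForest, config: PropagationConfig
) -> OntologyForest:
    """Return a new forest with counts summed into ancestors.

    For every node with ``level >= config.max_level`` the propagated count
    is its raw count (when ``include_self``) plus the propagated counts of
    its children, computed bottom-up. Shallower nodes keep
    ``propagated_count == raw_count``. A disabled config is the identity.
    """
    result = copy.deepcopy(forest)
    if not config.enabled:
        for node in result.iter_nodes():
            node.propagated_count = node.raw_count
        return result

    def visit(node: OntologyNode) -> float:
        child_sum = sum(visit(child) for child in node.children)
        if node.level >= config.max_level:
            own = node.raw_count if (config.include_self or not node.children) else 0.0
            node.propagated_count = own + child_sum
        else:
            node.propagated_count = node.raw_count
        return node.propagated_count

    for root in result.roots:
        visit(root)
    return result


def drop_empty(forest: OntologyForest) -> OntologyForest:
    """Remove maximal all-empty subtrees (fixpoint of zero-leaf pruning).

    A node survives iff some node in its subtree has a non-zero effective
    (propagated) count. Never removes a node with effective count > 0.
    """
    result = copy.deepcopy(forest)

    def prune(node: OntologyNode) -> bool:
        node.children = [c for c in node.children if prune(c)]
        return node.propagated_count > 0 or bool(node.children)

    result.roots = [r for r in result.roots if prune(r)]
    return result


def _round_half_away(x: float) -> int:
    # round-half-away-from-zero, for cross-platform determinism
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _hex_to_rgb(color: str) -> tuple[int, int, int]:
    return (int(color[1:3], 16), int(color[3:5], 16), int(color[5:7], 16))


def interpolate_color(scale: ColorScale, v: float) -> str:
    """Linearly interpolate the scale at ``v`` in RGB space.

    Channels are rounded half-away-from-zero; the result is an uppercase
    ``#RRGGBB`` string. Raises :class:`ConfigError` for ``v`` outside
    ``[0, 1]``.
    """
    if not 0.0 <= v <= 1.0:
        raise ConfigError(f"color position {v} outside [0, 1]")
    stops = scale.stops
    for (p0, c0), (p1, c1) in zip(stops, stops[1:]):
        if p0 <= v <= p1:
            t = 0.0 if p1 == p0 else (v - p0) / (p1 - p0)
            rgb0, rgb1 = _hex_to_rgb(c0), _hex_to_rgb(c1)
            channels = [
                _round_half_away(a + (b - a) * t) for a, b in zip(rgb0, rgb1)
            ]
            return "#{:02X}{:02X}{:02X}".format(*channels)
    raise ConfigError(f"no bracketing stops for {v}")  # pragma: no cover


def assign_colors(
    forest: OntologyForest, scale: ColorScale, per_branch: bool = False
) -> OntologyForest:
    """Resolve node colors from effective counts.

    Counts are normalized by the global maximum over the forest (or per
    level-1 tree when ``per_branch``). Manual colors from the input always
    override automatic coloring. If the maximum is 0, every node gets the
    scale's position-0 color.
    """
    result = copy.deepcopy(forest)

    def colorize(nodes, max_count: float) -> None:
        for node in nodes:
            if node.color is not None:
                continue
            v = node.propagated_count / max_count if max_count > 0 else 0.0
            node.color = interpolate_color(scale, min(v, 1.0))

    if per_branch:
        for root in result.roots:
            subtree = list(root.iter_subtree())
            colorize(subtree, max((n.propagated_count for n in subtree), default=0.0))
    else:
        nodes = list(result.iter_nodes())
        colorize(nodes, max((n.propagated_count for n in nodes), default=0.0))
    return result
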