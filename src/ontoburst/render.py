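"""Sunburst plot specifications and HTML / JSON export.

The renderer is split in two layers: :func:`build_plot_spec` produces
renderer-agnostic parallel arrays (one :class:`PlotSpec` per level-1
branch) that are fully testable without a browser, and :func:`export_html`
turns a spec or a tiled :class:`GridLayout` into a single self-contained
HTML file with inline SVG sunbursts — no scripts or resources are loaded
from the network.
"""

from __future__ import annotations

import html
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

from .errors import ConfigError, EmptyInputError, FormatError
from .model import HEX_COLOR_RE, OntologyForest, OntologyNode

__all__ = [
    "PlotConfig",
    "PlotSpec",
    "GridLayout",
    "build_plot_spec",
    "layout_summary",
    "export_html",
    "export_json",
    "load_json",
    "SPEC_VERSION",
]

SPEC_VERSION = 1


@dataclass(frozen=True)
class PlotConfig:
    """Appearance settings shared by every sunburst in one run.

    ``show_labels`` is ``"all"``, ``"none"`` or an integer L meaning
    "labels up to level L". Border settings control the wedge outline.
    """

    summary: bool = True
    plots_per_row: int = 5
    show_labels: Union[str, int] = "all"
    border_enabled: bool = True
    border_color: str = "#FFFFFF"
    border_width: float = 1.0
    drop_empty: bool = True
    title: str = ""
    precision: int = 2

    def __post_init__(self) -> None:
        if self.plots_per_row < 1:
            raise ConfigError(f"plots_per_row must be >= 1, got {self.plots_per_row}")
        if self.border_width < 0:
            raise ConfigError(f"border width must be >= 0, got {self.border_width}")
        if not HEX_COLOR_RE.match(self.border_color):
            raise ConfigError(f"invalid border color {self.border_color!r}")
        if isinstance(self.show_labels, str):
            if self.show_labels not in ("all", "none"):
                raise ConfigError(
                    f"show_labels must be 'all', 'none' or an integer, got {self.show_labels!r}"
                )
        elif self.show_labels < 1:
            raise ConfigError("show_labels level must be >= 1")

    def label_visible(self, level: int) -> bool:
        if self.show_labels == "all":
            return True
        if self.show_labels == "none":
            return False
        return level <= int(self.show_labels)

    def to_dict(self) -> dict:
        return {
            "summary": self.summary,
            "plots_per_row": self.plots_per_row,
            "show_labels": self.show_labels,
            "border_enabled": self.border_enabled,
            "border_color": self.border_color,
            "border_width": self.border_width,
            "drop_empty": self.drop_empty,
            "title": self.title,
            "precision": self.precision,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PlotConfig":
        return cls(**data)


@dataclass
class PlotSpec:
    """Parallel arrays describing one branch sunburst.

    ``parent_id`` is the empty string for the branch root; all arrays have
    equal length and node ids are unique within the spec.
    """

    branch_root_label: str
    node_id: list[str] = field(default_factory=list)
    parent_id: list[str] = field(default_factory=list)
    label: list[str] = field(default_factory=list)
    value: list[float] = field(default_factory=list)
    color: list[str] = field(default_factory=list)
    hover_text: list[str] = field(default_factory=list)
    level: list[int] = field(default_factory=list)
    config: PlotConfig = field(default_factory=PlotConfig)

    def __len__(self) -> int:
        return len(self.node_id)

    def to_dict(self) -> dict:
        return {
            "branch_root_label": self.branch_root_label,
            "node_id": self.node_id,
            "parent_id": self.parent_id,
            "label": self.label,
            "value": self.value,
            "color": self.color,
            "hover_text": self.hover_text,
            "level": self.level,
            "config": self.config.to_dict(),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PlotSpec":
        data = dict(data)
        data["config"] = PlotConfig.from_dict(data["config"])
        return cls(**data)


@dataclass
class GridLayout:
    """Row-major tiling of branch sunbursts for the summary view."""

    rows: list[list[PlotSpec]]
    plots_per_row: int

    @property
    def row_lengths(self) -> list[int]:
        return [len(row) for row in self.rows]

    @property
    def specs(self) -> list[PlotSpec]:
        return [spec for row in self.rows for spec in row]

    def to_dict(self) -> dict:
        return {
            "plots_per_row": self.plots_per_row,
            "rows": [[spec.to_dict() for spec in row] for row in self.rows],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "GridLayout":
        return cls(
            rows=[[PlotSpec.from_dict(s) for s in row] for row in data["rows"]],
            plots_per_row=data["plots_per_row"],
        )


def _format_count(count: float, precision: int) -> str:
    if float(count).is_integer():
        return str(int(count))
    return f"{count:.{precision}f}"


def _hover(node: OntologyNode, precision: int) -> str:
    parts = [node.label, node.code, _format_count(node.propagated_count, precision)]
    if node.description:
        parts.append(node.description)
    return " | ".join(parts)


def build_plot_spec(forest: OntologyForest, config: PlotConfig) -> list[PlotSpec]:
    """One :class:`PlotSpec` per level-1 root, ordered by root code.

    Nodes are emitted depth-first with children ordered by code. Labels
    suppressed by the label policy become empty strings; hover text is kept
    regardless. Raises :class:`EmptyInputError` for an empty forest.
    """
    if not forest.roots:
        raise EmptyInputError("forest has no branches to plot")
    specs: list[PlotSpec] = []
    for root in forest.roots:
        spec = PlotSpec(branch_root_label=root.label, config=config)

        def emit(node: OntologyNode, parent_code: str) -> None:
            spec.node_id.append(node.code)
            spec.parent_id.append(parent_code)
            spec.label.append(node.label if config.label_visible(node.level) else "")
            spec.value.append(node.propagated_count)
            spec.color.append(node.color or "#FFFFFF")
            spec.hover_text.append(_hover(node, config.precision))
            spec.level.append(node.level)
            for child in node.children:
                emit(child, node.code)

        emit(root, "")
        specs.append(spec)
    return specs


def layout_summary(specs: list[PlotSpec], plots_per_row: int) -> GridLayout:
    """Tile specs row-major; the last row may be partial."""
    if plots_per_row < 1:
        raise ConfigError(f"plots_per_row must be >= 1, got {plots_per_row}")
    if not specs:
        raise EmptyInputError("no plot specs to lay out")
    rows = [
        specs[i : i + plots_per_row] for i in range(0, len(specs), plots_per_row)
    ]
    return GridLayout(rows=rows, plots_per_row=plots_per_row)


# --------------------------------------------------------------------------
# JSON export
# --------------------------------------------------------------------------

def export_json(obj: Union[GridLayout, PlotSpec], path: Union[str, Path]) -> None:
    """Lossless, deterministic (sorted keys) serialization of a spec/layout."""
    if isinstance(obj, GridLayout):
        payload = {"spec_version": SPEC_VERSION, "kind": "layout", "data": obj.to_dict()}
    elif isinstance(obj, PlotSpec):
        payload = {"spec_version": SPEC_VERSION, "kind": "spec", "data": obj.to_dict()}
    else:
        raise TypeError(f"cannot export {type(obj).__name__}")
    Path(path).write_text(
        json.dumps(payload, sort_keys=True, indent=2) + "\n", encoding="utf-8"
    )


def load_json(path: Union[str, Path]) -> Union[GridLayout, PlotSpec]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("spec_version") != SPEC_VERSION:
        raise FormatError(f"unsupported spec_version {payload.get('spec_version')!r}")
    if payload["kind"] == "layout":
        return GridLayout.from_dict(payload["data"])
    if payload["kind"] == "spec":
        return PlotSpec.from_dict(payload["data"])
    raise FormatError(f"unknown payload kind {payload['kind']!r}")


# --------------------------------------------------------------------------
# HTML export (inline SVG, no external resources)
# --------------------------------------------------------------------------

_TAU = 2 * math.pi
_SVG_SIZE = 420.0
_HOLE_FRACTION = 0.12


def _polar(cx: float, cy: float, r: float, angle: float) -> tuple[float, float]:
    return (cx + r * math.cos(angle), cy + r * math.sin(angle))


def _arc_path(cx, cy, r0, r1, a0, a1) -> str:
    """Annular sector path. Spans are clamped just below a full turn."""
    span = min(a1 - a0, _TAU - 1e-4)
    a1 = a0 + span
    large = 1 if span > math.pi else 0
    x0o, y0o = _polar(cx, cy, r1, a0)
    x1o, y1o = _polar(cx, cy, r1, a1)
    x1i, y1i = _polar(cx, cy, r0, a1)
    x0i, y0i = _polar(cx, cy, r0, a0)
    return (
        f"M {x0o:.3f} {y0o:.3f} "
        f"A {r1:.3f} {r1:.3f} 0 {large} 1 {x1o:.3f} {y1o:.3f} "
        f"L {x1i:.3f} {y1i:.3f} "
        f"A {r0:.3f} {r0:.3f} 0 {large} 0 {x0i:.3f} {y0i:.3f} Z"
    )


def _angular_layout(spec: PlotSpec) -> dict[str, tuple[float, float]]:
    """Assign ``(start, end)`` angles to every node of a branch spec.

    Children subdivide the parent's span proportionally to their values.
    Zero-valued children (kept when drop-empty is off) equally split the
    residual left by the parent's own contribution, or a small epsilon so
    they stay visible.
    """
    children: dict[str, list[int]] = {}
    by_id = {nid: i for i, nid in enumerate(spec.node_id)}
    root_idx = None
    for i, (nid, pid) in enumerate(zip(spec.node_id, spec.parent_id)):
        if pid == "":
            root_idx = i
        else:
            children.setdefault(pid, []).append(i)
    assert root_idx is not None

    spans: dict[str, tuple[float, float]] = {spec.node_id[root_idx]: (0.0, _TAU)}

    def subdivide(idx: int) -> None:
        nid = spec.node_id[idx]
        kids = children.get(nid, [])
        if not kids:
            return
        a0, a1 = spans[nid]
        span = a1 - a0
        values = [spec.value[k] for k in kids]
        child_sum = sum(values)
        zeros = [k for k, v in zip(kids, values) if v <= 0]
        residual = max(spec.value[idx] - child_sum, 0.0)
        eps = residual / len(zeros) if zeros and residual > 0 else 0.0
        if zeros and eps == 0.0:
            eps = 0.01 * (max(values) if child_sum > 0 else 1.0)
        weights = [v if v > 0 else eps for v in values]
        total = sum(weights)
        if total <= 0:
            weights = [1.0] * len(kids)
            total = float(len(kids))
        cursor = a0
        for k, w in zip(kids, weights):
            width = span * w / total
            spans[spec.node_id[k]] = (cursor, cursor + width)
            cursor += width
        for k in kids:
            subdivide(k)

    subdivide(root_idx)
    return spans


def _render_svg(spec: PlotSpec) -> str:
    config = spec.config
    cx = cy = _SVG_SIZE / 2
    outer = _SVG_SIZE / 2 - 4
    hole = outer * _HOLE_FRACTION
    min_level = min(spec.level)
    depth = max(spec.level) - min_level + 1
    ring = (outer - hole) / depth
    spans = _angular_layout(spec)

    stroke = config.border_color if config.border_enabled else "none"
    width = config.border_width if config.border_enabled else 0

    wedges: list[str] = []
    texts: list[str] = []
    for i, nid in enumerate(spec.node_id):
        a0, a1 = spans[nid]
        band = spec.level[i] - min_level
        r0 = hole + band * ring
        r1 = r0 + ring
        path = _arc_path(cx, cy, r0, r1, a0, a1)
        title = html.escape(spec.hover_text[i])
        wedges.append(
            f'<path d="{path}" fill="{spec.color[i]}" stroke="{stroke}" '
            f'stroke-width="{width}"><title>{title}</title></path>'
        )
        if spec.label[i]:
            mid = (a0 + a1) / 2
            tx, ty = _polar(cx, cy, (r0 + r1) / 2, mid)
            texts.append(
                f'<text x="{tx:.1f}" y="{ty:.1f}" text-anchor="middle" '
                f'dominant-baseline="middle" class="lbl">{html.escape(spec.label[i])}</text>'
            )
    return (
        f'<svg viewBox="0 0 {_SVG_SIZE:.0f} {_SVG_SIZE:.0f}" class="sunburst" '
        f'role="img">{"".join(wedges)}{"".join(texts)}</svg>'
    )


_HTML_STYLE = """
body { font-family: sans-serif; margin: 1em; background: #fafafa; }
h1 { font-size: 1.2em; }
.grid { display: grid; gap: 12px; }
.cell { text-align: center; }
.cell figcaption { font-size: 0.85em; margin-top: 4px; }
svg.sunburst { width: 100%; height: auto; }
svg.sunburst path:hover { opacity: 0.75; cursor: pointer; }
svg.sunburst text.lbl { font-size: 9px; pointer-events: none; }
""".strip()


def export_html(obj: Union[GridLayout, PlotSpec], path: Union[str, Path]) -> None:
    """Write a single self-contained HTML file of hoverable sunbursts.

    No external scripts, stylesheets or fonts are referenced; hover text
    uses native SVG ``<title>`` tooltips. Raises
    :class:`EmptyInputError` for an empty layout or spec.
    """
    if isinstance(obj, PlotSpec):
        if len(obj) == 0:
            raise EmptyInputError("plot spec has no nodes")
        layout = GridLayout(rows=[[obj]], plots_per_row=1)
    elif isinstance(obj, GridLayout):
        if not obj.rows or not any(obj.rows):
            raise EmptyInputError("layout has no plots")
        layout = obj
    else:
        raise TypeError(f"cannot export {type(obj).__name__}")

    first = layout.rows[0][0]
    title = first.config.title or "Ontology sunburst"
    ncols = min(layout.plots_per_row, max(layout.row_lengths))
    cells: list[str] = []
    for row in layout.rows:
        for spec in row:
            caption = html.escape(spec.branch_root_label)
            cells.append(
                f'<figure class="cell">{_render_svg(spec)}'
                f"<figcaption>{caption}</figcaption></figure>"
            )
    doc = (
        "<!DOCTYPE html>\n<html>\n<head>\n<meta charset=\"utf-8\">\n"
        f"<title>{html.escape(title)}</title>\n<style>\n{_HTML_STYLE}\n</style>\n"
        "</head>\n<body>\n"
        f"<h1>{html.escape(title)}</h1>\n"
        f'<div class="grid" style="grid-template-columns: repeat({ncols}, 1fr);">\n'
        + "\n".join(cells)
        + "\n</div>\n</body>\n</html>\n"
    )
    Path(path).write_text(doc, encoding="utf-8")
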