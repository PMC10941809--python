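"""Readers and writers for template tables and ontology source formats.

Template tables are the tool's tabular input: one row per ontology
position with a code, a label, a numeric count, and optional hex color and
description columns. TSV (UTF-8, tab-separated, header row) and XLSX
(first worksheet, header row) are supported and round-trip losslessly.
Unrecognized columns are carried through verbatim as ``extra_columns``.
"""

from __future__ import annotations

import csv
import io
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Optional, Sequence, Union

from .errors import (
    CycleError,
    DuplicateCodeError,
    EmptyInputError,
    FormatError,
    MalformedCodeError,
    ValidationError,
)
from .model import HEX_COLOR_RE, TermRecord, parse_atc_code

__all__ = [
    "TemplateTable",
    "read_template",
    "write_template",
    "parse_obo",
    "parse_mesh_descriptor_xml",
    "parse_atc_flat_table",
]

logger = logging.getLogger(__name__)

# header synonyms, matched case-insensitively after stripping
_CODE_HEADERS = {"id", "code", "tree_number", "atc_code"}
_LABEL_HEADERS = {"name", "label", "term"}
_COUNT_HEADERS = {"count", "counts", "value"}
_COLOR_HEADERS = {"color", "colour"}
_DESC_HEADERS = {"description", "comment"}


@dataclass
class TemplateTable:
    """Parsed template: records plus pass-through extra columns.

    ``extra_columns`` maps original header name to one value per row,
    preserved byte-identically on round trip.
    """

    rows: list[TermRecord] = field(default_factory=list)
    extra_columns: dict[str, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rows)


def _classify_headers(header: Sequence[str]) -> dict[str, Optional[int]]:
    roles: dict[str, Optional[int]] = {
        "code": None, "label": None, "count": None, "color": None, "description": None,
    }
    extra_idx: list[int] = []
    for i, name in enumerate(header):
        key = name.strip().lower()
        if key in _CODE_HEADERS and roles["code"] is None:
            roles["code"] = i
        elif key in _LABEL_HEADERS and roles["label"] is None:
            roles["label"] = i
        elif key in _COUNT_HEADERS and roles["count"] is None:
            roles["count"] = i
        elif key in _COLOR_HEADERS and roles["color"] is None:
            roles["color"] = i
        elif key in _DESC_HEADERS and roles["description"] is None:
            roles["description"] = i
        else:
            extra_idx.append(i)
    roles["_extra"] = extra_idx  # type: ignore[assignment]
    return roles


def _rows_to_table(header: Sequence[str], rows: Iterable[Sequence[object]]) -> TemplateTable:
    roles = _classify_headers([str(h) for h in header])
    if roles["code"] is None:
        raise FormatError(
            f"no code column found in header {list(header)!r} "
            f"(accepted: {sorted(_CODE_HEADERS)})"
        )
    extra_idx: list[int] = roles["_extra"]  # type: ignore[assignment]
    table = TemplateTable(extra_columns={str(header[i]): [] for i in extra_idx})

    def cell(row: Sequence[object], idx: Optional[int]) -> str:
        if idx is None or idx >= len(row) or row[idx] is None:
            return ""
        return str(row[idx])

    for rownum, row in enumerate(rows, start=2):  # header is row 1
        code = cell(row, roles["code"]).strip()
        if not code:
            raise ValidationError("empty code cell", row=rownum)
        raw_count = cell(row, roles["count"]).strip()
        if raw_count == "":
            count = 0.0
        else:
            try:
                count = float(raw_count)
            except ValueError:
                raise ValidationError(f"unparseable count {raw_count!r}", row=rownum)
        if count < 0:
            raise ValidationError(f"negative count {count}", row=rownum)
        color = cell(row, roles["color"]).strip() or None
        if color is not None and not HEX_COLOR_RE.match(color):
            raise ValidationError(f"invalid hex color {color!r}", row=rownum)
        description = cell(row, roles["description"]) or None
        table.rows.append(
            TermRecord(
                code=code,
                label=cell(row, roles["label"]),
                count=count,
                color=color.upper() if color else None,
                description=description,
            )
        )
        for i in extra_idx:
            table.extra_columns[str(header[i])].append(cell(row, i))
    return table


def _resolve_format(path: Path, format: str) -> str:
    if format != "auto":
        return format
    suffix = path.suffix.lower()
    if suffix == ".tsv":
        return "tsv"
    if suffix == ".xlsx":
        return "xlsx"
    raise FormatError(f"cannot infer format from extension {suffix!r} of {path}")


def read_template(path: Union[str, Path], format: str = "auto") -> TemplateTable:
    """Read a TSV or XLSX template file into a :class:`TemplateTable`.

    ``format`` is ``"tsv"``, ``"xlsx"`` or ``"auto"`` (resolve by
    extension). Empty count cells become 0. Recognized columns (matched
    case-insensitively, with synonyms): code, label, count, color,
    description; everything else is kept as an extra column.
    """
    path = Path(path)
    fmt = _resolve_format(path, format)
    if fmt == "tsv":
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.reader(fh, delimiter="\t", quoting=csv.QUOTE_NONE)
            try:
                header = next(reader)
            except StopIteration:
                raise FormatError(f"{path} is empty (no header row)")
            return _rows_to_table(header, reader)
    if fmt == "xlsx":
        from openpyxl import load_workbook

        wb = load_workbook(path, read_only=True, data_only=True)
        try:
            ws = wb.worksheets[0]
            rows = ws.iter_rows(values_only=True)
            try:
                header = [("" if c is None else str(c)) for c in next(rows)]
            except StopIteration:
                raise FormatError(f"{path} has no header row")
            return _rows_to_table(header, rows)
        finally:
            wb.close()
    raise FormatError(f"unknown template format {fmt!r}")


def _format_count(count: float) -> str:
    return str(int(count)) if float(count).is_integer() else repr(float(count))


def write_template(table: TemplateTable, path: Union[str, Path], format: str = "auto") -> None:
    """Write a :class:`TemplateTable` so that reading it back reproduces it.

    Raises :class:`EmptyInputError` for an empty table and
    :class:`ValidationError` if a TSV cell would embed a tab or newline.
    """
    if not table.rows:
        raise EmptyInputError("refusing to write an empty template")
    path = Path(path)
    fmt = _resolve_format(path, format)
    header = ["code", "label", "count", "color", "description"]
    header += list(table.extra_columns)
    body: list[list[str]] = []
    for i, rec in enumerate(table.rows):
        row = [
            rec.code,
            rec.label,
            _format_count(rec.count),
            rec.color or "",
            rec.description or "",
        ]
        row += [table.extra_columns[name][i] for name in table.extra_columns]
        body.append(row)

    if fmt == "tsv":
        for rownum, row in enumerate(body, start=2):
            for value in row:
                if "\t" in value or "\n" in value:
                    raise ValidationError(
                        f"value {value!r} contains a tab or newline", row=rownum
                    )
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", quoting=csv.QUOTE_NONE, quotechar=None)
            writer.writerow(header)
            writer.writerows(body)
        return
    if fmt == "xlsx":
        from openpyxl import Workbook

        wb = Workbook()
        ws = wb.active
        ws.append(header)
        for row in body:
            ws.append(row)
        wb.save(path)
        return
    raise FormatError(f"unknown template format {fmt!r}")


# --------------------------------------------------------------------------
# OBO
# --------------------------------------------------------------------------

def parse_obo(stream: Union[str, IO[str]]) -> list[TermRecord]:
    """Unfold the is_a graph of an OBO document into positional records.

    Every root-to-term path becomes one GENERIC-grammar record whose code is
    the dot-joined sequence of path-local ordinals (siblings sorted by term
    id, ordinals zero-padded to 3 digits). Term names become labels;
    obsolete terms are skipped; counts start at 0.

    Raises :class:`CycleError` for a cyclic is_a graph and
    :class:`FormatError` for a ``[Term]`` stanza without an id.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)

    terms: dict[str, dict] = {}
    current: Optional[dict] = None
    in_term = False
    for raw_line in stream:
        line = raw_line.strip()
        if line.startswith("["):
            if in_term and current is not None:
                _store_term(terms, current)
            in_term = line == "[Term]"
            current = {"id": None, "name": "", "is_a": [], "obsolete": False} if in_term else None
            continue
        if not in_term or current is None or not line:
            continue
        key, _, value = line.partition(":")
        value = value.strip()
        if key == "id":
            current["id"] = value
        elif key == "name":
            current["name"] = value
        elif key == "is_a":
            # strip trailing "! comment"
            current["is_a"].append(value.split("!", 1)[0].strip())
        elif key == "is_obsolete" and value.lower() == "true":
            current["obsolete"] = True
    if in_term and current is not None:
        _store_term(terms, current)

    # drop edges to unknown terms; such children become roots
    children: dict[Optional[str], list[str]] = {}
    for tid, term in terms.items():
        parents = [p for p in term["is_a"] if p in terms] or [None]
        for parent in parents:
            children.setdefault(parent, []).append(tid)

    _check_acyclic(terms)

    records: list[TermRecord] = []

    def descend(tid: str, code: str) -> None:
        # `code` already carries this node's ordinal as its last segment
        records.append(TermRecord(code=code, label=terms[tid]["name"] or tid))
        for i, child in enumerate(sorted(children.get(tid, [])), start=1):
            descend(child, f"{code}.{i:03d}")

    roots = sorted(children.get(None, []))
    for i, tid in enumerate(roots, start=1):
        descend(tid, f"{i:03d}")
    return records


def _store_term(terms: dict, current: dict) -> None:
    if current["id"] is None:
        raise FormatError("[Term] stanza without an id line")
    if current["obsolete"]:
        return
    terms[current["id"]] = current


def _check_acyclic(terms: dict[str, dict]) -> None:
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {tid: WHITE for tid in terms}

    for start in terms:
        if color[start] != WHITE:
            continue
        stack: list[tuple[str, iter]] = [
            (start, iter([p for p in terms[start]["is_a"] if p in terms]))
        ]
        color[start] = GRAY
        while stack:
            tid, it = stack[-1]
            advanced = False
            for nxt in it:
                if color[nxt] == GRAY:
                    raise CycleError(nxt)
                if color[nxt] == WHITE:
                    color[nxt] = GRAY
                    stack.append((nxt, iter([p for p in terms[nxt]["is_a"] if p in terms])))
                    advanced = True
                    break
            if not advanced:
                color[tid] = BLACK
                stack.pop()


# --------------------------------------------------------------------------
# MeSH descriptor XML
# --------------------------------------------------------------------------

def parse_mesh_descriptor_xml(
    stream: Union[str, Path, IO], subtree_prefix: str = "C"
) -> list[TermRecord]:
    """Extract (descriptor, tree number) pairs from NLM descriptor XML.

    One record is produced per tree number that starts with
    ``subtree_prefix`` (a descriptor with several matching tree numbers
    yields several records — MeSH is poly-hierarchical). Descriptors
    without tree numbers are skipped with a log message.

    Raises :class:`FormatError` if the XML is not well-formed.
    """
    try:
        if isinstance(stream, (str, Path)) and Path(str(stream)).exists():
            tree = ET.parse(str(stream))
            root = tree.getroot()
        elif isinstance(stream, str):
            root = ET.fromstring(stream)
        else:
            root = ET.parse(stream).getroot()
    except ET.ParseError as exc:
        raise FormatError(f"malformed MeSH XML: {exc}") from exc

    records: list[TermRecord] = []
    for descriptor in root.iter("DescriptorRecord"):
        name_el = descriptor.find("./DescriptorName/String")
        name = name_el.text.strip() if name_el is not None and name_el.text else ""
        numbers = [
            el.text.strip()
            for el in descriptor.findall("./TreeNumberList/TreeNumber")
            if el.text
        ]
        if not numbers:
            logger.info("descriptor %r has no tree numbers; skipped", name)
            continue
        for number in numbers:
            if number.startswith(subtree_prefix):
                records.append(TermRecord(code=number, label=name))
    return records


# --------------------------------------------------------------------------
# Flat ATC tables
# --------------------------------------------------------------------------

def parse_atc_flat_table(rows: Iterable[tuple[str, str]]) -> list[TermRecord]:
    """Turn ``(code, name)`` pairs into ATC term records with count 0.

    Ancestors need not be present; forest building synthesizes them.
    Raises :class:`MalformedCodeError` (with the row index) on a bad code
    and :class:`DuplicateCodeError` on repeats.
    """
    records: list[TermRecord] = []
    seen: set[str] = set()
    dups: list[str] = []
    for i, (code, name) in enumerate(rows):
        code = code.strip().upper()
        try:
            parse_atc_code(code)
        except MalformedCodeError as exc:
            raise MalformedCodeError(code, f"at row index {i}: {exc}") from exc
        if code in seen:
            dups.append(code)
        seen.add(code)
        records.append(TermRecord(code=code, label=name.strip()))
    if dups:
        raise DuplicateCodeError(dups)
    return records
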