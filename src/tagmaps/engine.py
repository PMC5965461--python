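"""The TagMap engine: declarative DICOM skeletons evaluated against a backend.

A TagMap is an XML file listing, for one DICOM-RT object type, every DICOM
tag to emit.  Each tag carries either a literal value or a query that
locates the value in the source storage — an XPath expression over a
tomo-lite master document, or an SQL statement against a relational
oncology-information-system backend.  Sequences are modelled by a single
template item plus a count source; the engine expands the template and
exposes the 1-based item index as the variable ``$i`` (XPath) or as an
``item`` parameter source (SQL).

The pipeline is skeleton-then-evaluate: ``build_skeleton`` turns a parsed
TagMap into a dataset whose query-bearing elements are distinguishable
placeholders, then ``evaluate`` walks the skeleton strictly in document
order, so later queries may bind values already resolved by earlier tags
(staged evaluation: patient, then study, then series, then plan).

TagMap dialect (exact file shape)::

    <dicom type="CT" version_scope="V3 V4_0 V4_2PLUS">
      <attr tag="GGGGEEEE" vr="XX" [src="literal|query"]
            [count="query"] [params="input:name,tag:GGGG,EEEE,item"]>payload</attr>
      <attr tag="GGGGEEEE" vr="SQ" ...>
        <item> ...exactly one template item of nested <attr>... </item>
      </attr>
    </dicom>

A payload is classified as a query when it starts with ``SELECT `` or with
``$`` or ``(``, or contains a ``/``; the ``src`` attribute overrides the
heuristic.  SQL ``?`` placeholders are bound positionally from ``params``
entries (``input:<name>`` reads the binding context's user inputs,
``tag:GGGG,EEEE`` a previously evaluated element, ``item`` the current
sequence item index).
"""

from __future__ import annotations

import copy
import re
import sqlite3
from dataclasses import dataclass, field
from typing import Any

from lxml import etree
from pydicom.datadict import dictionary_VR
from pydicom.dataset import Dataset
from pydicom.sequence import Sequence
from pydicom.tag import Tag

from .archive import StorageVersion

__all__ = [
    "TagMapError",
    "EvaluationError",
    "TagEntry",
    "TagMap",
    "BindingContext",
    "BlobRef",
    "DicomObjectSpec",
    "XPathBackend",
    "SQLBackend",
    "parse_tagmap",
    "build_skeleton",
    "expand_sequence",
    "evaluate",
    "evaluate_sql",
    "TYPE1_TAGS",
]

TARGET_TYPES = {
    "CT",
    "MVCT",
    "RTPLAN",
    "RTDOSE",
    "RTSTRUCT",
    "QADOSE",
    "DELIVERY_SINOGRAM",
    "RTRECORD",
}


class TagMapError(Exception):
    """Malformed TagMap file."""


class EvaluationError(Exception):
    """A query failed or produced a value that does not fit its VR."""


# ---------------------------------------------------------------------------
# model


@dataclass
class TagEntry:
    tag: Tag
    vr: str
    kind: str  # "literal" | "query"
    payload: str
    children: list["TagEntry"] = field(default_factory=list)  # template item, vr == SQ
    count_source: str | None = None
    params: list[str] = field(default_factory=list)


@dataclass
class TagMap:
    target_type: str
    version_scope: frozenset[StorageVersion]
    entries: list[TagEntry]


@dataclass
class BindingContext:
    """Inputs and already-resolved values available to queries.

    ``resolved`` is filled in document order during evaluation; a query may
    only see values produced by earlier entries (staged evaluation).
    """

    user_inputs: dict[str, Any] = field(default_factory=dict)
    resolved: dict[Tag, Any] = field(default_factory=dict)


@dataclass(frozen=True)
class BlobRef:
    """Marks an element whose value is the UID of a raw binary payload;
    the object builders replace it with transformed pixel bytes."""

    uid: str


#: Type-1 (mandatory) tags per object type; a query returning nothing for one
#: of these marks the whole dataset INCOMPLETE.  Anything else degrades to a
#: logged warning, so partial archives still export with accounting.
TYPE1_TAGS: dict[str, frozenset[Tag]] = {
    t: frozenset(tags)
    for t, tags in {
        "CT": [Tag(0x0010, 0x0020), Tag(0x0020, 0x000D), Tag(0x0020, 0x000E), Tag(0x7FE0, 0x0010)],
        "MVCT": [Tag(0x0010, 0x0020), Tag(0x0020, 0x000D), Tag(0x0020, 0x000E), Tag(0x7FE0, 0x0010)],
        "RTPLAN": [Tag(0x0010, 0x0020), Tag(0x0020, 0x000D), Tag(0x300D, 0x10A7)],
        "RTDOSE": [Tag(0x0010, 0x0020), Tag(0x0020, 0x000D), Tag(0x7FE0, 0x0010)],
        "QADOSE": [Tag(0x0010, 0x0020), Tag(0x0020, 0x000D), Tag(0x7FE0, 0x0010)],
        "RTSTRUCT": [Tag(0x0010, 0x0020), Tag(0x0020, 0x000D)],
        "DELIVERY_SINOGRAM": [Tag(0x0010, 0x0020), Tag(0x7FE0, 0x0010)],
        "RTRECORD": [Tag(0x0010, 0x0010)],
    }.items()
}


# ---------------------------------------------------------------------------
# parsing

_TAG_RE = re.compile(r"^[0-9A-Fa-f]{8}$")
_BINARY_VRS = {"OB", "OW", "OF", "UN"}


def _parse_tag(text: str) -> Tag:
    text = text.replace(" ", "")
    if not _TAG_RE.match(text):
        raise TagMapError(f"malformed hex tag {text!r} (need GGGGEEEE)")
    return Tag(int(text[:4], 16), int(text[4:], 16))


def _classify(payload: str, src: str | None) -> str:
    if src is not None:
        if src not in ("literal", "query"):
            raise TagMapError(f"src must be 'literal' or 'query', got {src!r}")
        return src
    if payload.startswith("SELECT ") or payload.startswith("$") or payload.startswith("("):
        return "query"
    if "/" in payload:
        return "query"
    return "literal"


def _infer_vr(tag: Tag, declared: str | None) -> str:
    if declared:
        return declared
    try:
        vr = dictionary_VR(tag)
    except KeyError:
        raise TagMapError(f"tag {tag} is not in the DICOM dictionary; a vr attribute is required")
    return vr.split(" ")[0]  # ambiguous entries like "US or SS" -> first


def _parse_params(raw: str | None) -> list[str]:
    if not raw:
        return []
    # tag:GGGG,EEEE contains a comma, so split on commas *not* following "tag:GGGG"
    parts: list[str] = []
    for piece in raw.split(","):
        piece = piece.strip()
        if parts and re.fullmatch(r"tag:[0-9A-Fa-f]{4}", parts[-1]):
            parts[-1] = f"{parts[-1]},{piece}"
        else:
            parts.append(piece)
    for p in parts:
        if not (p == "item" or p.startswith("input:") or re.fullmatch(r"tag:[0-9A-Fa-f]{4},[0-9A-Fa-f]{4}", p)):
            raise TagMapError(f"bad params source {p!r}")
    return parts


def _parse_attr(elem: etree._Element) -> TagEntry:
    tag = _parse_tag(elem.get("tag", ""))
    vr = _infer_vr(tag, elem.get("vr"))
    count_source = elem.get("count")
    params = _parse_params(elem.get("params"))

    if vr == "SQ":
        items = [c for c in elem if c.tag == "item"]
        if len(items) != 1:
            raise TagMapError(f"sequence {tag} must carry exactly one <item> template, found {len(items)}")
        children = _parse_level(items[0])
        return TagEntry(tag=tag, vr=vr, kind="literal", payload="", children=children,
                        count_source=count_source, params=params)

    payload = (elem.text or "").strip()
    kind = _classify(payload, elem.get("src"))
    return TagEntry(tag=tag, vr=vr, kind=kind, payload=payload,
                    count_source=count_source, params=params)


def _parse_level(parent: etree._Element) -> list[TagEntry]:
    entries: list[TagEntry] = []
    seen: set[Tag] = set()
    for child in parent:
        if not isinstance(child.tag, str) or child.tag != "attr":
            continue  # comments and foreign elements are ignored
        entry = _parse_attr(child)
        if entry.tag in seen:
            raise TagMapError(f"duplicate tag {entry.tag} at one nesting level")
        seen.add(entry.tag)
        entries.append(entry)
    return entries


def parse_tagmap(xml_text: str | bytes) -> TagMap:
    """Parse a TagMap document; entry order is preserved exactly."""
    try:
        root = etree.fromstring(xml_text.encode() if isinstance(xml_text, str) else xml_text)
    except etree.XMLSyntaxError as exc:
        raise TagMapError(f"not well-formed XML: {exc}") from exc
    if root.tag != "dicom":
        raise TagMapError(f"root element is <{root.tag}>, expected <dicom>")
    target = root.get("type", "RTRECORD")
    if target not in TARGET_TYPES:
        raise TagMapError(f"unknown target type {target!r}")
    scope_raw = root.get("version_scope", "V3 V4_0 V4_2PLUS").split()
    try:
        scope = frozenset(StorageVersion[s] for s in scope_raw)
    except KeyError as exc:
        raise TagMapError(f"unknown storage version in version_scope: {exc}") from exc
    return TagMap(target_type=target, version_scope=scope, entries=_parse_level(root))


# ---------------------------------------------------------------------------
# skeleton


@dataclass
class SkeletonElement:
    entry: TagEntry
    value: Any = None  # final value once resolved
    resolved: bool = False
    items: list[list["SkeletonElement"]] | None = None  # expanded SQ items


@dataclass
class DicomObjectSpec:
    """A DICOM dataset under construction.

    Starts as a query-bearing skeleton; after :func:`evaluate` every element
    is either resolved or recorded in ``failures``.  ``complete`` is False
    exactly when a Type-1 tag failed.
    """

    target_type: str
    elements: list[SkeletonElement]
    failures: list[tuple[Tag, str]] = field(default_factory=list)
    warnings: list[tuple[Tag, str]] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return not self.failures

    def element(self, tag: Tag | int) -> SkeletonElement:
        tag = Tag(tag)
        for el in self.elements:
            if el.entry.tag == tag:
                return el
        raise KeyError(f"tag {tag} not in spec")

    def to_dataset(self) -> Dataset:
        """Materialise the resolved elements as a pydicom Dataset.

        Unresolved placeholders and blob references are skipped; builders
        attach transformed payloads afterwards.
        """
        return _to_dataset(self.elements)


def _to_dataset(elements: list[SkeletonElement]) -> Dataset:
    ds = Dataset()
    for el in sorted(elements, key=lambda e: e.entry.tag):
        tag, vr = el.entry.tag, el.entry.vr
        if vr == "SQ":
            seq = [_to_dataset(item) for item in (el.items or [])]
            ds.add_new(tag, "SQ", Sequence(seq))
        elif el.resolved and not isinstance(el.value, BlobRef):
            ds.add_new(tag, vr, el.value)
    return ds


def build_skeleton(tagmap: TagMap) -> DicomObjectSpec:
    """Build the query-bearing skeleton: literals final, queries placeholders."""

    def make(entries: list[TagEntry]) -> list[SkeletonElement]:
        out = []
        for e in entries:
            el = SkeletonElement(entry=e)
            if e.vr == "SQ":
                el.items = None  # expanded during evaluation
            elif e.kind == "literal":
                el.value = coerce_value(e.vr, [e.payload] if e.payload != "" else [])
                el.resolved = True
            out.append(el)
        return out

    return DicomObjectSpec(target_type=tagmap.target_type, elements=make(tagmap.entries))


def expand_sequence(entry: TagEntry, count: int) -> list[list[SkeletonElement]]:
    """Expand a sequence template into ``count`` items.

    Each item is a deep copy of the single template item; queries inside
    item number i see the 1-based index through ``$i`` / the ``item``
    parameter source.
    """
    if entry.vr != "SQ":
        raise EvaluationError(f"{entry.tag} is not a sequence")
    if count < 0:
        raise EvaluationError(f"sequence {entry.tag}: negative item count {count}")

    def make(entries: list[TagEntry]) -> list[SkeletonElement]:
        out = []
        for e in entries:
            el = SkeletonElement(entry=copy.deepcopy(e))
            if e.vr != "SQ" and e.kind == "literal":
                el.value = coerce_value(e.vr, [e.payload] if e.payload != "" else [])
                el.resolved = True
            out.append(el)
        return out

    return [make(entry.children) for _ in range(count)]


# ---------------------------------------------------------------------------
# VR coercion


def _iso_date(value: str) -> str:
    return value.split("T")[0].replace("-", "")


def _iso_time(value: str) -> str:
    part = value.split("T")[1] if "T" in value else value
    return part.replace(":", "").split(".")[0]


def coerce_value(vr: str, atoms: list) -> Any:
    """Coerce backend-returned atoms to a value pydicom accepts for ``vr``.

    Multi-column person names follow the (given, family) -> "family^given"
    composition rule; dates and times accept ISO-8601 input.
    """
    atoms = [a for a in atoms]
    if vr in _BINARY_VRS:
        if len(atoms) == 1 and isinstance(atoms[0], (bytes, bytearray)):
            return bytes(atoms[0])
        raise EvaluationError(f"VR {vr} needs raw bytes")
    strs = [str(a) for a in atoms]
    try:
        if vr == "PN":
            if len(strs) == 2:  # (first, last) columns -> LAST^FIRST
                return f"{strs[1]}^{strs[0]}"
            return strs[0] if strs else ""
        if vr == "DA":
            return [_iso_date(s) for s in strs] if len(strs) > 1 else _iso_date(strs[0])
        if vr == "TM":
            return [_iso_time(s) for s in strs] if len(strs) > 1 else _iso_time(strs[0])
        if vr == "DT":
            return "".join(c for c in strs[0] if c.isdigit())
        if vr in ("IS", "US", "UL", "SS", "SL"):
            vals = [int(float(s)) for s in strs]
            return vals if len(vals) > 1 else vals[0]
        if vr in ("FL", "FD"):
            vals = [float(s) for s in strs]
            return vals if len(vals) > 1 else vals[0]
        if vr == "DS":
            flat: list[str] = []
            for s in strs:
                flat.extend(p for p in re.split(r"[\\\s]+", s) if p)
            vals = [format(float(p), "g") for p in flat]
            return vals if len(vals) > 1 else vals[0]
        # text-ish VRs (UI, LO, SH, CS, ST, LT, AE, AS ...)
        if len(strs) > 1:
            return strs
        return strs[0] if strs else ""
    except (ValueError, IndexError) as exc:
        raise EvaluationError(f"cannot coerce {strs!r} to VR {vr}: {exc}") from exc


# ---------------------------------------------------------------------------
# backends


def _tag_var_name(tag: Tag) -> str:
    return f"t{tag.group:04X}{tag.element:04X}"


class XPathBackend:
    """Evaluates XPath queries against one tomo-lite master document.

    Queries see every user input as an XPath variable of the same name, the
    current sequence item index as ``$i``, and every already-resolved
    top-level element as ``$tGGGGEEEE``.  The supported language is lxml's
    XPath 1.0 path/predicate subset (paths, predicates, ``count()``,
    ``text()``, variables); anything it rejects raises
    :class:`EvaluationError` naming the expression — the engine never
    silently skips an unsupported construct.
    """

    kind = "XPATH"

    def __init__(self, document: etree._ElementTree):
        self.document = document

    def evaluate(self, query: str, params: list[str], ctx: BindingContext, item_index: int = 1) -> list:
        variables: dict[str, Any] = {k: str(v) for k, v in ctx.user_inputs.items()}
        variables["i"] = item_index
        for tag, value in ctx.resolved.items():
            if isinstance(value, (str, int, float)):
                variables[_tag_var_name(tag)] = value if isinstance(value, (int, float)) else str(value)
        try:
            result = self.document.xpath(query, **variables)
        except etree.XPathError as exc:
            raise EvaluationError(f"XPath evaluation failed for {query!r}: {exc}") from exc
        if isinstance(result, (str, float, bool, int)):
            return [result]
        out = []
        for node in result:
            if isinstance(node, str):
                out.append(node.strip())
            elif hasattr(node, "text"):
                out.append((node.text or "").strip())
            else:
                out.append(node)
        return out


class SQLBackend:
    """Evaluates SQL queries with positional ``?`` binding over sqlite3.

    ``params`` sources are resolved in order: ``input:<name>`` from the
    binding context's user inputs, ``tag:GGGG,EEEE`` from an element already
    evaluated earlier in the TagMap (staged evaluation), ``item`` from the
    current sequence item index.
    """

    kind = "SQL"

    def __init__(self, connection: sqlite3.Connection):
        self.connection = connection

    @classmethod
    def from_script(cls, sql_text: str) -> "SQLBackend":
        conn = sqlite3.connect(":memory:")
        conn.executescript(sql_text)
        return cls(conn)

    def _bindings(self, params: list[str], ctx: BindingContext, item_index: int) -> list:
        values = []
        for p in params:
            if p == "item":
                values.append(item_index)
            elif p.startswith("input:"):
                name = p[len("input:"):]
                if name not in ctx.user_inputs:
                    raise EvaluationError(f"no user input named {name!r}")
                values.append(ctx.user_inputs[name])
            else:  # tag:GGGG,EEEE
                g, e = p[len("tag:"):].split(",")
                tag = Tag(int(g, 16), int(e, 16))
                if tag not in ctx.resolved:
                    raise EvaluationError(f"parameter {p}: tag {tag} not yet evaluated")
                values.append(ctx.resolved[tag])
        return values

    def evaluate(self, query: str, params: list[str], ctx: BindingContext, item_index: int = 1) -> list:
        n_placeholders = query.count("?")
        if n_placeholders != len(params):
            raise EvaluationError(
                f"query has {n_placeholders} '?' placeholders but {len(params)} params: {query!r}"
            )
        bindings = self._bindings(params, ctx, item_index)
        try:
            rows = self.connection.execute(query, bindings).fetchall()
        except sqlite3.Error as exc:
            raise EvaluationError(f"SQL error for {query!r}: {exc}") from exc
        if not rows:
            return []
        if len(rows) > 1:
            raise EvaluationError(f"query returned {len(rows)} rows where one was expected: {query!r}")
        return [v for v in rows[0] if v is not None]


def evaluate_sql(query: str, bindings: list, backend: SQLBackend) -> list:
    """Run one positionally-bound SQL query and return the single row's values."""
    ctx = BindingContext(user_inputs={f"b{i}": v for i, v in enumerate(bindings)})
    params = [f"input:b{i}" for i in range(len(bindings))]
    return backend.evaluate(query, params, ctx)


# ---------------------------------------------------------------------------
# evaluation


def _eval_count(entry: TagEntry, backend, ctx: BindingContext, item_index: int) -> int:
    if entry.count_source is None:
        return 1
    result = backend.evaluate(entry.count_source, entry.params, ctx, item_index)
    if not result:
        raise EvaluationError(f"sequence {entry.tag}: count query returned nothing")
    value = result[0]
    count = int(float(value))
    if count < 0:
        raise EvaluationError(f"sequence {entry.tag}: negative count {count}")
    return count


def evaluate(
    skeleton: DicomObjectSpec,
    backend,
    ctx: BindingContext,
    blob_uids: set[str] | None = None,
) -> DicomObjectSpec:
    """Resolve every placeholder in document order.

    A query on an element with a binary VR (OB/OW/OF/UN) must return the
    UID of a raw payload; the element is then marked with a
    :class:`BlobRef` for the builders to attach the transformed bytes.
    ``blob_uids``, when given, is the set of UIDs known to name binary
    payloads and is used to validate such references.

    Failures on Type-1 tags mark the spec INCOMPLETE (recorded, never
    silently empty); anything else is a logged warning.
    """
    type1 = TYPE1_TAGS.get(skeleton.target_type, frozenset())

    def record_missing(tag: Tag, message: str) -> None:
        if tag in type1:
            skeleton.failures.append((tag, message))
        else:
            skeleton.warnings.append((tag, message))

    def walk(elements: list[SkeletonElement], item_index: int, top_level: bool) -> None:
        for el in elements:
            entry = el.entry
            if entry.vr == "SQ":
                try:
                    count = _eval_count(entry, backend, ctx, item_index)
                    el.items = expand_sequence(entry, count)
                except EvaluationError as exc:
                    record_missing(entry.tag, str(exc))
                    el.items = []
                    continue
                if entry.count_source is None:
                    # an uncounted sequence inherits the enclosing item index,
                    # so nested templates can keep addressing the outer $i
                    for item in el.items:
                        walk(item, item_index, top_level=False)
                else:
                    for i, item in enumerate(el.items, start=1):
                        walk(item, i, top_level=False)
                continue
            if el.resolved:  # literal, already final
                if top_level:
                    ctx.resolved[entry.tag] = el.value
                continue
            try:
                atoms = backend.evaluate(entry.payload, entry.params, ctx, item_index)
            except EvaluationError as exc:
                record_missing(entry.tag, str(exc))
                continue
            if not atoms:
                record_missing(entry.tag, f"query returned no result: {entry.payload!r}")
                continue
            if entry.vr in _BINARY_VRS:
                uid = str(atoms[0])
                if blob_uids is not None and uid not in blob_uids:
                    record_missing(entry.tag, f"no binary payload for UID {uid!r}")
                    continue
                el.value = BlobRef(uid)
                el.resolved = True
                continue
            try:
                el.value = coerce_value(entry.vr, atoms)
            except EvaluationError as exc:
                record_missing(entry.tag, str(exc))
                continue
            el.resolved = True
            if top_level:
                ctx.resolved[entry.tag] = el.value

    walk(skeleton.elements, item_index=1, top_level=True)
    return skeleton
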