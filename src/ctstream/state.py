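"""Hierarchical state model with diff-only synchronization.

View and session state live in a tree of slash-separated paths with typed
leaves (number, string, boolean). Only differences between revisions ever
cross the wire: :func:`compute_diff` produces the minimal set of upserts
and deletes, :func:`apply_diff` replays it against a tree at the matching
base revision, and the diff serializes to a small XML document (JSON is a
drop-in alternative for the wire). A server-side :class:`SyncHub`
serializes client mutations in arrival order (last-writer-wins per path)
and rebroadcasts diffs so every client converges to the server tree.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

from .errors import DiffParseError, StaleDiffError, UnknownPathError

LeafValue = float | int | str | bool


def _check_paths(paths) -> None:
    """No leaf may also be an interior node."""
    pset = set(paths)
    for p in pset:
        parts = p.split("/")
        for i in range(1, len(parts)):
            if "/".join(parts[:i]) in pset:
                raise ValueError(
                    f"path {'/'.join(parts[:i])!r} is both leaf and interior node"
                )


@dataclass
class StateModel:
    """Tree of path -> typed leaf value with a monotone revision counter."""

    leaves: dict[str, LeafValue] = field(default_factory=dict)
    revision: int = 0

    def __post_init__(self):
        _check_paths(self.leaves)

    def set(self, path: str, value: LeafValue) -> None:
        _check_paths(list(self.leaves) + [path])
        self.leaves[path] = value
        self.revision += 1

    def get(self, path: str, default=None):
        return self.leaves.get(path, default)

    def delete(self, path: str) -> None:
        if path not in self.leaves:
            raise UnknownPathError(f"unknown path {path!r}")
        del self.leaves[path]
        self.revision += 1

    def copy(self) -> "StateModel":
        return StateModel(leaves=dict(self.leaves), revision=self.revision)

    def __eq__(self, other):
        return (
            isinstance(other, StateModel)
            and self.leaves == other.leaves
        )


@dataclass
class StateDiff:
    """Minimal difference between two state revisions."""

    upserts: list[tuple[str, LeafValue]] = field(default_factory=list)
    deletes: list[str] = field(default_factory=list)
    base_revision: int = 0
    new_revision: int = 1

    def __post_init__(self):
        up = {p for p, _ in self.upserts}
        if up & set(self.deletes):
            raise ValueError("upsert and delete path sets must be disjoint")
        if self.new_revision <= self.base_revision:
            raise ValueError("new_revision must exceed base_revision")

    @property
    def empty(self) -> bool:
        return not self.upserts and not self.deletes


def compute_diff(old: StateModel, new: StateModel) -> StateDiff:
    """Upserts for changed or added paths, deletes for removed ones.

    Never emits an upsert whose value (and type) equals the old value, so
    ``compute_diff(T, T)`` is empty.
    """
    upserts = [
        (p, v)
        for p, v in sorted(new.leaves.items())
        if p not in old.leaves
        or old.leaves[p] != v
        or type(old.leaves[p]) is not type(v)
    ]
    deletes = sorted(p for p in old.leaves if p not in new.leaves)
    return StateDiff(
        upserts=upserts,
        deletes=deletes,
        base_revision=old.revision,
        new_revision=max(new.revision, old.revision + 1),
    )


def apply_diff(tree: StateModel, diff: StateDiff) -> StateModel:
    """Replay a diff; the tree must be at the diff's base revision.

    A stale base revision raises :class:`StaleDiffError` — the caller is
    expected to request a full resync rather than merge.
    """
    if tree.revision != diff.base_revision:
        raise StaleDiffError(
            f"stale diff: base revision {diff.base_revision} != "
            f"tree revision {tree.revision}"
        )
    out = tree.copy()
    for path in diff.deletes:
        if path not in out.leaves:
            raise UnknownPathError(f"unknown path {path!r}")
        del out.leaves[path]
    for path, value in diff.upserts:
        out.leaves[path] = value
    _check_paths(out.leaves)
    out.revision = diff.new_revision
    return out


def full_resync_diff(server: StateModel, client_revision: int) -> StateDiff:
    """A keyframe diff: applied to any tree at client_revision, yields server."""
    return StateDiff(
        upserts=sorted(server.leaves.items()),
        deletes=[],
        base_revision=client_revision,
        new_revision=max(server.revision, client_revision + 1),
    )


def apply_resync(tree: StateModel, diff: StateDiff) -> StateModel:
    """Apply a full-state keyframe diff: existing leaves are discarded."""
    out = StateModel(leaves=dict(diff.upserts), revision=diff.new_revision)
    return out


# ---------------------------------------------------------------------------
# XML serialization
# ---------------------------------------------------------------------------

_TYPE_NAMES = {bool: "boolean", int: "number", float: "number", str: "string"}


def _encode_value(v: LeafValue) -> tuple[str, str]:
    if isinstance(v, bool):
        return "boolean", "true" if v else "false"
    if isinstance(v, (int, float)):
        return "number", repr(v)
    return "string", v


def _decode_value(type_name: str, text: str) -> LeafValue:
    if type_name == "boolean":
        if text not in ("true", "false"):
            raise DiffParseError(f"bad boolean literal {text!r}")
        return text == "true"
    if type_name == "number":
        try:
            f = float(text)
        except ValueError as exc:
            raise DiffParseError(f"bad number literal {text!r}") from exc
        return int(f) if f.is_integer() and "." not in text and "e" not in text.lower() else f
    if type_name == "string":
        return text
    raise DiffParseError(f"unknown leaf type {type_name!r}")


def serialize_diff(diff: StateDiff) -> str:
    """Serialize a diff to the XML document schema shipped in docs/."""
    root = ET.Element(
        "statediff",
        base=str(diff.base_revision),
        new=str(diff.new_revision),
    )
    for path, value in diff.upserts:
        tname, text = _encode_value(value)
        el = ET.SubElement(root, "set", path=path, type=tname)
        el.text = text
    for path in diff.deletes:
        ET.SubElement(root, "del", path=path)
    return ET.tostring(root, encoding="unicode")


def parse_diff(document: str) -> StateDiff:
    """Parse a diff document; malformed input raises DiffParseError."""
    try:
        root = ET.fromstring(document)
    except ET.ParseError as exc:
        line = exc.position[0] if exc.position else None
        raise DiffParseError(str(exc), line=line) from exc
    if root.tag != "statediff":
        raise DiffParseError(f"unexpected root element {root.tag!r}")
    try:
        base = int(root.attrib["base"])
        new = int(root.attrib["new"])
    except (KeyError, ValueError) as exc:
        raise DiffParseError("missing or bad revision attributes") from exc
    upserts: list[tuple[str, LeafValue]] = []
    deletes: list[str] = []
    for el in root:
        if el.tag == "set":
            if "path" not in el.attrib or "type" not in el.attrib:
                raise DiffParseError("set element missing path/type")
            upserts.append(
                (el.attrib["path"], _decode_value(el.attrib["type"], el.text or ""))
            )
        elif el.tag == "del":
            if "path" not in el.attrib:
                raise DiffParseError("del element missing path")
            deletes.append(el.attrib["path"])
        else:
            raise DiffParseError(f"unexpected element {el.tag!r}")
    try:
        return StateDiff(upserts=upserts, deletes=deletes,
                         base_revision=base, new_revision=new)
    except ValueError as exc:
        raise DiffParseError(str(exc)) from exc


# ---------------------------------------------------------------------------
# server-side synchronization hub
# ---------------------------------------------------------------------------

class SyncHub:
    """Serializes mutations and rebroadcasts diffs to attached clients.

    Conflict policy is last-writer-wins per path in server arrival order;
    no operational transforms. Multiple hubs namespaced by server id model
    one client attached to several servers.
    """

    def __init__(self):
        self.tree = StateModel()
        self._clients: dict[str, StateModel] = {}
        self.outbox: dict[str, list[StateDiff]] = {}

    def attach(self, client_id: str) -> StateDiff:
        """Register a client; returns the full-state keyframe diff."""
        self._clients[client_id] = StateModel()
        self.outbox[client_id] = []
        return full_resync_diff(self.tree, 0)

    def submit(self, client_id: str, mutations: dict[str, LeafValue],
               deletes: tuple[str, ...] = ()) -> StateDiff:
        """Apply one client's mutation batch and queue the rebroadcast."""
        old = self.tree.copy()
        for path in deletes:
            self.tree.delete(path)
        for path, value in mutations.items():
            self.tree.set(path, value)
        diff = compute_diff(old, self.tree)
        for cid in self.outbox:
            self.outbox[cid].append(diff)
        return diff

    def deliver_all(self) -> None:
        """Flush queued diffs to every client's shadow tree."""
        for cid, queue in self.outbox.items():
            shadow = self._clients[cid]
            for diff in queue:
                try:
                    shadow = apply_diff(shadow, diff)
                except StaleDiffError:
                    shadow = apply_resync(
                        shadow, full_resync_diff(self.tree, shadow.revision)
                    )
            self._clients[cid] = shadow
            queue.clear()

    def client_tree(self, client_id: str) -> StateModel:
        return self._clients[client_id]
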