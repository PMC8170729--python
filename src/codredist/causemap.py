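"""Cause hierarchy, ICD-style code mapping, and garbage-code classification.

The cause list is a levelled tree: level 0 is the all-cause root, level 1
holds the three broad groupings (communicable/maternal/neonatal/nutritional,
non-communicable, injuries), and levels 2-4 hold increasingly detailed
causes.  Every raw code either resolves to a valid underlying cause or to a
*garbage group* -- a set of diagnostically related codes that cannot serve
as an underlying cause of death and must be redistributed.

Garbage groups carry a specificity class:

* class 1 -- plausible targets span two or more level-1 causes
* class 2 -- targets within a single level-1 cause
* class 3 -- targets within a single level-2 cause
* class 4 -- targets within a single level-3 cause (e.g. stroke subtypes)

Classes 1 and 2 together are "major garbage".
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "CauseNode",
    "CauseHierarchy",
    "GarbageGroup",
    "Resolution",
    "normalize_code",
    "load_hierarchy",
    "write_hierarchy",
    "load_garbage_groups",
    "write_garbage_groups",
    "resolve_code",
    "infer_class",
    "validate_group_classes",
    "MAJOR_CLASSES",
]

MAJOR_CLASSES = frozenset({1, 2})

VALID_METHODS = {"multiple_cause", "negative_correlation", "impairment", "proportional"}


@dataclass(frozen=True)
class CauseNode:
    cause_id: str
    name: str
    level: int
    parent_id: str | None
    is_yll_cause: bool


@dataclass(frozen=True)
class Resolution:
    """Destination of a raw code: a valid cause or a garbage group."""

    kind: str  # "cause" | "garbage"
    dest: str

    @property
    def is_garbage(self) -> bool:
        return self.kind == "garbage"


class HierarchyError(ValueError):
    pass


class MappingError(ValueError):
    pass


def normalize_code(code: str) -> str:
    """Canonical code dialect: uppercase, no dots or surrounding space."""
    return code.strip().upper().replace(".", "")


@dataclass
class CauseHierarchy:
    nodes: dict[str, CauseNode]
    code_map: dict[str, Resolution] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        roots = [n for n in self.nodes.values() if n.level == 0]
        if len(roots) != 1:
            raise HierarchyError(f"expected exactly one level-0 root, found {len(roots)}")
        if roots[0].parent_id is not None:
            raise HierarchyError("root node must have no parent")
        for n in self.nodes.values():
            if n.level == 0:
                continue
            if n.parent_id not in self.nodes:
                raise HierarchyError(f"node {n.cause_id!r} has unknown parent {n.parent_id!r}")
            parent = self.nodes[n.parent_id]
            if parent.level != n.level - 1:
                raise HierarchyError(
                    f"node {n.cause_id!r} at level {n.level} has parent at level {parent.level}"
                )

    @property
    def root(self) -> CauseNode:
        return next(n for n in self.nodes.values() if n.level == 0)

    def children(self, cause_id: str) -> list[CauseNode]:
        return [n for n in self.nodes.values() if n.parent_id == cause_id]

    def leaves(self) -> list[CauseNode]:
        parents = {n.parent_id for n in self.nodes.values()}
        return [n for n in self.nodes.values() if n.cause_id not in parents]

    def yll_causes(self) -> list[str]:
        return sorted(n.cause_id for n in self.nodes.values() if n.is_yll_cause)

    def ancestor_at_level(self, cause_id: str, level: int) -> str | None:
        """Ancestor of ``cause_id`` at ``level`` (the node itself if already there).

        Returns None when the node sits above the requested level.
        """
        node = self.nodes[cause_id]
        while node.level > level:
            node = self.nodes[node.parent_id]
        return node.cause_id if node.level == level else None

    # -- code mapping ------------------------------------------------------

    def add_code(self, code: str, kind: str, dest: str) -> None:
        norm = normalize_code(code)
        if norm in self.code_map:
            raise MappingError(f"code {code!r} mapped more than once")
        if kind == "cause":
            if dest not in self.nodes:
                raise MappingError(f"code {code!r} maps to unknown cause {dest!r}")
        elif kind != "garbage":
            raise MappingError(f"bad destination kind {kind!r} for code {code!r}")
        self.code_map[norm] = Resolution(kind, dest)


@dataclass
class GarbageGroup:
    group_id: str
    member_codes: set[str]
    garbage_class: int
    method: str
    target_causes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.member_codes:
            raise ValueError(f"garbage group {self.group_id!r} has no member codes")
        if self.garbage_class not in (1, 2, 3, 4):
            raise ValueError(f"garbage class must be 1-4, got {self.garbage_class}")
        if self.method not in VALID_METHODS:
            raise ValueError(f"unknown method {self.method!r} for group {self.group_id!r}")
        self.member_codes = {normalize_code(c) for c in self.member_codes}

    @property
    def is_major(self) -> bool:
        return self.garbage_class in MAJOR_CLASSES


# ---------------------------------------------------------------------------
# operations


def resolve_code(
    code: str,
    hierarchy: CauseHierarchy,
    unknown: str = "error",
    residual_group: str = "_residual_garbage",
) -> Resolution:
    """Resolve a raw code to a cause or a garbage group.

    Lookup is dialect-normalised (uppercase, dots stripped); unmapped
    4-character codes fall back to their 3-character truncation, mirroring
    tabulation-list coarsening.  ``unknown`` selects the policy for codes
    absent from the map: ``"error"`` raises, ``"residual"`` maps to the
    designated residual garbage group.
    """
    if code.strip() in hierarchy.nodes:
        # already a cause identifier (post-mapping data)
        return Resolution("cause", code.strip())
    norm = normalize_code(code)
    res = hierarchy.code_map.get(norm)
    if res is None and len(norm) == 4:
        res = hierarchy.code_map.get(norm[:3])
    if res is None:
        if unknown == "residual":
            return Resolution("garbage", residual_group)
        raise MappingError(f"code {code!r} not present in the code map")
    return res


def infer_class(targets: Iterable[str], hierarchy: CauseHierarchy) -> int:
    """Garbage class implied by the span of a target-cause set.

    Classes grade specificity by the highest hierarchy level at which the
    targets still share a single ancestor: spanning several level-1 causes
    is class 1 (least specific); all targets under one level-3 cause is
    class 4 (most specific).
    """
    targets = list(targets)
    if not targets:
        raise ValueError("cannot classify an empty target set")
    for t in targets:
        if t not in hierarchy.nodes:
            raise ValueError(f"unknown target cause {t!r}")
    for level, klass in ((1, 1), (2, 2), (3, 3)):
        ancestors = {hierarchy.ancestor_at_level(t, level) for t in targets}
        if len(ancestors) > 1:
            return klass
    return 4


def validate_group_classes(
    groups: Iterable[GarbageGroup], hierarchy: CauseHierarchy
) -> dict[str, tuple[int, int]]:
    """Flag stored garbage classes inconsistent with ``infer_class``.

    Returns {group_id: (stored, derived)} for the inconsistent groups;
    groups with empirically derived (empty) target sets are skipped.
    """
    bad: dict[str, tuple[int, int]] = {}
    seen_codes: set[str] = set()
    for g in groups:
        overlap = seen_codes & g.member_codes
        if overlap:
            raise MappingError(f"member codes shared across groups: {sorted(overlap)}")
        seen_codes |= g.member_codes
        for t in g.target_causes:
            if not hierarchy.nodes[t].is_yll_cause:
                raise ValueError(
                    f"group {g.group_id!r} targets non-YLL cause {t!r}"
                )
        if g.target_causes:
            derived = infer_class(g.target_causes, hierarchy)
            if derived != g.garbage_class:
                bad[g.group_id] = (g.garbage_class, derived)
    return bad


# ---------------------------------------------------------------------------
# I/O  (cause-map CSV: cause_id,name,level,parent_id,is_yll_cause
#       code-map CSV:  code,destination_kind,destination_id
#       garbage CSV:   group_id,code,garbage_class,method,target_cause_id)


def load_hierarchy(cause_map_path, code_map_path=None) -> CauseHierarchy:
    nodes: dict[str, CauseNode] = {}
    with open(cause_map_path, newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.DictReader(fh), start=2):
            try:
                cid = row["cause_id"].strip()
                node = CauseNode(
                    cause_id=cid,
                    name=row["name"],
                    level=int(row["level"]),
                    parent_id=row["parent_id"].strip() or None,
                    is_yll_cause=row["is_yll_cause"].strip().lower() in ("1", "true", "yes"),
                )
            except (KeyError, ValueError) as exc:
                raise HierarchyError(f"{cause_map_path}: malformed row at line {lineno}: {exc}")
            if node.cause_id in nodes:
                raise HierarchyError(f"{cause_map_path}: duplicate cause_id {cid!r} at line {lineno}")
            nodes[node.cause_id] = node
    hier = CauseHierarchy(nodes)
    if code_map_path is not None:
        with open(code_map_path, newline="", encoding="utf-8") as fh:
            for lineno, row in enumerate(csv.DictReader(fh), start=2):
                try:
                    hier.add_code(row["code"], row["destination_kind"], row["destination_id"])
                except KeyError as exc:
                    raise MappingError(f"{code_map_path}: malformed row at line {lineno}: {exc}")
    return hier


def write_hierarchy(hierarchy: CauseHierarchy, cause_map_path, code_map_path=None) -> None:
    with open(cause_map_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["cause_id", "name", "level", "parent_id", "is_yll_cause"])
        for n in sorted(hierarchy.nodes.values(), key=lambda n: (n.level, n.cause_id)):
            w.writerow([n.cause_id, n.name, n.level, n.parent_id or "", str(n.is_yll_cause).lower()])
    if code_map_path is not None:
        with open(code_map_path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["code", "destination_kind", "destination_id"])
            for code, res in sorted(hierarchy.code_map.items()):
                w.writerow([code, res.kind, res.dest])


def load_garbage_groups(path, hierarchy: CauseHierarchy | None = None) -> dict[str, GarbageGroup]:
    rows: list[Mapping[str, str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    by_id: dict[str, dict] = {}
    for row in rows:
        gid = row["group_id"].strip()
        rec = by_id.setdefault(
            gid,
            {"codes": set(), "garbage_class": int(row["garbage_class"]), "method": row["method"].strip(), "targets": set()},
        )
        if row.get("code", "").strip():
            rec["codes"].add(row["code"].strip())
        if row.get("target_cause_id", "").strip():
            rec["targets"].add(row["target_cause_id"].strip())
    groups = {
        gid: GarbageGroup(gid, rec["codes"], rec["garbage_class"], rec["method"], rec["targets"])
        for gid, rec in by_id.items()
    }
    if hierarchy is not None:
        validate_group_classes(groups.values(), hierarchy)
    return groups


def write_garbage_groups(groups: Mapping[str, GarbageGroup], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["group_id", "code", "garbage_class", "method", "target_cause_id"])
        for gid in sorted(groups):
            g = groups[gid]
            targets = sorted(g.target_causes) or [""]
            codes = sorted(g.member_codes)
            # first row carries the first code; extra codes / targets get their own rows
            for i in range(max(len(codes), len(targets))):
                w.writerow([
                    gid,
                    codes[i] if i < len(codes) else "",
                    g.garbage_class,
                    g.method,
                    targets[i] if i < len(targets) else "",
                ])
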