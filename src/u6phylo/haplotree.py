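"""Haplogroup tree representation and motif-based haplotype classification.

Two classifiers are provided, matching the two kinds of data a U6 survey
produces:

* :func:`classify_profile` scores a haplotype (complete genome or any
  partial range) against every root-to-node path of a haplogroup tree.
  Only defining variants that fall inside the profile's covered range are
  scoreable, so an HVS-I fragment is never penalised for coding-region
  motifs it could not observe. The best node maximises
  ``matched - missing``; ties go to the deeper node, then the
  lexicographically smaller name.

* :func:`classify_hvr1` sorts a U6 HVS-I haplotype into the eight
  phylogeographic categories used for regional frequency tables, keyed on
  the diagnostic control-region positions (16169/16189 for U6c, 16311 with
  16261 or 16174 for U6d, 16311+16163 for U6b1, bare 16311 for U6b, and
  the 16189/16239/16235 splits within U6a). Each category carries the
  geographic component it predominantly traces (MAG Maghreb, EAF East
  Africa, COS cosmopolitan, CAN Canary Islands, MED Mediterranean).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator

from .mtvar import (
    HaplotypeProfile,
    Variant,
    format_variant,
    is_hypervariable,
    parse_variant,
)

__all__ = [
    "HaploNode",
    "HaploTree",
    "TreeLoadError",
    "ClassificationResult",
    "load_tree",
    "loads_tree",
    "default_tree",
    "classify_profile",
    "classify_hvr1",
    "classification_table",
    "CATEGORIES",
    "CATEGORY_GEO",
    "NOT_U6",
    "HVR1_DIAGNOSTIC_POSITIONS",
]

GEO_LABELS = frozenset({"MAG", "EAF", "COS", "CAN", "MED"})

#: The eight HVS-I categories, in frequency-table column order.
CATEGORIES = (
    "U6a without 235",
    "U6a 235",
    "U6a189 without 239",
    "U6a189 239",
    "U6b",
    "U6b1",
    "U6d",
    "U6c",
)

#: Geographic component of each category (frequency-table header row).
CATEGORY_GEO = {
    "U6a without 235": "MAG",
    "U6a 235": "MAG",
    "U6a189 without 239": "EAF",
    "U6a189 239": "MAG",
    "U6b": "COS",
    "U6b1": "CAN",
    "U6d": "MAG",
    "U6c": "MED",
}

NOT_U6 = "not-U6"

#: Control-region positions that split the eight categories.
HVR1_DIAGNOSTIC_POSITIONS = (16169, 16189, 16311, 16261, 16174, 16163, 16235, 16239)


class TreeLoadError(ValueError):
    """Raised on an invalid tree definition, listing the offenders."""


@dataclass
class HaploNode:
    """A named haplogroup with its defining-mutation list."""

    name: str
    defining_variants: tuple[Variant, ...]
    parent: "HaploNode | None" = None
    children: list["HaploNode"] = field(default_factory=list)
    geo_label: str | None = None

    @property
    def depth(self) -> int:
        d, n = 0, self
        while n.parent is not None:
            d, n = d + 1, n.parent
        return d

    def path(self) -> list["HaploNode"]:
        """Root-to-self node list."""
        out, n = [], self
        while n is not None:
            out.append(n)
            n = n.parent
        return out[::-1]

    def path_variants(self) -> list[Variant]:
        """Defining variants accumulated from the root down to this node."""
        out: list[Variant] = []
        for n in self.path():
            out.extend(n.defining_variants)
        return out


class HaploTree:
    """A rooted haplogroup tree with uniquely named nodes."""

    def __init__(self, root: HaploNode):
        self.root = root
        self._index: dict[str, HaploNode] = {}
        for node in self._walk(root):
            if node.name in self._index:
                raise TreeLoadError(f"duplicate node name {node.name!r}")
            self._index[node.name] = node

    @staticmethod
    def _walk(node: HaploNode) -> Iterator[HaploNode]:
        yield node
        for c in node.children:
            yield from HaploTree._walk(c)

    def __iter__(self) -> Iterator[HaploNode]:
        return self._walk(self.root)

    def __len__(self) -> int:
        return len(self._index)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __getitem__(self, name: str) -> HaploNode:
        return self._index[name]

    def names(self) -> list[str]:
        return list(self._index)

    def dumps(self) -> str:
        """Serialise to the tab-separated definition format (round-trips)."""
        lines = []
        for node in self:
            tokens = " ".join(format_variant(v) for v in node.defining_variants)
            fields = [node.name, node.parent.name if node.parent else "-", tokens]
            if node.geo_label:
                fields.append(node.geo_label)
            lines.append("\t".join(fields))
        return "\n".join(lines) + "\n"

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.dumps())


def loads_tree(text: str) -> HaploTree:
    """Parse a tree definition: ``name<TAB>parent<TAB>tokens[<TAB>geo]``.

    ``#`` starts a comment; the root line uses ``-`` as its parent. Errors
    (duplicate names, empty motif on a non-root node, unknown parents,
    cyclic links) are collected and reported together.
    """
    rows: list[tuple[int, str, str, tuple[Variant, ...], str | None]] = []
    errors: list[str] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) == 2:
            fields.append("")  # empty motif field; caught below for non-roots
        if len(fields) < 3:
            errors.append(f"line {lineno}: expected name<TAB>parent<TAB>tokens")
            continue
        name, parent = fields[0].strip(), fields[1].strip()
        geo = fields[3].strip() if len(fields) > 3 and fields[3].strip() else None
        if geo is not None and geo not in GEO_LABELS:
            errors.append(f"line {lineno}: unknown geographic label {geo!r}")
        if name in seen:
            errors.append(f"line {lineno}: duplicate node name {name!r}")
        seen.add(name)
        try:
            variants = tuple(parse_variant(t) for t in fields[2].split())
        except ValueError as exc:
            errors.append(f"line {lineno}: {exc}")
            continue
        if parent != "-" and not variants:
            errors.append(f"line {lineno}: non-root node {name!r} has no motif")
        rows.append((lineno, name, parent, variants, geo))

    nodes = {name: HaploNode(name, variants, geo_label=geo)
             for _, name, _, variants, geo in rows}
    root: HaploNode | None = None
    for lineno, name, parent, _, _ in rows:
        if parent == "-":
            if root is not None:
                errors.append(f"line {lineno}: second root {name!r}")
            root = nodes[name]
        elif parent not in nodes:
            errors.append(f"line {lineno}: unknown parent {parent!r} for {name!r}")
        else:
            nodes[name].parent = nodes[parent]
            nodes[parent].children.append(nodes[name])
    if root is None:
        errors.append("no root node (parent '-') found")
    elif not errors:
        # iterative, cycle-safe reachability check
        seen_ids: set[int] = set()
        stack = [root]
        while stack:
            n = stack.pop()
            if id(n) in seen_ids:
                errors.append("cyclic parent links detected")
                break
            seen_ids.add(id(n))
            stack.extend(n.children)
        else:
            if len(seen_ids) != len(nodes):
                errors.append("cyclic or disconnected parent links detected")
    if errors:
        raise TreeLoadError("; ".join(errors))
    assert root is not None
    return HaploTree(root)


def load_tree(path) -> HaploTree:
    with open(path) as fh:
        return loads_tree(fh.read())


def default_tree() -> HaploTree:
    """The shipped U6 haplogroup tree."""
    text = resources.files("u6phylo.data").joinpath("u6_tree.tsv").read_text()
    return loads_tree(text)


# ---------------------------------------------------------------------------
# full-tree classification

@dataclass
class ClassificationResult:
    """Outcome of scoring a profile against a haplogroup tree."""

    best_node: str
    matched: int
    missing: int
    extra_private: int
    score: int
    category8: str | None = None
    geo_label: str | None = None
    warning: bool = False
    sample_id: str | None = None


def classify_profile(
    profile: HaplotypeProfile,
    tree: HaploTree | None = None,
    *,
    include_hypervariable: bool = False,
) -> ClassificationResult:
    """Assign a haplotype to the best-supported named haplogroup.

    Every root-to-node path is scored as ``matched - missing`` over the
    defining variants that fall inside the profile's covered range
    (hypervariable sites skipped under the default policy). Back-mutation
    motifs (``750!``) count as matched only when the profile carries the
    explicit ``!`` token. Deterministic tie-break: higher score, then
    greater depth, then lexicographically smaller name.

    A profile whose range contains no scoreable defining position of any
    node is returned as the root with ``warning=True``.
    """
    if tree is None:
        tree = default_tree()
    if not profile.covered_range:
        raise ValueError("profile has an empty covered range")

    def scoreable(v: Variant) -> bool:
        if not profile.covers(v.position):
            return False
        return include_hypervariable or not is_hypervariable(v)

    best: tuple[int, int, str] | None = None  # (score, depth, name)
    best_node: HaploNode = tree.root
    best_counts = (0, 0)
    any_scoreable = False
    for node in tree:
        path = node.path_variants()
        sc = [v for v in path if scoreable(v)]
        any_scoreable = any_scoreable or bool(sc)
        matched = sum(v in profile.variants for v in sc)
        missing = len(sc) - matched
        score = matched - missing
        key = (score, node.depth, node.name)
        if best is None or (key[0], key[1]) > (best[0], best[1]) or (
            (key[0], key[1]) == (best[0], best[1]) and key[2] < best[2]
        ):
            best, best_node, best_counts = key, node, (matched, missing)

    if not any_scoreable:
        return ClassificationResult(
            tree.root.name, 0, 0, len(profile.variants), 0,
            warning=True, sample_id=profile.sample_id,
            geo_label=tree.root.geo_label,
        )

    path_set = set(best_node.path_variants())
    extra = sum(
        1
        for v in profile.variants
        if v not in path_set
        and (include_hypervariable or not is_hypervariable(v))
        and not v.heteroplasmic
    )
    return ClassificationResult(
        best_node.name,
        best_counts[0],
        best_counts[1],
        extra,
        best[0] if best else 0,
        geo_label=best_node.geo_label,
        sample_id=profile.sample_id,
    )


# ---------------------------------------------------------------------------
# HVS-I eight-way categorisation

def classify_hvr1(profile: HaplotypeProfile) -> tuple[str, str | None]:
    """Sort a U6 HVS-I haplotype into one of the eight table categories.

    Requires the basal U6 control-region motif (16172 and 16219) to be
    present; otherwise returns ``(NOT_U6, None)``. The decision tree is
    exhaustive and mutually exclusive: U6c on 16169+16189; U6d on 16311
    together with 16261 or 16174; U6b1 on 16311+16163; U6b on bare 16311;
    then the U6a splits on 16189/16239/16235. Haplotypes carrying 16311
    without a U6d subgroup marker are binned as U6b.
    """
    pos = {
        v.position
        for v in profile.variants
        if not v.heteroplasmic and v.kind.value != "back_mutation"
    }
    if not {16172, 16219} <= pos:
        return NOT_U6, None
    if {16169, 16189} <= pos:
        cat = "U6c"
    elif 16311 in pos and (16261 in pos or 16174 in pos):
        cat = "U6d"
    elif {16311, 16163} <= pos:
        cat = "U6b1"
    elif 16311 in pos:
        cat = "U6b"
    elif {16189, 16239} <= pos:
        cat = "U6a189 239"
    elif 16189 in pos:
        cat = "U6a189 without 239"
    elif 16235 in pos:
        cat = "U6a 235"
    else:
        cat = "U6a without 235"
    return cat, CATEGORY_GEO[cat]


def classification_table(
    profiles: Iterable[HaplotypeProfile],
    tree: HaploTree | None = None,
    *,
    hvr1: bool = False,
):
    """Classify profiles and return a pandas DataFrame (CSV-ready).

    Columns: sample_id, best_node, matched, missing, extra_private,
    category8, geo_label.
    """
    import pandas as pd

    if tree is None:
        tree = default_tree()
    rows = []
    for i, p in enumerate(profiles, 1):
        res = classify_profile(p, tree)
        cat, geo = classify_hvr1(p) if hvr1 else (None, res.geo_label)
        rows.append(
            {
                "sample_id": p.sample_id or f"S{i}",
                "best_node": res.best_node,
                "matched": res.matched,
                "missing": res.missing,
                "extra_private": res.extra_private,
                "category8": cat,
                "geo_label": geo if not hvr1 else geo,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "best_node",
            "matched",
            "missing",
            "extra_private",
            "category8",
            "geo_label",
        ],
    )
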