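"""File formats: profile tables, tree bundles, Newick topologies.

Profiles travel as tab-separated text — one row per sample, the identifier
first and then the n copy counts — with ``#`` comment lines. A solved tree
is written as a small bundle of TSV files (edges, vertex profiles, events)
plus the leaf topology in standard Newick.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

from .core import CopyNumberTree, Profile, sequence_cost

__all__ = ["ProfileTable", "read_profiles", "write_profiles",
           "write_tree_bundle", "to_newick"]


@dataclass
class ProfileTable:
    """Ordered sample identifiers with their equal-length profiles."""

    ids: tuple[str, ...]
    profiles: tuple[Profile, ...]

    def __getitem__(self, sample_id: str) -> Profile:
        try:
            return self.profiles[self.ids.index(sample_id)]
        except ValueError:
            raise KeyError(f"no sample {sample_id!r}") from None


def read_profiles(path: str | os.PathLike) -> ProfileTable:
    """Parse a profile TSV; errors carry the offending line number."""
    ids: list[str] = []
    profiles: list[Profile] = []
    n = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: need an id and at least one value")
            sid = fields[0]
            if sid in ids:
                raise ValueError(f"{path}:{lineno}: duplicate identifier {sid!r}")
            try:
                values = tuple(int(x) for x in fields[1:])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer copy number") from None
            if any(v < 0 for v in values):
                raise ValueError(f"{path}:{lineno}: negative copy number")
            if n is None:
                n = len(values)
            elif len(values) != n:
                raise ValueError(
                    f"{path}:{lineno}: row has {len(values)} values, expected {n}"
                )
            ids.append(sid)
            profiles.append(values)
    if not ids:
        raise ValueError(f"{path}: no profiles found")
    return ProfileTable(tuple(ids), tuple(profiles))


def write_profiles(table: ProfileTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for sid, prof in zip(table.ids, table.profiles):
            fh.write(sid + "\t" + "\t".join(str(v) for v in prof) + "\n")


def _vertex_name(tree: CopyNumberTree, v: int) -> str:
    if v in tree.leaf_labels:
        return tree.leaf_labels[v]
    return "root" if v == tree.root else f"v{v}"


def to_newick(tree: CopyNumberTree, drop_auxiliary: bool = True) -> str:
    """Leaf topology as Newick (leaf names only, internal nodes unlabeled)."""

    def build(v) -> str | None:
        kids = tree.children.get(v, ())
        if not kids:
            if drop_auxiliary and v in tree.auxiliary_leaves:
                return None
            return tree.leaf_labels.get(v, str(v))
        parts = [p for p in (build(c) for c in kids) if p is not None]
        if not parts:
            return None
        if len(parts) == 1:
            return parts[0]
        return "(" + ",".join(parts) + ")"

    body = build(tree.root)
    if body is None:
        raise ValueError("tree has no non-auxiliary leaves")
    return body + ";"


def write_tree_bundle(tree: CopyNumberTree, prefix: str | os.PathLike) -> list[str]:
    """Write ``<prefix>.edges.tsv``, ``.profiles.tsv``, ``.events.tsv``, ``.nwk``."""
    prefix = os.fspath(prefix)
    paths = []

    path = prefix + ".edges.tsv"
    with open(path, "w") as fh:
        fh.write("# parent\tchild\tcost\n")
        for (u, v) in tree.edges():
            fh.write(
                f"{_vertex_name(tree, u)}\t{_vertex_name(tree, v)}\t"
                f"{sequence_cost(tree.events.get((u, v), ()))}\n"
            )
    paths.append(path)

    path = prefix + ".profiles.tsv"
    with open(path, "w") as fh:
        for v in sorted(tree.profiles):
            fh.write(
                _vertex_name(tree, v) + "\t"
                + "\t".join(str(x) for x in tree.profiles[v]) + "\n"
            )
    paths.append(path)

    path = prefix + ".events.tsv"
    with open(path, "w") as fh:
        fh.write("# parent\tchild\torder\ts\tt\tb\n")
        for (u, v) in tree.edges():
            for order, ev in enumerate(tree.events.get((u, v), ()), start=1):
                fh.write(
                    f"{_vertex_name(tree, u)}\t{_vertex_name(tree, v)}\t"
                    f"{order}\t{ev.s}\t{ev.t}\t{ev.b}\n"
                )
    paths.append(path)

    path = prefix + ".nwk"
    with open(path, "w") as fh:
        fh.write(to_newick(tree) + "\n")
    paths.append(path)
    return paths
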