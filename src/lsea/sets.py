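"""Lipid-set collections: biological process -> member mediators.

Associations between lipid mediators and biological processes are
harvested from tabular snapshot dumps of ChEBI, LMSD, Reactome and SMPDB.
Since each source exports its own column layout, every dialect is mapped
onto a two/three-column interchange schema (process, lipid[, external id])
declared in :data:`DIALECTS`. Built collections serialize to GMT, the
tab-separated one-set-per-line format standard in enrichment tooling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .registry import LipidRegistry, Miss, slugify

SOURCES = ("ChEBI", "LMSD", "Reactome", "SMPDB", "custom")

#: per-source interchange column names: (process, lipid[, external id])
DIALECTS: Mapping[str, tuple[str, ...]] = {
    "ChEBI": ("role", "compound_name", "chebi_id"),
    "LMSD": ("category", "common_name", "lmsd_id"),
    "Reactome": ("pathway_name", "participant", "reactome_id"),
    "SMPDB": ("pathway_name", "metabolite_name", "smpdb_id"),
    "custom": ("process", "lipid"),
}


class GmtParseError(ValueError):
    """Malformed GMT line (fewer than 3 tab-separated fields)."""


class DialectError(ValueError):
    """Unknown association-dump dialect."""


@dataclass
class AssociationTable:
    """Parsed association rows plus a malformed-row tally."""

    source: str
    pairs: list[tuple[str, str]]  # (process_label, raw_lipid_name)
    n_rows: int = 0
    n_malformed: int = 0


@dataclass
class LipidSet:
    set_id: str
    description: str
    members: tuple[str, ...]
    source: str = "custom"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"set {self.set_id!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"set {self.set_id!r} has duplicate members")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class LipidSetCollection:
    sets: list[LipidSet] = field(default_factory=list)
    provenance: dict[str, str] = field(default_factory=dict)
    #: set_id -> raw names that did not resolve against the registry
    unresolved: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.set_id for s in self.sets]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate set_ids in collection: {dup}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def get(self, set_id: str) -> LipidSet:
        for s in self.sets:
            if s.set_id == set_id:
                return s
        raise KeyError(set_id)

    def member_sets(self) -> dict[str, tuple[str, ...]]:
        return {s.set_id: s.members for s in self.sets}


def parse_association_dump(path: str | Path, dialect: str) -> AssociationTable:
    """Read one source dump into (process, raw lipid name) pairs.

    Rows missing either the process or the lipid column are counted as
    malformed and skipped, never fatal. Duplicate rows are emitted as-is;
    deduplication happens at collection build time.
    """
    if dialect not in DIALECTS:
        raise DialectError(
            f"unknown dialect {dialect!r}; expected one of {sorted(DIALECTS)}"
        )
    cols = DIALECTS[dialect]
    proc_col, lipid_col = cols[0], cols[1]
    pairs: list[tuple[str, str]] = []
    n_rows = n_malformed = 0
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line.strip():
            warnings.warn(f"empty association dump: {path}")
            return AssociationTable(source=dialect, pairs=[], n_rows=0)
        header = header_line.rstrip("\n").split("\t")
        try:
            pi, li = header.index(proc_col), header.index(lipid_col)
        except ValueError as exc:
            raise DialectError(
                f"{path}: header {header} lacks {dialect} columns "
                f"({proc_col!r}, {lipid_col!r})"
            ) from exc
        for line in fh:
            if not line.strip():
                continue
            n_rows += 1
            fields = line.rstrip("\n").split("\t")
            proc = fields[pi].strip() if pi < len(fields) else ""
            lipid = fields[li].strip() if li < len(fields) else ""
            if not proc or not lipid:
                n_malformed += 1
                continue
            pairs.append((proc, lipid))
    if not pairs:
        warnings.warn(f"no usable associations in {path}")
    return AssociationTable(
        source=dialect, pairs=pairs, n_rows=n_rows, n_malformed=n_malformed
    )


def build_collection(
    assocs: Iterable[tuple[str, str]],
    registry: LipidRegistry,
    min_size: int = 3,
    max_size: int = 500,
    source: str = "custom",
) -> LipidSetCollection:
    """Group associations by process, resolve names, apply size bounds.

    Members are deduplicated and stored lexicographically by canonical_id
    so the built collection is invariant to input row order. Sets whose
    resolved membership falls outside ``[min_size, max_size]`` are
    dropped; unresolved raw names are recorded per set, not discarded
    silently.
    """
    if min_size < 1 or max_size < min_size:
        raise ValueError("need 1 <= min_size <= max_size")
    by_process: dict[str, set[str]] = {}
    missed: dict[str, list[str]] = {}
    for process, raw in assocs:
        hit = registry.resolve(raw)
        if isinstance(hit, Miss):
            missed.setdefault(process, []).append(raw)
        else:
            by_process.setdefault(process, set()).add(hit.canonical_id)
    sets = []
    for process in sorted(by_process):
        members = tuple(sorted(by_process[process]))
        if min_size <= len(members) <= max_size:
            sets.append(
                LipidSet(
                    set_id=slugify(process),
                    description=process,
                    members=members,
                    source=source,
                )
            )
    unresolved = {slugify(p): sorted(set(v)) for p, v in missed.items()}
    if not sets and missed:
        warnings.warn("no set survived: every lipid name missed the registry")
    return LipidSetCollection(sets=sets, unresolved=unresolved)


def merge_collections(colls: Sequence[LipidSetCollection]) -> LipidSetCollection:
    """Concatenate collections from different sources; set_ids must not clash."""
    merged = LipidSetCollection(
        sets=[s for c in colls for s in c.sets],
    )
    for c in colls:
        merged.provenance.update(c.provenance)
        for sid, names in c.unresolved.items():
            merged.unresolved.setdefault(sid, []).extend(names)
    return merged


# ---------------------------------------------------------------------- GMT


def write_gmt(coll: LipidSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for s in coll.sets:
            fh.write("\t".join([s.set_id, s.description, *s.members]) + "\n")


def read_gmt(
    path: str | Path, registry: LipidRegistry | None = None
) -> LipidSetCollection:
    """Parse a GMT file; optionally verify members against a registry.

    Unverifiable members (when a registry is given) land in the
    collection's unresolved report; lines with fewer than three fields
    raise :class:`GmtParseError` naming the line number.
    """
    sets: list[LipidSet] = []
    unresolved: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: GMT needs >=3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            set_id, description, *members = fields
            members = tuple(dict.fromkeys(m for m in members if m))
            if registry is not None:
                miss = [m for m in members if isinstance(registry.resolve(m), Miss)]
                if miss:
                    unresolved[set_id] = miss
            sets.append(LipidSet(set_id=set_id, description=description, members=members))
    return LipidSetCollection(sets=sets, unresolved=unresolved)
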