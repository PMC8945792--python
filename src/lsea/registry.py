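"""Canonical lipid-mediator identities.

Bioactive oxygenated PUFA derivatives (prostaglandins, leukotrienes,
resolvins, maresins, HETEs, EpOMEs, ...) go by many aliases across
databases — ChEBI, LMSD, Reactome and SMPDB each use their own spelling,
dashes and capitalisation. This module provides a small registry that
harmonizes mediator names, resolves synonyms, and carries the two
classifications used throughout the analysis: the precursor fatty acid
(AA, DGLA, LA on the omega-6 side; DHA, EPA, LNA, DPA on the omega-3
side) and the main biosynthetic enzyme class (COX, LOX, CYP450,
non-enzymatic routes).
"""

from __future__ import annotations

import csv
import enum
import importlib.resources
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping


class Precursor(str, enum.Enum):
    """Fatty-acid precursor of a lipid mediator."""

    AA = "AA"
    DGLA = "DGLA"
    LA = "LA"
    DHA = "DHA"
    EPA = "EPA"
    LNA = "LNA"
    DPA = "DPA"
    OTHER = "other"


class EnzymeClass(str, enum.Enum):
    """Main biosynthetic enzyme route of a mediator."""

    COX = "COX"
    LOX = "LOX"
    CYP450 = "CYP450"
    NON_ENZYMATIC = "non_enzymatic"
    MIXED = "mixed"
    UNKNOWN = "unknown"


#: omega family implied by the precursor fatty acid
OMEGA_FAMILY: Mapping[Precursor, str] = {
    Precursor.AA: "omega-6",
    Precursor.DGLA: "omega-6",
    Precursor.LA: "omega-6",
    Precursor.DHA: "omega-3",
    Precursor.EPA: "omega-3",
    Precursor.LNA: "omega-3",
    Precursor.DPA: "omega-3",
    Precursor.OTHER: "unknown",
}

# every unicode dash/minus variant that shows up in database exports
_DASHES = "‐‑‒–—―−"
_DASH_TABLE = str.maketrans({c: "-" for c in _DASHES})
_WS_RE = re.compile(r"\s+")


class RegistryError(ValueError):
    """Registry integrity violation (duplicate ids, colliding synonyms)."""


def normalize_name(raw: str) -> str:
    """Deterministic canonical form of a mediator name.

    Case-folded, whitespace collapsed, unicode dashes and the plus-minus
    sign mapped to ASCII. Stereo/regio punctuation — parentheses, commas,
    ASCII hyphens — is preserved, so ``9(10)-EpOME`` keeps its locant.
    Idempotent by construction.
    """
    if not isinstance(raw, str) or not raw.strip():
        raise ValueError("lipid name must be a nonempty string")
    s = raw.translate(_DASH_TABLE).replace("±", "+/-")
    s = _WS_RE.sub(" ", s).strip()
    return s.casefold()


def slugify(name: str) -> str:
    """Canonical id slug: normalized name with spaces collapsed to dashes."""
    return normalize_name(name).replace(" ", "-")


@dataclass(frozen=True)
class LipidRecord:
    canonical_id: str
    display_name: str
    synonyms: tuple[str, ...] = ()
    precursor: Precursor = Precursor.OTHER
    enzyme_class: EnzymeClass = EnzymeClass.UNKNOWN
    external_ids: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.canonical_id:
            raise RegistryError("canonical_id must be nonempty")

    @property
    def omega_family(self) -> str:
        return OMEGA_FAMILY[self.precursor]

    def classify(self) -> tuple[Precursor, EnzymeClass]:
        return self.precursor, self.enzyme_class

    def all_names(self) -> Iterator[str]:
        yield self.display_name
        yield from self.synonyms


@dataclass
class Miss:
    """Failed lookup; the query is echoed so callers can report it."""

    query: str
    normalized: str


class LipidRegistry:
    """A set of :class:`LipidRecord` with synonym-aware lookup.

    Lookup keys are normalized names; a synonym claimed by two records is
    a :class:`RegistryError` at load time, never a silent pick.
    """

    #: registry TSV column order
    COLUMNS = (
        "canonical_id",
        "display_name",
        "synonyms",
        "precursor",
        "enzyme_class",
        "chebi_id",
        "lmsd_id",
    )

    def __init__(self, records: Iterable[LipidRecord] = ()) -> None:
        self._records: dict[str, LipidRecord] = {}
        self._index: dict[str, str] = {}  # normalized name -> canonical_id
        for rec in records:
            self.add(rec)

    def add(self, rec: LipidRecord) -> None:
        if rec.canonical_id in self._records:
            raise RegistryError(f"duplicate canonical_id {rec.canonical_id!r}")
        claims = {normalize_name(n) for n in rec.all_names()}
        claims.add(normalize_name(rec.canonical_id))
        for key in claims:
            owner = self._index.get(key)
            if owner is not None and owner != rec.canonical_id:
                raise RegistryError(
                    f"synonym {key!r} claimed by both {owner!r} "
                    f"and {rec.canonical_id!r}"
                )
        self._records[rec.canonical_id] = rec
        for key in claims:
            self._index[key] = rec.canonical_id

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[LipidRecord]:
        return iter(self._records.values())

    def __contains__(self, canonical_id: str) -> bool:
        return canonical_id in self._records

    def get(self, canonical_id: str) -> LipidRecord:
        return self._records[canonical_id]

    def resolve(self, raw: str) -> LipidRecord | Miss:
        """Exact match on normalized canonical name or any synonym."""
        key = normalize_name(raw)
        cid = self._index.get(key)
        if cid is None:
            return Miss(query=raw, normalized=key)
        return self._records[cid]

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LipidRegistry":
        reg = cls()
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            missing = set(cls.COLUMNS) - set(reader.fieldnames or ())
            if missing:
                raise RegistryError(
                    f"registry file {path} missing columns {sorted(missing)}"
                )
            for row in reader:
                external = {
                    k: row[col]
                    for k, col in (("ChEBI", "chebi_id"), ("LMSD", "lmsd_id"))
                    if row.get(col)
                }
                syns = tuple(
                    s.strip() for s in (row["synonyms"] or "").split("|") if s.strip()
                )
                reg.add(
                    LipidRecord(
                        canonical_id=row["canonical_id"],
                        display_name=row["display_name"],
                        synonyms=syns,
                        precursor=Precursor(row["precursor"]),
                        enzyme_class=EnzymeClass(row["enzyme_class"]),
                        external_ids=external,
                    )
                )
        return reg

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(self.COLUMNS)
            for rec in self:
                writer.writerow(
                    [
                        rec.canonical_id,
                        rec.display_name,
                        "|".join(rec.synonyms),
                        rec.precursor.value,
                        rec.enzyme_class.value,
                        rec.external_ids.get("ChEBI", ""),
                        rec.external_ids.get("LMSD", ""),
                    ]
                )


def load_seed_registry() -> LipidRegistry:
    """Curated seed panel of common eicosanoids/docosanoids and oxylipins.

    A best-effort curation shipped as editable data, not ground truth;
    enzyme assignments follow the dominant published route per mediator.
    """
    ref = importlib.resources.files("lsea.data").joinpath("seed_registry.tsv")
    with importlib.resources.as_file(ref) as path:
        return LipidRegistry.from_tsv(path)
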