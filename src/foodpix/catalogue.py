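"""FoodEx2-like food catalogue and food composition database (FCDB) linkage.

The catalogue is a flat abstraction of a FoodEx2 list: each entry carries a
list-term code, an English food name and one of the four coarse food
categories (raw, derivative, simple composite, aggregated composite). Entry
names are profiled once at load time and indexed by their noun lemmas, which
is what candidate retrieval searches. The FCDB is keyed solely by FoodEx2
code; nutrient amounts are per 100 g.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from foodpix.textproc import Tagger, TextProfile, DEFAULT_TAGGER, profile

CATEGORIES = ("raw", "derivative", "simple composite", "aggregated composite")


class CatalogueError(ValueError):
    """Raised for malformed catalogue or FCDB inputs."""


class CodeNotFoundError(KeyError):
    """Raised when a FoodEx2 code has no FCDB record."""

    def __init__(self, code: str):
        super().__init__(code)
        self.code = code

    def __str__(self) -> str:
        return f"no FCDB record for FoodEx2 code {self.code!r}"


@dataclass(frozen=True)
class CatalogueEntry:
    code: str
    name: str
    category: str
    profile: TextProfile

    def __post_init__(self) -> None:
        if not self.name:
            raise CatalogueError("entry name must be non-empty")
        if self.category not in CATEGORIES:
            raise CatalogueError(
                f"unknown category {self.category!r}; expected one of {CATEGORIES}"
            )


@dataclass
class Catalogue:
    """Ordered catalogue entries plus a noun-lemma retrieval index."""

    entries: list[CatalogueEntry]
    noun_index: dict[str, set[str]] = field(default_factory=dict)
    _by_code: dict[str, CatalogueEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._by_code = {}
        for e in self.entries:
            if e.code in self._by_code:
                raise CatalogueError(f"duplicate catalogue code {e.code!r}")
            self._by_code[e.code] = e
        self.noun_index = {}
        for e in self.entries:
            for lemma in e.profile.nouns:
                self.noun_index.setdefault(lemma, set()).add(e.code)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, code: str) -> CatalogueEntry:
        return self._by_code[code]

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def lookup_noun(self, lemma: str) -> set[str]:
        """Codes of entries whose name contains the given noun lemma."""
        return set(self.noun_index.get(lemma, set()))

    @classmethod
    def from_rows(
        cls,
        rows: Iterable[tuple[str, str, str]],
        tagger: Tagger = DEFAULT_TAGGER,
    ) -> "Catalogue":
        entries = [
            CatalogueEntry(code=c, name=n, category=cat, profile=profile(n, tagger))
            for c, n, cat in rows
        ]
        return cls(entries)


def read_catalogue(path: str | Path, tagger: Tagger = DEFAULT_TAGGER) -> Catalogue:
    """Load a catalogue CSV with header ``code,name,category``.

    Entry name profiles are computed at load time and the noun index built
    over them. Duplicate codes and categories outside the closed set are
    load-time errors.
    """
    rows: list[tuple[str, str, str]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"code", "name", "category"}.issubset(
            reader.fieldnames
        ):
            raise CatalogueError(
                f"catalogue CSV must have header code,name,category; got {reader.fieldnames}"
            )
        for row in reader:
            rows.append((row["code"], row["name"], row["category"]))
    return Catalogue.from_rows(rows, tagger)


@dataclass(frozen=True)
class NutrientRecord:
    """Nutrient amounts per 100 g for one FoodEx2 code."""

    code: str
    name: str
    nutrients: Mapping[str, float]

    def __post_init__(self) -> None:
        for k, v in self.nutrients.items():
            if v < 0:
                raise CatalogueError(f"nutrient {k!r} of {self.code!r} is negative")


def read_fcdb(path: str | Path) -> list[NutrientRecord]:
    """Load an FCDB CSV: ``code,name,<nutrient columns...>``.

    Every column beyond ``code`` and ``name`` is read as a numeric nutrient
    amount per 100 g. Duplicate codes are a load-time error so lookup is
    never ambiguous.
    """
    records: list[NutrientRecord] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"code", "name"}.issubset(reader.fieldnames):
            raise CatalogueError(
                f"FCDB CSV must have columns code,name,...; got {reader.fieldnames}"
            )
        nutrient_cols = [c for c in reader.fieldnames if c not in ("code", "name")]
        for row in reader:
            code = row["code"]
            if code in seen:
                raise CatalogueError(f"duplicate FCDB code {code!r}")
            seen.add(code)
            records.append(
                NutrientRecord(
                    code=code,
                    name=row["name"],
                    nutrients={c: float(row[c]) for c in nutrient_cols},
                )
            )
    return records


def write_fcdb(path: str | Path, records: list[NutrientRecord]) -> None:
    if not records:
        raise CatalogueError("cannot write an empty FCDB")
    cols = sorted({k for r in records for k in r.nutrients})
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["code", "name", *cols])
        for r in records:
            writer.writerow([r.code, r.name, *(r.nutrients.get(c, 0.0) for c in cols)])


def link_fcdb(food, fcdb: Iterable[NutrientRecord]) -> NutrientRecord:
    """Return the FCDB record for a standardized food (or bare code).

    ``food`` is anything with a resolved ``code`` attribute (e.g. a
    StandardizedFood) or the code string itself. Raises
    :class:`CodeNotFoundError` when the code is absent; callers that hold an
    FCDB without FoodEx2 identifiers can standardize the FCDB's own food
    names first to obtain codes, then link.
    """
    code = getattr(food, "code", food)
    for rec in fcdb:
        if rec.code == code:
            return rec
    raise CodeNotFoundError(code)
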