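"""Curated use reports and the species x use-category x culture matrix.

A *use report* is one curated record that a species is used for a category
(food, medicinal, ritual, cosmetic, toxic) by a culture, traceable to a
literature source.  Cultures are identified at language-family granularity
by a 3-letter code (ISO 639-2 / ISO 639-5 / WALS, or an explicitly created
custom code); individual languages are merged into their family except for
registered exceptions (e.g. jpn and kor, which inherited a neighbouring
family's plant knowledge directly and are treated as independent cultures).

Medicinal indications are mapped to ICD-11 chapter/system labels through a
curated mapping table; indications with no mapping are retained as *emic*
solitary subcategories (culture-internal disease concepts such as
"eghindi"), never dropped.

The central container is :class:`UseMatrix`: integer report-unit counts on
the species x (domain, subcategory) x culture grid, plus the denominator
constant ``N`` = number of distinct cultures with at least one report.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .taxonomy import CanonicalName

__all__ = [
    "DOMAINS",
    "CultureCode",
    "CultureRegistry",
    "UseCategory",
    "UseReport",
    "UseMatrix",
    "load_registry",
    "categorize_use",
    "build_matrix",
    "read_reports_csv",
    "read_mapping_csv",
]

DOMAINS = ("food", "medicinal", "ritual", "cosmetic", "toxic")

#: language codes treated as independent cultures despite belonging to a
#: registered family (they adopted a neighbouring tradition wholesale)
INDEPENDENT_CULTURE_EXCEPTIONS = ("jpn", "kor")


@dataclass(frozen=True)
class CultureCode:
    """A 3-letter culture identifier at language-family granularity."""

    code: str
    family_name: str = ""
    source_standard: str = "custom"  # ISO639-2 | ISO639-5 | WALS | custom
    region: str = ""

    def __post_init__(self) -> None:
        if len(self.code) != 3 or not self.code.isalpha():
            raise ValueError(f"culture code must be 3 letters: {self.code!r}")
        allowed = ("ISO639-2", "ISO639-5", "WALS", "custom")
        if self.source_standard not in allowed:
            raise ValueError(f"standard {self.source_standard!r} not in {allowed}")


@dataclass
class CultureRegistry:
    """Registry of culture codes; custom codes must not shadow registry ones."""

    entries: dict[str, CultureCode] = field(default_factory=dict)

    def add(self, code: CultureCode) -> None:
        existing = self.entries.get(code.code)
        if existing is not None:
            if existing.family_name != code.family_name:
                raise ValueError(
                    f"code {code.code!r} already registered for "
                    f"{existing.family_name!r}, conflicts with {code.family_name!r}"
                )
            return
        if code.source_standard == "custom":
            clash = [
                c for c in self.entries.values()
                if c.code == code.code and c.source_standard != "custom"
            ]
            if clash:
                raise ValueError(f"custom code {code.code!r} collides with registry")
            warnings.warn(f"created custom culture code {code.code!r} "
                          f"({code.family_name})", stacklevel=3)
        self.entries[code.code] = code

    def __contains__(self, code: str) -> bool:
        return code in self.entries

    def __getitem__(self, code: str) -> CultureCode:
        return self.entries[code]


def load_registry(rows: Iterable[Mapping[str, str]]) -> CultureRegistry:
    """Build a :class:`CultureRegistry` from rows with keys
    ``code, family_name, standard[, region]``.

    Duplicate codes with conflicting family names raise; custom-code
    creation is logged as a warning.
    """
    registry = CultureRegistry()
    for row in rows:
        registry.add(CultureCode(
            code=row["code"],
            family_name=row.get("family_name", ""),
            source_standard=row.get("standard", "custom"),
            region=row.get("region", ""),
        ))
    return registry


@dataclass(frozen=True)
class UseCategory:
    """A use domain with an optional medicinal subcategory.

    ``subcategory`` is an ICD-11 chapter/system label ("eye", "kidney", ...)
    or, when ``emic_flag`` is set, a culture-internal solitary label kept
    verbatim.  Non-medicinal domains carry no subcategory.
    """

    domain: str
    subcategory: str = ""
    emic_flag: bool = False

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"domain {self.domain!r} not in {DOMAINS}")
        if self.subcategory and self.domain != "medicinal":
            raise ValueError("subcategory only valid for medicinal domain")

    @property
    def label(self) -> str:
        return f"{self.domain}:{self.subcategory}" if self.subcategory else self.domain


def categorize_use(
    raw_indication: str,
    mapping_table: Mapping[str, tuple[str, str]],
) -> UseCategory:
    """Map a raw use/indication label to a :class:`UseCategory`.

    ``mapping_table`` maps raw labels to ``(domain, subcategory)`` pairs.
    Labels absent from the table are assumed medicinal and become emic
    solitary subcategories carrying the raw label itself.
    """
    if not raw_indication or not raw_indication.strip():
        raise ValueError("empty indication label")
    key = raw_indication.strip()
    if key in mapping_table:
        domain, sub = mapping_table[key]
        return UseCategory(domain=domain, subcategory=sub)
    return UseCategory(domain="medicinal", subcategory=key, emic_flag=True)


@dataclass(frozen=True)
class UseReport:
    """One curated record: species used for a category by a culture."""

    species: CanonicalName
    category: UseCategory
    culture: str  # 3-letter culture code
    source_ref: str = ""
    plant_part: str = ""
    preparation: str = ""

    def __post_init__(self) -> None:
        if len(self.culture) != 3 or not self.culture.isalpha():
            raise ValueError(f"culture code must be 3 letters: {self.culture!r}")


@dataclass
class UseMatrix:
    """Report-unit counts on the species x category x culture grid.

    ``counts`` is a long-format DataFrame with columns
    ``species, domain, subcategory, culture, count`` (count >= 1 integers);
    axis orders are stored explicitly so exports are deterministic.  ``N``
    is the number of distinct cultures with at least one surviving report —
    the denominator constant shared by FL, CII and RFC.
    """

    counts: pd.DataFrame
    species_order: list[str]
    category_order: list[tuple[str, str]]
    culture_order: list[str]
    N: int
    count_unit: str = "triple"
    rejected: pd.DataFrame | None = None

    def total_units(self, *, include_toxic: bool = True) -> int:
        df = self.counts if include_toxic else self.counts[
            self.counts["domain"] != "toxic"]
        return int(df["count"].sum())

    # -- export / import -------------------------------------------------

    def to_csv(self, path, sidecar_path=None) -> None:
        """Write long-format CSV plus a JSON sidecar with N and axis orders."""
        self.counts.to_csv(path, index=False)
        if sidecar_path is not None:
            meta = {
                "N": self.N,
                "count_unit": self.count_unit,
                "species_order": self.species_order,
                "category_order": [list(c) for c in self.category_order],
                "culture_order": self.culture_order,
            }
            with open(sidecar_path, "w", encoding="utf-8") as fh:
                json.dump(meta, fh, indent=1)

    @classmethod
    def from_csv(cls, path, sidecar_path) -> "UseMatrix":
        counts = pd.read_csv(path, dtype={"count": int}).fillna("")
        with open(sidecar_path, encoding="utf-8") as fh:
            meta = json.load(fh)
        return cls(
            counts=counts,
            species_order=meta["species_order"],
            category_order=[tuple(c) for c in meta["category_order"]],
            culture_order=meta["culture_order"],
            N=meta["N"],
            count_unit=meta.get("count_unit", "triple"),
        )

    def to_wide(self, *, include_toxic: bool = True) -> pd.DataFrame:
        """Species x category wide table (summed over cultures) for heatmaps."""
        df = self.counts if include_toxic else self.counts[
            self.counts["domain"] != "toxic"]
        wide = df.pivot_table(
            index="species", columns=["domain", "subcategory"],
            values="count", aggfunc="sum", fill_value=0,
        )
        order = [c for c in self.category_order if c in set(wide.columns)]
        wide = wide.reindex(
            index=[s for s in self.species_order if s in wide.index],
            columns=pd.MultiIndex.from_tuples(order),
        ).fillna(0).astype(int)
        return wide


def build_matrix(
    reports: Sequence[UseReport],
    *,
    revised_checklist: set[str] | None = None,
    count_unit: str = "triple",
) -> UseMatrix:
    """Assemble validated use reports into a :class:`UseMatrix`.

    Counting unit (what one "report-unit" is):

    - ``triple`` (default): a distinct (species, culture, category) triple —
      several literature sources repeating the same triple count once;
    - ``source``: a distinct (species, culture, category, source_ref) tuple.

    Reports citing species outside ``revised_checklist`` (when given) are
    collected into ``matrix.rejected`` and the run continues.  Exact
    duplicate tuples are collapsed with a warning.  Axis orders are
    lexicographic; the result is invariant to input report order.
    """
    if count_unit not in ("triple", "source"):
        raise ValueError("count_unit must be 'triple' or 'source'")

    kept: list[UseReport] = []
    rejected_rows: list[dict] = []
    for rep in reports:
        if (revised_checklist is not None
                and rep.species.binomial not in revised_checklist):
            rejected_rows.append({
                "species": rep.species.binomial,
                "category": rep.category.label,
                "culture": rep.culture,
                "source_ref": rep.source_ref,
                "reason": "species not in revised checklist",
            })
            continue
        kept.append(rep)

    seen: set[tuple] = set()
    units: dict[tuple[str, str, str, str], int] = {}
    n_dupes = 0
    for rep in sorted(
        kept, key=lambda r: (r.species.binomial, r.category.label,
                             r.culture, r.source_ref),
    ):
        full_key = (rep.species.binomial, rep.category.domain,
                    rep.category.subcategory, rep.culture, rep.source_ref)
        if full_key in seen:
            n_dupes += 1
            continue
        seen.add(full_key)
        unit_key = full_key[:4] if count_unit == "triple" else full_key
        cell = (rep.species.binomial, rep.category.domain,
                rep.category.subcategory, rep.culture)
        if count_unit == "triple":
            if unit_key in units:
                continue  # same triple from another source: one unit
            units[cell] = 1
        else:
            units[cell] = units.get(cell, 0) + 1
    if n_dupes:
        warnings.warn(f"collapsed {n_dupes} duplicate report tuple(s)",
                      stacklevel=2)

    counts = pd.DataFrame(
        [{"species": s, "domain": d, "subcategory": sub,
          "culture": c, "count": n}
         for (s, d, sub, c), n in units.items()],
        columns=["species", "domain", "subcategory", "culture", "count"],
    )
    counts = counts.sort_values(
        ["species", "domain", "subcategory", "culture"]).reset_index(drop=True)

    species_order = sorted(counts["species"].unique())
    domain_rank = {d: i for i, d in enumerate(DOMAINS)}
    category_order = sorted(
        {(r.domain, r.subcategory) for r in counts.itertuples()},
        key=lambda c: (domain_rank[c[0]], c[1]),
    )
    culture_order = sorted(counts["culture"].unique())
    rejected = pd.DataFrame(
        rejected_rows,
        columns=["species", "category", "culture", "source_ref", "reason"],
    )
    return UseMatrix(
        counts=counts,
        species_order=species_order,
        category_order=category_order,
        culture_order=culture_order,
        N=len(culture_order),
        count_unit=count_unit,
        rejected=rejected if len(rejected) else None,
    )


# ---------------------------------------------------------------------------
# File I/O


def read_mapping_csv(path) -> dict[str, tuple[str, str]]:
    """Read the indication mapping table: raw_label -> (domain, subcategory)."""
    df = pd.read_csv(path, dtype=str).fillna("")
    if not {"raw_label", "domain"}.issubset(df.columns):
        raise ValueError("mapping file needs columns raw_label, domain")
    if "subcategory" not in df.columns:
        df["subcategory"] = ""
    return {
        r["raw_label"]: (r["domain"], r["subcategory"])
        for _, r in df.iterrows()
    }


def read_reports_csv(
    path,
    mapping_table: Mapping[str, tuple[str, str]] | None = None,
) -> list[UseReport]:
    """Read use reports from CSV with columns
    ``species, author, domain, indication, culture_code, source_ref``
    (plus optional ``plant_part, preparation``).

    When ``domain`` is medicinal (or blank) the ``indication`` column is run
    through :func:`categorize_use` with ``mapping_table``; otherwise the
    stated domain is used directly.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"species", "indication", "culture_code"}
    if not required.issubset(df.columns):
        raise ValueError(f"reports file needs columns {sorted(required)}")
    mapping = dict(mapping_table or {})
    reports = []
    for _, row in df.iterrows():
        domain = row.get("domain", "")
        if domain and domain != "medicinal":
            category = UseCategory(domain=domain)
        else:
            category = categorize_use(row["indication"], mapping)
        from .taxonomy import normalize_name
        species = normalize_name(row["species"], row.get("author", ""))
        reports.append(UseReport(
            species=species,
            category=category,
            culture=row["culture_code"],
            source_ref=row.get("source_ref", ""),
            plant_part=row.get("plant_part", ""),
            preparation=row.get("preparation", ""),
        ))
    return reports
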