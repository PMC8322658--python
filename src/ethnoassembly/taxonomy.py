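"""Documentation-based taxonomic reconciliation across nomenclatural checklists.

Multiple global nomenclatural databases (e.g. COL, POWO, WFO, TPL) publish
overlapping but inconsistent species lists for the same genus.  This module
normalizes the raw names, builds a name x source comparison table, applies a
five-rule documentation-based revision procedure to produce a single revised
(accepted) checklist, and summarizes the source overlap structure with
exclusive ("UpSet") intersection counts.

The five rules, in the order applied per name:

1. names accepted in *all* external sources are accepted automatically;
2. infraspecific taxa and hybrids (varieties, subspecies, forms, crosses)
   are removed;
3./4. names accepted in only a strict subset of sources require documentary
   evidence (type specimens, protologues, regional floras) — that judgement
   is externalized as a :class:`CuratorDecision` table; undecided names go to
   a ``needs_review`` queue rather than being guessed;
5. names confirmed to be synonyms are removed.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CanonicalName",
    "SourceChecklist",
    "ComparisonTable",
    "CuratorDecision",
    "RevisedChecklist",
    "UpSetSummary",
    "MalformedNameError",
    "normalize_name",
    "build_comparison",
    "apply_revision_rules",
    "upset_counts",
    "read_checklists_csv",
    "read_decisions_csv",
]

# Cell states in the comparison table.  "unresolved" (a TPL status) is kept
# distinct from "absent" but is treated as non-accepted by the rules.
STATUSES = ("accepted", "synonym", "unresolved")
CELL_STATES = STATUSES + ("absent",)

RANK_MARKERS = {
    "var.": "variety",
    "var": "variety",
    "subsp.": "subspecies",
    "subsp": "subspecies",
    "ssp.": "subspecies",
    "ssp": "subspecies",
    "f.": "form",
    "fo.": "form",
}


class MalformedNameError(ValueError):
    """Raised when a raw name cannot be reduced to a two-epithet binomial."""


@dataclass(frozen=True)
class CanonicalName:
    """A normalized binomial with its authority string and rank flags.

    ``binomial`` is always "Genus epithet" (capitalized genus, lowercase
    epithet).  ``rank_flags`` records any infraspecific/hybrid markers that
    were stripped during normalization; a plain species has an empty set.
    """

    binomial: str
    author: str = ""
    rank_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if len(self.binomial.split()) != 2:
            raise MalformedNameError(
                f"binomial must have exactly two epithets: {self.binomial!r}"
            )


@dataclass
class SourceChecklist:
    """One source database's species list: (raw_name, author, status) rows."""

    source_id: str
    entries: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        if not self.source_id:
            raise ValueError("source_id must be non-empty")
        seen: set[tuple[str, str]] = set()
        for raw_name, author, status in self.entries:
            if not raw_name:
                raise ValueError(f"{self.source_id}: empty raw_name")
            if status not in STATUSES:
                raise ValueError(
                    f"{self.source_id}: status {status!r} not in {STATUSES}"
                )
            key = (raw_name, author)
            if key in seen:
                raise ValueError(f"{self.source_id}: duplicate entry {key}")
            seen.add(key)


@dataclass
class ComparisonTable:
    """Name x source presence/status matrix driving the revision rules.

    ``presence`` is a DataFrame indexed by binomial with one column per
    source_id and cell values from ``CELL_STATES``.  ``names`` maps each
    binomial to its CanonicalName (first-seen author wins); ``author_conflicts``
    lists binomials whose sources disagree on the authority string.
    """

    names: dict[str, CanonicalName]  # row key -> canonical name
    sources: list[str]
    presence: pd.DataFrame
    author_conflicts: dict[str, set[str]] = field(default_factory=dict)

    @staticmethod
    def row_key(canon: CanonicalName) -> str:
        """Row identity: the binomial, suffixed with rank flags when present
        so an infraspecific entry never merges with its parent species."""
        if not canon.rank_flags:
            return canon.binomial
        return f"{canon.binomial} [{'+'.join(sorted(canon.rank_flags))}]"

    def __post_init__(self) -> None:
        if list(self.presence.columns) != self.sources:
            raise ValueError("presence columns must match sources")
        if set(self.presence.index) != set(self.names):
            raise ValueError("presence rows must match names")
        if ((self.presence == "absent").all(axis=1)).any():
            raise ValueError("every name must be present in at least one source")


@dataclass(frozen=True)
class CuratorDecision:
    """A human verdict on a disputed name, with its documentary evidence."""

    binomial: str
    verdict: str  # accept | reject_synonym | reject_invalid
    evidence_note: str = ""

    VERDICTS = ("accept", "reject_synonym", "reject_invalid")

    def __post_init__(self) -> None:
        if self.verdict not in self.VERDICTS:
            raise ValueError(f"verdict {self.verdict!r} not in {self.VERDICTS}")


@dataclass
class RevisedChecklist:
    """The accepted set plus a per-name audit trail and the review queue.

    ``audit`` maps every input binomial to ``(rule, outcome)`` where rule is
    1-5 and outcome is one of accepted/removed/needs_review.
    """

    accepted: set[CanonicalName]
    audit: dict[str, tuple[int, str]]
    needs_review: list[str] = field(default_factory=list)

    @property
    def accepted_binomials(self) -> set[str]:
        return {n.binomial for n in self.accepted}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"binomial": b, "rule": r, "outcome": o}
            for b, (r, o) in sorted(self.audit.items())
        ]
        return pd.DataFrame(rows, columns=["binomial", "rule", "outcome"])


@dataclass
class UpSetSummary:
    """Exclusive (exact-pattern) intersection counts over a family of sets."""

    per_source_totals: dict[str, int]
    exclusive_counts: dict[frozenset[str], int]

    @property
    def union_size(self) -> int:
        return sum(self.exclusive_counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"subset": "+".join(sorted(s)), "degree": len(s), "count": c}
            for s, c in sorted(
                self.exclusive_counts.items(),
                key=lambda kv: (-kv[1], sorted(kv[0])),
            )
        ]
        return pd.DataFrame(rows, columns=["subset", "degree", "count"])


# ---------------------------------------------------------------------------
# Name normalization

_HYBRID_RE = re.compile(r"(?:×\s*|\bx\s+)", re.IGNORECASE)


def normalize_name(raw_name: str, author: str = "") -> CanonicalName:
    """Normalize a raw checklist name to a :class:`CanonicalName`.

    Collapses whitespace, strips infraspecific rank markers ("var.",
    "subsp.", "f.") and hybrid signs (both "×" U+00D7 and ASCII "x " before
    an epithet) into ``rank_flags``, capitalizes the genus and lowercases the
    specific epithet.  The author string is preserved verbatim (trimmed).

    Raises :class:`MalformedNameError` when fewer than two epithets remain.
    """
    if not raw_name or not raw_name.strip():
        raise MalformedNameError("empty name")
    text = " ".join(raw_name.split())
    flags: set[str] = set()
    if _HYBRID_RE.search(" " + text):
        flags.add("hybrid")
        text = _HYBRID_RE.sub("", " " + text).strip()
    tokens = text.split()
    core: list[str] = []
    i = 0
    while i < len(tokens):
        marker = RANK_MARKERS.get(tokens[i].lower())
        if marker is not None:
            flags.add(marker)
            i += 2  # skip the marker and its epithet
        else:
            core.append(tokens[i])
            i += 1
    if len(core) < 2:
        raise MalformedNameError(f"fewer than two epithets in {raw_name!r}")
    if len(core) > 2 and not flags:
        # trailing tokens without a marker are treated as authority overflow
        core = core[:2]
    binomial = f"{core[0].capitalize()} {core[1].lower()}"
    return CanonicalName(binomial, author.strip(), frozenset(flags))


# ---------------------------------------------------------------------------
# Comparison table


def build_comparison(checklists: Sequence[SourceChecklist]) -> ComparisonTable:
    """Merge per-source checklists into a single name x source status matrix.

    Names are matched on the rank-stripped binomial; conflicting authority
    strings are recorded in ``author_conflicts`` rather than splitting rows.
    Malformed names are rejected with a warning, never silently dropped.
    Row order is lexicographic by binomial (deterministic).
    """
    if not checklists:
        raise ValueError("at least one checklist required")
    sources = [c.source_id for c in checklists]
    if len(set(sources)) != len(sources):
        raise ValueError(f"duplicate source_id in {sources}")

    names: dict[str, CanonicalName] = {}
    conflicts: dict[str, set[str]] = {}
    cells: dict[str, dict[str, str]] = {}
    for checklist in checklists:
        for raw_name, author, status in checklist.entries:
            try:
                canon = normalize_name(raw_name, author)
            except MalformedNameError as exc:
                warnings.warn(
                    f"{checklist.source_id}: rejected malformed name "
                    f"{raw_name!r}: {exc}",
                    stacklevel=2,
                )
                continue
            b = ComparisonTable.row_key(canon)
            if b not in names:
                names[b] = canon
            else:
                prev = names[b]
                if canon.author and prev.author and canon.author != prev.author:
                    conflicts.setdefault(canon.binomial,
                                         {prev.author}).add(canon.author)
            row = cells.setdefault(b, {})
            prior = row.get(checklist.source_id)
            # accepted beats synonym beats unresolved within one source
            order = {"accepted": 2, "synonym": 1, "unresolved": 0}
            if prior is None or order[status] > order[prior]:
                row[checklist.source_id] = status

    ordered = sorted(names)
    presence = pd.DataFrame(
        [[cells[b].get(s, "absent") for s in sources] for b in ordered],
        index=ordered,
        columns=sources,
    )
    return ComparisonTable(
        names={b: names[b] for b in ordered},
        sources=sources,
        presence=presence,
        author_conflicts=conflicts,
    )


# ---------------------------------------------------------------------------
# Revision rules


def apply_revision_rules(
    table: ComparisonTable,
    decisions: Iterable[CuratorDecision] = (),
    *,
    unanimity_sources: Sequence[str] | None = None,
) -> RevisedChecklist:
    """Apply the five documentation-based revision rules to a comparison table.

    ``unanimity_sources`` restricts rule 1's "accepted everywhere" test to a
    subset of the table's sources (default: all of them); rules 3-5 always
    consider the full table.  Decisions citing names absent from the table
    are warned about and ignored.  Returns the accepted set, a full audit
    trail, and the queue of undecidable names.
    """
    decision_map: dict[str, CuratorDecision] = {}
    for d in decisions:
        if d.binomial in decision_map:
            raise ValueError(f"duplicate decision for {d.binomial}")
        decision_map[d.binomial] = d
    table_binomials = {c.binomial for c in table.names.values()}
    unknown = set(decision_map) - table_binomials
    for b in sorted(unknown):
        warnings.warn(f"decision for {b!r} not in comparison table; ignored",
                      stacklevel=2)
        del decision_map[b]

    rule1_cols = list(unanimity_sources or table.sources)
    missing = set(rule1_cols) - set(table.sources)
    if missing:
        raise ValueError(f"unanimity sources not in table: {sorted(missing)}")

    accepted: set[CanonicalName] = set()
    audit: dict[str, tuple[int, str]] = {}
    needs_review: list[str] = []

    for key, canon in table.names.items():
        row = table.presence.loc[key]
        if canon.rank_flags:
            audit[key] = (2, "removed")  # varieties and hybrids out
            continue
        if all(row[s] == "accepted" for s in rule1_cols):
            accepted.add(canon)
            audit[key] = (1, "accepted")
            continue
        decision = decision_map.get(canon.binomial)
        if decision is None:
            needs_review.append(key)
            audit[key] = (3, "needs_review")
            continue
        if decision.verdict == "accept":
            accepted.add(canon)
            audit[key] = (4, "accepted")
        elif decision.verdict == "reject_synonym":
            audit[key] = (5, "removed")
        else:  # reject_invalid
            audit[key] = (4, "removed")

    return RevisedChecklist(accepted=accepted, audit=audit,
                            needs_review=sorted(needs_review))


# ---------------------------------------------------------------------------
# UpSet exclusive intersections


def upset_counts(sets: Mapping[str, set]) -> UpSetSummary:
    """Exclusive-intersection counts: each element is tallied under the exact
    subset of sources containing it, so the counts partition the union."""
    if not sets or all(not s for s in sets.values()):
        raise ValueError("at least one non-empty set required")
    exclusive: dict[frozenset[str], int] = {}
    for element in set().union(*sets.values()):
        pattern = frozenset(k for k, v in sets.items() if element in v)
        exclusive[pattern] = exclusive.get(pattern, 0) + 1
    totals = {k: len(v) for k, v in sets.items()}
    return UpSetSummary(per_source_totals=totals, exclusive_counts=exclusive)


# ---------------------------------------------------------------------------
# File I/O (CSV/TSV, UTF-8)


def read_checklists_csv(path) -> list[SourceChecklist]:
    """Read checklists from CSV/TSV with columns source, name, author, status."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str).fillna("")
    required = {"source", "name", "status"}
    if not required.issubset(df.columns):
        raise ValueError(f"checklist file needs columns {sorted(required)}")
    if "author" not in df.columns:
        df["author"] = ""
    out = []
    for source_id, group in df.groupby("source", sort=True):
        entries = [
            (r["name"], r["author"], r["status"]) for _, r in group.iterrows()
        ]
        out.append(SourceChecklist(source_id=str(source_id), entries=entries))
    return out


def read_decisions_csv(path) -> list[CuratorDecision]:
    """Read curator decisions from CSV with columns binomial, verdict[, evidence_note]."""
    df = pd.read_csv(path, dtype=str).fillna("")
    if not {"binomial", "verdict"}.issubset(df.columns):
        raise ValueError("decisions file needs columns binomial, verdict")
    if "evidence_note" not in df.columns:
        df["evidence_note"] = ""
    return [
        CuratorDecision(r["binomial"], r["verdict"], r["evidence_note"])
        for _, r in df.iterrows()
    ]
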