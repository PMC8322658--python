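"""Shared fixtures: a hand-enumerable toy dataset and a brute-force oracle.

The oracle recounts every index directly from the raw report list with
plain set/dict arithmetic, never touching the UseMatrix container, so the
pipeline and the oracle share no code path.
"""

from __future__ import annotations

from fractions import Fraction

import pytest

from ethnoassembly.taxonomy import CanonicalName
from ethnoassembly.usedata import UseCategory, UseReport, build_matrix


def make_report(species: str, domain: str, culture: str,
                subcategory: str = "", source_ref: str = "r1") -> UseReport:
    return UseReport(
        species=CanonicalName(species, "Auct."),
        category=UseCategory(domain=domain, subcategory=subcategory,
                             emic_flag=False),
        culture=culture,
        source_ref=source_ref,
    )


TOY_REPORTS = [
    make_report("Genus alpha", "food", "aaa"),
    make_report("Genus alpha", "food", "bbb"),
    make_report("Genus alpha", "medicinal", "aaa", "eye"),
    make_report("Genus alpha", "medicinal", "aaa", "kidney"),
    make_report("Genus alpha", "ritual", "ccc"),
    make_report("Genus beta", "food", "aaa"),
    make_report("Genus beta", "medicinal", "bbb", "eye"),
    make_report("Genus gamma", "toxic", "ccc"),
]


@pytest.fixture
def toy_reports():
    return list(TOY_REPORTS)


@pytest.fixture
def toy_matrix():
    return build_matrix(TOY_REPORTS)


def brute_force_indices(reports):
    """Recount N, R_u, R_uc,s, N_s, per-culture sets from raw reports.

    Report-units are distinct (species, domain, subcategory, culture)
    triples; toxic rows are kept out of every index quantity but still
    count toward N (a culture with any report is an informant).
    Returns exact Fractions keyed the way the pipeline labels things.
    """
    triples = sorted({
        (r.species.binomial, r.category.domain, r.category.subcategory,
         r.culture)
        for r in reports
    })
    N = len({c for (_, _, _, c) in triples})
    R_u: dict[str, int] = {}
    R_ucs: dict[tuple[str, str], int] = {}
    cultures_of: dict[str, set[str]] = {}
    sets_of: dict[str, set[str]] = {}
    for sp, domain, sub, culture in triples:
        if domain == "toxic":
            continue
        label = f"{domain}:{sub}" if sub else domain
        R_u[label] = R_u.get(label, 0) + 1
        if sub:
            R_u[domain] = R_u.get(domain, 0) + 1
        R_ucs[(sp, domain)] = R_ucs.get((sp, domain), 0) + 1
        cultures_of.setdefault(sp, set()).add(culture)
        sets_of.setdefault(culture, set()).add(sp)
    N_s = {sp: len(cs) for sp, cs in cultures_of.items()}
    FL = {u: Fraction(r, N) for u, r in R_u.items()}
    CII = {(sp, d): Fraction(r, N) for (sp, d), r in R_ucs.items()}
    RFC = {sp: Fraction(ns, N) for sp, ns in N_s.items()}
    UV = {sp: Fraction(R_ucs.get((sp, "medicinal"), 0), N_s[sp])
          for sp in N_s}
    return {"N": N, "R_u": R_u, "R_ucs": R_ucs, "N_s": N_s,
            "FL": FL, "CII": CII, "RFC": RFC, "UV": UV,
            "culture_sets": sets_of}
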