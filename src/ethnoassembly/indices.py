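"""Quantitative ethnobotanical indices adapted to genus-level, culture-unit data.

All four indices are exact integer ratios over counts held in a
:class:`~ethnoassembly.usedata.UseMatrix`.  The informant unit is the
*culture* (language family), not the individual interviewee, and the study
unit is a whole genus, which changes the usual bounds:

- Fidelity Level       FL_u   = R_u / N       (may exceed 1: many species of
                                               the genus can serve one use)
- Cultural Importance  CII_s  = R_uc,s / N    (per species, per domain)
- Rel. Freq. Citation  RFC_s  = N_s / N       (bounded by 1)
- Use Value            UV_s   = R_c,s / N_s   (medicinal only: food and
                                               ritual carry no subcategories)

where N is the number of cultures with any recorded use of the genus, R_u
the report-units for use u summed over all species and cultures, R_uc,s the
report-units of species s in a use domain, N_s the number of distinct
cultures reporting *any* (non-toxic) use of s, and R_c,s the medicinal
report-units of s.  Toxicity records are excluded by default: the matrix
keeps them, but they are caveats, not uses.

Internal arithmetic is exact (integer numerators and denominators); callers
round to 2 decimals only at export time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .usedata import UseCategory, UseMatrix

__all__ = [
    "IndexTable",
    "fidelity_level",
    "cultural_importance",
    "relative_frequency",
    "use_value",
    "index_table",
]

#: domains that count as "uses" for index purposes
USE_DOMAINS = ("food", "medicinal", "ritual", "cosmetic")
#: domains with their own CII per the adapted definition
CII_DOMAINS = ("medicinal", "food", "ritual")


def _active(matrix: UseMatrix, include_toxic: bool) -> pd.DataFrame:
    df = matrix.counts
    return df if include_toxic else df[df["domain"] != "toxic"]


def _use_mask(df: pd.DataFrame, use: "UseCategory | str") -> pd.Series:
    """Rows matching a use: a bare domain, or a (medicinal, subcategory) pair."""
    if isinstance(use, UseCategory):
        if use.subcategory:
            return (df["domain"] == use.domain) & (
                df["subcategory"] == use.subcategory)
        return df["domain"] == use.domain
    if ":" in use:
        domain, sub = use.split(":", 1)
        return (df["domain"] == domain) & (df["subcategory"] == sub)
    return df["domain"] == use


def fidelity_level(
    matrix: UseMatrix,
    use: "UseCategory | str",
    *,
    per_use_cultures: bool = False,
) -> float:
    """FL_u = R_u / N for one use (a domain, or ``"medicinal:<subcategory>"``).

    The denominator is the genus-level culture count N by default, which is
    what lets FL exceed 1.  ``per_use_cultures=True`` switches the
    denominator to the number of cultures recording that specific use
    (the conservative reading, always <= 1).
    """
    if matrix.N <= 0:
        raise ValueError("matrix has no cultures (N = 0)")
    df = _active(matrix, include_toxic=False)
    label = use.label if isinstance(use, UseCategory) else use
    known = set(df["domain"]).union(
        f"{d}:{s}" for d, s in zip(df["domain"], df["subcategory"]) if s)
    if label not in known and label not in USE_DOMAINS:
        raise KeyError(f"unknown use label {label!r}")
    sub = df[_use_mask(df, use)]
    r_u = int(sub["count"].sum())
    denom = sub["culture"].nunique() if per_use_cultures else matrix.N
    if denom == 0:
        return 0.0
    return r_u / denom


def cultural_importance(matrix: UseMatrix, species: str, domain: str) -> float:
    """CII_s = R_uc,s / N: report-units of ``species`` in ``domain`` over N."""
    if matrix.N <= 0:
        raise ValueError("matrix has no cultures (N = 0)")
    if species not in matrix.species_order:
        raise KeyError(f"species {species!r} not on matrix axis")
    df = _active(matrix, include_toxic=False)
    sub = df[(df["species"] == species) & (df["domain"] == domain)]
    return int(sub["count"].sum()) / matrix.N


def _n_s(matrix: UseMatrix, species: str) -> int:
    """Distinct cultures reporting any non-toxic use of the species."""
    df = _active(matrix, include_toxic=False)
    return int(df.loc[df["species"] == species, "culture"].nunique())


def relative_frequency(matrix: UseMatrix, species: str) -> float:
    """RFC_s = N_s / N: fraction of cultures reporting any use of the species."""
    if matrix.N <= 0:
        raise ValueError("matrix has no cultures (N = 0)")
    if species not in matrix.species_order:
        raise KeyError(f"species {species!r} not on matrix axis")
    return _n_s(matrix, species) / matrix.N


def use_value(matrix: UseMatrix, species: str) -> float | None:
    """UV_s = R_c,s / N_s: medicinal report-units over cultures citing s.

    Returns None (with a warning stating the reason) when N_s = 0, i.e. the
    species has no qualifying reports at all.
    """
    if species not in matrix.species_order:
        raise KeyError(f"species {species!r} not on matrix axis")
    n_s = _n_s(matrix, species)
    if n_s == 0:
        warnings.warn(f"UV undefined for {species!r}: no reporting cultures "
                      "(N_s = 0)", stacklevel=2)
        return None
    df = _active(matrix, include_toxic=False)
    r_cs = int(df.loc[(df["species"] == species)
                      & (df["domain"] == "medicinal"), "count"].sum())
    return r_cs / n_s


@dataclass
class IndexTable:
    """Per-use FL rows and per-species CII/RFC/UV rows, export-ready."""

    per_use: pd.DataFrame      # use, R_u, FL
    per_species: pd.DataFrame  # species, N_s, RFC, CII_<domain>, UV_medicinal
    N: int

    def to_long(self) -> pd.DataFrame:
        """Long export: entity_type, label, domain, R, N_denominator, value, index_name."""
        rows = []
        for r in self.per_use.itertuples():
            rows.append(("use", r.use, r.use.split(":")[0], r.R_u, self.N,
                         r.FL, "FL"))
        for r in self.per_species.itertuples():
            rows.append(("species", r.species, "", r.N_s, self.N, r.RFC, "RFC"))
            for domain in CII_DOMAINS:
                rows.append(("species", r.species, domain,
                             getattr(r, f"R_{domain}"), self.N,
                             getattr(r, f"CII_{domain}"), "CII"))
            rows.append(("species", r.species, "medicinal", r.R_medicinal,
                         r.N_s, r.UV_medicinal, "UV"))
        return pd.DataFrame(rows, columns=[
            "entity_type", "label", "domain", "R", "N_denominator",
            "value", "index_name"])


def index_table(matrix: UseMatrix) -> IndexTable:
    """All four indices for every species and every use in the matrix.

    Per-use rows cover each domain and each medicinal subcategory present;
    per-species rows are sorted descending by medicinal CII (ties broken by
    species name), matching the conventional importance ranking.
    """
    df = _active(matrix, include_toxic=False)
    if df.empty:
        warnings.warn("empty matrix: returning empty index table", stacklevel=2)
        empty_cols_use = ["use", "R_u", "FL"]
        empty_cols_sp = ["species", "N_s", "RFC"] + [
            f"R_{d}" for d in CII_DOMAINS] + [
            f"CII_{d}" for d in CII_DOMAINS] + ["R_medicinal", "UV_medicinal"]
        return IndexTable(pd.DataFrame(columns=empty_cols_use),
                          pd.DataFrame(columns=empty_cols_sp), matrix.N)

    use_rows = []
    uses: list[str] = [d for d in USE_DOMAINS if (df["domain"] == d).any()]
    subs = sorted(df.loc[df["domain"] == "medicinal", "subcategory"].unique())
    uses += [f"medicinal:{s}" for s in subs if s]
    for use in uses:
        sub = df[_use_mask(df, use)]
        use_rows.append({
            "use": use,
            "R_u": int(sub["count"].sum()),
            "FL": fidelity_level(matrix, use),
        })

    species_rows = []
    for sp in matrix.species_order:
        if not (df["species"] == sp).any():
            continue  # toxic-only species carry no use indices
        row: dict = {"species": sp, "N_s": _n_s(matrix, sp),
                     "RFC": relative_frequency(matrix, sp)}
        for domain in CII_DOMAINS:
            r_dom = int(df.loc[(df["species"] == sp)
                               & (df["domain"] == domain), "count"].sum())
            row[f"R_{domain}"] = r_dom
            row[f"CII_{domain}"] = cultural_importance(matrix, sp, domain)
        row["UV_medicinal"] = use_value(matrix, sp)
        species_rows.append(row)

    per_use = pd.DataFrame(use_rows)
    per_species = pd.DataFrame(species_rows)
    # column order: identity, denominator pieces, then indices
    per_species = per_species[
        ["species", "N_s", "RFC"]
        + [f"R_{d}" for d in CII_DOMAINS]
        + [f"CII_{d}" for d in CII_DOMAINS]
        + ["UV_medicinal"]
    ].rename(columns={"R_medicinal": "R_medicinal"})
    per_species = per_species.sort_values(
        ["CII_medicinal", "species"], ascending=[False, True]
    ).reset_index(drop=True)
    return IndexTable(per_use=per_use, per_species=per_species, N=matrix.N)
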