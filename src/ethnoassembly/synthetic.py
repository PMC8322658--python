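"""Seeded synthetic data with fully known ground truth.

Generates the three inputs the pipeline consumes — per-source nomenclatural
checklists, curated use-report tables, and a Newick phylogeny — from a
ground-truth model, and records every intermediate count the downstream
stages are supposed to recover (accepted species list and oracle curator
decisions; intended R_u, R_uc,s, N_s, N; per-culture species sets).  All
randomness flows through one integer-seeded ``numpy.random.Generator``, so
identical configs give byte-identical outputs.

The default configuration emulates the *structure* of a genus-level
cross-cultural survey: a few dozen used species split between an Old World
and a New World clade, ~25 cultures keyed by 3-letter language-family
codes, food reports dense enough that the genus-level Fidelity Level
exceeds 1, medicinal reports spread over ICD-style organ-system
subcategories with occasional emic (culture-internal) labels, and
checklists that disagree through random omissions and injected
synonyms/varieties.  Everything it emits is synthetic — names, codes and
counts are generated, not transcribed from any real survey.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

from .taxonomy import CanonicalName, CuratorDecision, SourceChecklist
from .usedata import UseCategory, UseReport

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_checklists",
    "generate_use_reports",
    "generate_tree",
    "paper_like_config",
]

#: ICD-style organ-system subcategory labels for medicinal reports
MEDICINAL_SUBCATEGORIES = (
    "spleen", "brain", "skin", "eye", "MSK", "kidney", "heart", "lung",
    "dental", "liver", "blood", "fever",
)

GENUS = "Synthicum"  # deliberately invented genus: all data is synthetic

_SYL_A = ("al", "be", "cor", "del", "er", "fol", "gra", "hum", "in", "ju",
          "kal", "lon", "mon", "nig", "ov", "pal", "qua", "rub", "sub", "tor",
          "um", "vel", "wil", "xan", "yun", "zon")
_SYL_B = ("bense", "catum", "dense", "fera", "gense", "licum", "mense",
          "noides", "pense", "ricum", "sense", "tense", "vense", "xense")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic world; the defaults are the study conditions.

    ``intensity`` values are expected report-units per co-occurring
    species-culture pair (a unit being one distinct species x culture x
    category triple).  ``p_same_region``/``p_cross_region`` set how likely a
    culture is to use a species of its own vs. the other region, producing
    the regional high-similarity blocks real surveys show.
    """

    seed: int                     # mandatory: all randomness derives from it
    n_species: int = 36           # used species
    n_cultures: int = 25
    n_checklist_species: int | None = None  # accepted names in the genus
    old_world_fraction: float = 0.5
    p_same_region: float = 0.35
    p_cross_region: float = 0.05
    intensity: dict[str, float] = field(default_factory=lambda: {
        "food": 0.25, "medicinal": 0.5, "ritual": 0.04,
        "cosmetic": 0.03, "toxic": 0.03,
    })
    emic_indication_rate: float = 0.15
    duplicate_source_rate: float = 0.10  # same triple echoed by a 2nd source
    omission_rate: float = 0.10
    synonym_injection_rate: float = 0.10
    variety_injection_rate: float = 0.05
    source_ids: tuple[str, ...] = ("COL", "POWO", "WFO", "TPL")

    def __post_init__(self) -> None:
        for name in ("old_world_fraction", "p_same_region", "p_cross_region",
                     "emic_indication_rate", "duplicate_source_rate",
                     "omission_rate", "synonym_injection_rate",
                     "variety_injection_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_species < 1 or self.n_cultures < 1:
            raise ValueError("n_species and n_cultures must be >= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class GroundTruth:
    """Everything the pipeline is supposed to recover, recorded at birth.

    Index intentions (``R_u``, ``R_ucs``, ``N_s``, ``N``, ``culture_sets``)
    are counted directly from the generated triple list with plain
    set/dict arithmetic, independently of the pipeline's matrix code.
    """

    accepted_species: list[str] = field(default_factory=list)
    species_region: dict[str, str] = field(default_factory=dict)
    culture_region: dict[str, str] = field(default_factory=dict)
    oracle_decisions: list[CuratorDecision] = field(default_factory=list)
    injected: dict[str, list[str]] = field(default_factory=dict)  # per source
    N: int = 0
    R_u: dict[str, int] = field(default_factory=dict)
    R_ucs: dict[tuple[str, str], int] = field(default_factory=dict)
    N_s: dict[str, int] = field(default_factory=dict)
    culture_sets: dict[str, set[str]] = field(default_factory=dict)
    newick: str = ""


# ---------------------------------------------------------------------------
# Names and codes


def _species_names(rng: np.random.Generator, n: int) -> list[str]:
    epithets: list[str] = []
    seen: set[str] = set()
    suffix = 0
    while len(epithets) < n:
        e = (_SYL_A[rng.integers(len(_SYL_A))]
             + _SYL_B[rng.integers(len(_SYL_B))])
        if e in seen:  # syllable space is finite; disambiguate
            suffix += 1
            e = f"{e}{suffix}"
        seen.add(e)
        epithets.append(e)
    return [f"{GENUS} {e}" for e in epithets]


def _culture_codes(rng: np.random.Generator, n: int) -> list[str]:
    codes: list[str] = []
    seen: set[str] = set()
    letters = string.ascii_lowercase
    while len(codes) < n:
        c = "".join(letters[rng.integers(26)] for _ in range(3))
        if c not in seen:
            seen.add(c)
            codes.append(c)
    return codes


def _split_regions(rng: np.random.Generator, items: list[str],
                   old_fraction: float) -> dict[str, str]:
    n_old = int(round(len(items) * old_fraction))
    shuffled = list(items)
    rng.shuffle(shuffled)
    return {x: ("OldWorld" if i < n_old else "NewWorld")
            for i, x in enumerate(shuffled)}


# ---------------------------------------------------------------------------
# Checklists


def generate_checklists(
    config: SimulationConfig,
) -> tuple[list[SourceChecklist], list[CuratorDecision], GroundTruth]:
    """Per-source checklists = truth minus omissions plus injected errors.

    Each source drops each accepted name with probability ``omission_rate``
    and gains synonym injections (fake names listed as accepted only there)
    and variety injections (infraspecific names, removable by rule alone).
    The oracle decisions resolve every name the rules cannot: ``accept``
    for true names missing from some source, ``reject_synonym`` for every
    injected synonym.  Round-tripping through the reconciliation engine
    must return exactly the truth list.
    """
    rng = np.random.default_rng(config.seed)
    n_list = config.n_checklist_species or config.n_species
    names = _species_names(rng, n_list * (1 + len(config.source_ids)))
    truth = names[:n_list]
    fake_pool = iter(names[n_list:])

    checklists: list[SourceChecklist] = []
    injected: dict[str, list[str]] = {}
    present_in: dict[str, set[str]] = {b: set() for b in truth}
    for source_id in config.source_ids:
        entries: list[tuple[str, str, str]] = []
        for b in truth:
            if rng.random() >= config.omission_rate:
                entries.append((b, "Auct.", "accepted"))
                present_in[b].add(source_id)
        inj: list[str] = []
        n_syn = rng.binomial(n_list, config.synonym_injection_rate)
        for _ in range(n_syn):
            fake = next(fake_pool)
            entries.append((fake, "Auct.", "accepted"))
            inj.append(fake)
        n_var = rng.binomial(n_list, config.variety_injection_rate)
        var_seen = set()
        for _ in range(n_var):
            base = truth[rng.integers(len(truth))]
            epithet = _SYL_A[rng.integers(len(_SYL_A))] + "ana"
            name = f"{base} var. {epithet}"
            if name not in var_seen:  # avoid duplicate rows within a source
                var_seen.add(name)
                entries.append((name, "", "accepted"))
        if not entries:
            raise ValueError(
                f"omission_rate {config.omission_rate} emptied source "
                f"{source_id}; lower it or raise n_species")
        injected[source_id] = inj
        checklists.append(SourceChecklist(source_id=source_id, entries=entries))

    # names omitted from every source are unreachable: drop them from truth
    truth = [b for b in truth if present_in[b]]
    decisions: list[CuratorDecision] = []
    for b in truth:
        if len(present_in[b]) < len(config.source_ids):
            decisions.append(CuratorDecision(
                b, "accept", "synthetic oracle: true accepted name"))
    for source_id, fakes in injected.items():
        for fake in fakes:
            decisions.append(CuratorDecision(
                fake, "reject_synonym",
                f"synthetic oracle: synonym injected into {source_id}"))

    gt = GroundTruth(accepted_species=list(truth),
                     oracle_decisions=decisions, injected=injected)
    return checklists, decisions, gt


# ---------------------------------------------------------------------------
# Use reports


def generate_use_reports(
    config: SimulationConfig,
) -> tuple[list[UseReport], GroundTruth]:
    """Seeded use-report table plus the intended index bookkeeping.

    Cultures and species are split between regions; a culture's species
    pool is drawn with ``p_same_region`` for its own region and
    ``p_cross_region`` across, every culture keeping at least one species.
    For each pooled pair, single-category domains (food, ritual, cosmetic,
    toxic) contribute a Bernoulli report-unit and the medicinal domain a
    Poisson number of distinct subcategories.  A fraction of triples is
    echoed under a second literature reference to exercise deduplication.
    """
    # species names replay generate_checklists' stream so that the used
    # species are a subset of the genus checklist for the same config
    name_rng = np.random.default_rng(config.seed)
    n_list = config.n_checklist_species or config.n_species
    all_names = _species_names(name_rng,
                               n_list * (1 + len(config.source_ids)))
    species = all_names[:config.n_species]
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 7]).generate_state(1)[0])
    cultures = _culture_codes(rng, config.n_cultures)
    sp_region = _split_regions(rng, species, config.old_world_fraction)
    cu_region = _split_regions(rng, cultures, config.old_world_fraction)

    triples: list[tuple[str, str, str, str]] = []  # species, domain, sub, culture
    for culture in cultures:
        n_before = len(triples)
        pool = [
            sp for sp in species
            if rng.random() < (config.p_same_region
                               if sp_region[sp] == cu_region[culture]
                               else config.p_cross_region)
        ]
        if not pool:
            same = [sp for sp in species
                    if sp_region[sp] == cu_region[culture]] or species
            pool = [same[rng.integers(len(same))]]
        for sp in pool:
            for domain in ("food", "ritual", "cosmetic", "toxic"):
                if rng.random() < config.intensity.get(domain, 0.0):
                    triples.append((sp, domain, "", culture))
            n_med = rng.poisson(config.intensity.get("medicinal", 0.0))
            n_med = min(n_med, len(MEDICINAL_SUBCATEGORIES))
            if n_med > 0:
                picks = rng.choice(len(MEDICINAL_SUBCATEGORIES),
                                   size=n_med, replace=False)
                for idx in sorted(picks):
                    if rng.random() < config.emic_indication_rate:
                        sub = f"emic_{culture}_{idx}"
                    else:
                        sub = MEDICINAL_SUBCATEGORIES[idx]
                    triples.append((sp, "medicinal", sub, culture))
        if len(triples) == n_before:
            # a culture is in the dataset only through its reports: give a
            # reportless culture one food record for its first pool species
            triples.append((pool[0], "food", "", culture))

    reports: list[UseReport] = []
    for i, (sp, domain, sub, culture) in enumerate(triples):
        category = UseCategory(domain=domain, subcategory=sub,
                               emic_flag=sub.startswith("emic_"))
        name = CanonicalName(sp, "Auct.")
        reports.append(UseReport(species=name, category=category,
                                 culture=culture, source_ref=f"ref{i:04d}"))
        if rng.random() < config.duplicate_source_rate:
            reports.append(UseReport(species=name, category=category,
                                     culture=culture,
                                     source_ref=f"ref{i:04d}b"))

    # --- intended bookkeeping, by direct counting over the triple set ----
    gt = GroundTruth(species_region=sp_region, culture_region=cu_region)
    unique = sorted(set(triples))
    gt.N = len({c for (_, _, _, c) in unique})
    for sp, domain, sub, culture in unique:
        if domain != "toxic":
            label = f"{domain}:{sub}" if sub else domain
            gt.R_u[label] = gt.R_u.get(label, 0) + 1
            gt.R_u[domain] = gt.R_u.get(domain, 0) + (1 if sub else 0)
            gt.R_ucs[(sp, domain)] = gt.R_ucs.get((sp, domain), 0) + 1
            gt.culture_sets.setdefault(culture, set()).add(sp)
    per_species_cultures: dict[str, set[str]] = {}
    for sp, domain, sub, culture in unique:
        if domain != "toxic":
            per_species_cultures.setdefault(sp, set()).add(culture)
    gt.N_s = {sp: len(cs) for sp, cs in per_species_cultures.items()}
    gt.accepted_species = sorted({sp for sp, _, _, _ in unique})
    return reports, gt


# ---------------------------------------------------------------------------
# Tree


def _random_subtree(rng: np.random.Generator, tips: list[str]) -> str:
    nodes = [tip.replace(" ", "_") for tip in tips]
    while len(nodes) > 1:
        i = int(rng.integers(len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(len(nodes)))
        b = nodes.pop(j)
        la = round(float(rng.uniform(0.01, 0.2)), 4)
        lb = round(float(rng.uniform(0.01, 0.2)), 4)
        nodes.append(f"({a}:{la},{b}:{lb})")
    return nodes[0]


def generate_tree(truth: GroundTruth, seed: int) -> str:
    """Random rooted bifurcating Newick tree with region-clustered topology.

    The two deepest clades are the Old World and New World species blocks
    (purity 1 by construction), mirroring a biogeographically structured
    gene tree.  Tip labels are underscore-joined binomials.
    """
    if not truth.accepted_species:
        raise ValueError("species list is empty")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 13])
                                .generate_state(1)[0])
    regions: dict[str, list[str]] = {}
    for sp in truth.accepted_species:
        regions.setdefault(truth.species_region.get(sp, "OldWorld"),
                           []).append(sp)
    clades = [_random_subtree(rng, tips)
              for _, tips in sorted(regions.items()) if tips]
    if len(clades) == 1:
        return f"{clades[0]};"
    return f"({clades[0]}:0.1,{clades[1]}:0.1);"


def paper_like_config(seed: int) -> SimulationConfig:
    """The packaged demo preset: a genus-scale survey shape (dozens of used
    species out of ~100 accepted names, ~25 cultures, an Old/New World
    split, food reports dense enough for FL > 1).  Entirely synthetic."""
    return SimulationConfig(seed=seed, n_species=36, n_cultures=25,
                            n_checklist_species=100)
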