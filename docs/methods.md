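# Methods

## Scope and data model

The package operates on three curated inputs: per-source species
checklists from nomenclatural databases (name, author, status), a
curator-decision table for disputed names, and a use-report table in which
one row records that a species is used for a category by a culture,
traceable to a literature source. A Newick phylogeny of the genus may be
supplied; tree inference itself (alignment, ML search, bootstrap) is out
of scope — the tree is consumed, not built. Likewise out of scope are live
database queries and text mining: all inputs are files.

## Taxonomic reconciliation

Names are normalized before matching: whitespace collapsed, genus
capitalized, epithet lowercased, infraspecific markers (`var.`, `subsp.`,
`f.`) and hybrid signs (`×` U+00D7 or ASCII `x ` before an epithet)
stripped into rank flags. The matching key is the rank-stripped binomial —
databases cite authorities too inconsistently for the author string to
participate in identity — and author disagreements are flagged, never
silently merged. An infraspecific entry keeps its own comparison row so it
cannot drag its parent species down with it.

The five revision rules run per name, in order: (1) accepted in every
external source → accepted; (2) rank-flagged → removed; (3)/(4) accepted
in a strict subset of sources → resolved by the curator decision
(`accept`, `reject_invalid`), or queued for review when no decision
exists — this judgement needs protologues and specimens and is
deliberately not automated; (5) `reject_synonym` → removed. The audit
trail records the deciding rule for every input name. The unanimity test
of rule 1 defaults to all provided sources but accepts an explicit subset,
because which databases should vote is an editorial choice, not a fact of
the data. The revised list joins the UpSet summary as an additional set,
but never votes in rule 1.

A TPL-style `unresolved` status is kept as its own cell value in the
comparison table and treated as non-accepted by the rules, so the
information survives into exports.

UpSet counts are *exclusive*: each name is tallied under the exact subset
of sources containing it, so the counts partition the union — the
conservation identity Σ exclusive = |union| is asserted in tests on
random set families.

## Use matrix

Cultures are identified at language-family granularity by 3-letter codes;
an exceptions list covers languages treated as independent cultures
despite belonging to a registered family (e.g. `jpn`, `kor`). Custom codes
are allowed but must not shadow registry codes, and their creation is
logged.

Medicinal indications map to ICD-11-style organ-system labels through a
curated table; unmapped labels are retained verbatim as *emic* solitary
subcategories rather than dropped, since culture-internal disease concepts
are data, not noise. The shipped demo mapping is illustrative, not a
reconstruction of any published table.

The counting unit is configurable because literature-derived "number of
reports" is ambiguous: the default unit is a distinct (species, culture,
category) triple, which makes the indices independent of how many
publications repeat a claim; `count_unit="source"` instead counts distinct
(species, culture, category, reference) tuples. N is the number of
distinct cultures with at least one surviving report. Toxicity records
ride along in the matrix under `domain = toxic` but are excluded from all
indices and from Jaccard species sets by default.

## Indices

All indices are exact integer ratios (see README for the formulas);
values render to 2 decimals only at export. Two definitional choices
matter and are applied uniformly:

- FL's denominator is the dataset-level N, not the per-use culture count.
  This is what allows FL > 1 for a genus (many species per use); the
  per-use denominator remains available as an option.
- N_s counts cultures reporting *any* non-toxic use of the species, and
  the same N_s serves RFC and UV.

A species with only toxic records has no index rows; UV is null (with an
explicit reason) when N_s = 0, and 0 when the species is used but not
medicinally. The index table is ordered by descending medicinal CII.

## Cross-cultural similarity

JI is computed on the pooled species set of each culture across all
non-toxic domains (per-domain matrices via a flag). 0/0 pairs are null,
not 0, to keep "no data" distinct from "no overlap". 1 − JI/100 is the
Jaccard distance, a metric on non-empty sets; the triangle inequality is
property-tested. Output ordering is lexicographic by default, or
average-linkage dendrogram leaf order for heatmaps.

## Phylogeny overlay

Tip labels match species case-insensitively and underscore/space-
insensitively on the binomial only. Matrix rows are reordered to tip
order; unmatched tips and unplaced species are listed, never dropped.
Per-clade summaries report tip count, used-tip count, used fraction and
distinct domain count — a descriptive "hot clade" score, not a
statistical claim; no phylogenetic-signal statistics are computed.

## Synthetic data generator

The generator emulates the *structure* of a genus-scale literature
survey, with known ground truth for every pipeline stage:

- Checklists: each source is the true accepted list minus
  Binomial(omission_rate) names, plus injected fake synonyms (accepted
  only in that source) and infraspecific variants. The oracle decision
  table resolves exactly what the rules cannot, so reconciliation must
  round-trip to the truth list.
- Use reports: species and cultures split between two regions (default
  fraction 0.5, after the genus's Old World / New World biogeography); a
  culture's species pool is drawn with probability 0.35 within its region
  and 0.05 across, which produces the regional high-similarity blocks
  real surveys show. Single-category domains contribute Bernoulli
  report-units per pooled pair (defaults: food 0.25, ritual 0.04,
  cosmetic 0.03, toxic 0.03) and the medicinal domain a Poisson(0.5)
  number of distinct organ-system subcategories, 15% of them emic. These
  defaults put the genus-scale preset (36 used species, 25 cultures,
  ~100-name checklist) in the regime real genus-level surveys report:
  food FL above 1, ritual and cosmetic FL well below 1, RFC sparse.
  A culture that draws no reports receives one food record, since a
  culture enters a literature-derived dataset only through reports.
- Tree: random bifurcating topology whose two deepest clades are the two
  regional species blocks (purity 1 by construction).

All randomness flows through one integer-seeded `numpy.random.Generator`
with integer draw paths for counts, so outputs are byte-identical across
runs and platforms. The intended index bookkeeping (R_u, R_uc,s, N_s, N,
per-culture species sets) is counted directly from the generated triples
with plain set arithmetic, independently of the pipeline containers.

What the generator does *not* emulate: citation structure of the
literature (every triple is equally credible), orthographic name variants
beyond rank markers, within-family language diversity, and any real
species' identity — names are pseudo-Latin inventions under the invented
genus *Synthicum*. Passing tests therefore demonstrate arithmetic and
bookkeeping correctness on realistically shaped data, not the curation
quality of any real dataset.

## Numerical and testing choices

Index equality in tests is exact (integer-ratio arithmetic; the brute-
force oracle computes the same integers via `fractions.Fraction`).
Property suites run on deliberately small worlds (8 species × 6 cultures,
100 seeds; 12-name checklists, 100 families; 1000 set triples) so the
whole suite stays in the tens of seconds while still exercising every
code path; the genus-scale preset is used where the FL > 1 regime or the
Old/New World structure matters. The acceptance script runs that preset
end to end and reports only quantities it computed in that run.

## Known limitations

- Rules 3–4 are only as good as the curator-decision table; the engine
  never guesses at disputed names.
- Indices treat all cultures as equally weighted informants; there is no
  informant-level or population-size weighting.
- JI is reported raw, without permutation nulls or significance tests.
- The heatmap exports are plain CSVs; publication-grade figure styling is
  left to dedicated tools.
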