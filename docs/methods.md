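# Methods

## The authentication model

`cordytrace` treats geographic-origin authentication as presence/absence
lookup in a reference incidence structure, not as statistical assignment.
The unit of evidence is the *combined haplotype*: the concatenation of a
specimen's fungal ITS haplotype code and its host-insect COI haplotype code.
Haplotypes are exact-identity classes — two sequences belong to the same
haplotype only if they are byte-identical after uppercasing and U→T
mapping. No alignment is performed (sequences of different length are
distinct haplotypes) and IUPAC ambiguity codes are not expanded; resolving
ambiguous base calls is an upstream chromatogram-editing task, and identity
downstream must be deterministic. This makes the method exquisitely
sensitive to single substitutions, which is the point: origin discrimination
lives in low-level sequence variation, but it equally means that sequencing
error directly inflates the haplotype count, so the reference database must
be built from bidirectionally sequenced, manually checked reads.

A county is the locality unit, always keyed by the full
(province, prefecture, county) triple since county names repeat across
provinces. Traceability is a deterministic function of the incidence table:

* **traceable** — every combined haplotype in the county is county-unique;
* **conditionally traceable** — at least one unique and one shared;
* **untraceable** — only shared haplotypes; the sample traces to the set of
  counties holding that haplotype (`trace_origin` returns that set).

Sharing is annotated at two administrative scopes: across provinces, and
across prefectures within one province. The footnote rendered for a table
row is computed in the row's provincial context: a haplotype spanning five
Qinghai prefectures and one Gansu prefecture is cross-province everywhere,
but its within-province annotation appears only in Qinghai rows. Sharing
between counties of a single prefecture carries no annotation.

A query haplotype absent from the reference table has no defined origin;
the lookup raises an error that lists reference codes sharing either marker
component as a diagnostic hint. This is deliberately not an assignment
method — extending the approach to unseen haplotypes would require a model
of haplotype spatial turnover that presence/absence data cannot support.

## Code assignment

COI haplotypes are numbered by decreasing frequency (`H01` most frequent);
equal counts are broken by first occurrence in input order, a repository
convention chosen because any fixed, documented tie rule makes re-analysis
reproducible. ITS numbering may be inherited from earlier work through a
numbering reference (sequence → code); inherited numbering can contain gaps
(codes `F14` and `F18` are absent from the packaged table), and novel
sequences continue after the reference maximum. Codes are zero-padded to
width 2 and grow naturally (`F100`) without renumbering.

## The packaged reference table

`cordytrace/data/table1_counties.tsv` transcribes a published county-level
authentication of 215 specimens from 75 counties: marker and combined
haplotype codes, sharing annotations, the per-county classification label
and the core-production status. The loader validates the row count, the
decomposition of every combined code into the row's marker code lists, and
sample-size consistency. Two cells are stored in corrected, internally
consistent form (documented in `cordytrace.io`): the Sêrxü ITS cell (`F01`,
fixed by its combined haplotype `F01H59`), and the sharing footnote on
`F03H07`, whose two counties lie in the same prefecture and therefore
cannot carry the cross-prefecture annotation. With these corrections every
derived statistic in the test suite — classification labels, footnotes,
traceability tallies, per-province haplotype counts, core statuses — is
reproduced from the raw incidence with zero mismatches. Note that the table
yields 87 combined haplotypes confined to a single county (12 are shared);
the per-haplotype specimen counts within multi-haplotype counties are not
part of the table, so the fixture stores incidence, not within-county
abundances.

## Core delimitation

The core criteria configuration (`cordytrace/data/core_criteria.yaml`)
ships the explicit hallmark sets: core ITS haplotypes
{F01, F04, F07, F19, F23} and 24 core COI haplotypes. A combined haplotype
is core when both components are core; this both-components rule is the
package's formalisation and reproduces the published list of 26 core
combined haplotypes exactly, which is its justification. County status is
all/none/otherwise → core/non-core/mixed.

For new datasets a derivation mode exists: a marker haplotype is core when
its clade (from a user-supplied clade map) is a core clade and/or it is
observed in a configured core reference region, with the conjunction
controlled by `region_rule` (`and`/`or`/`ignore`). Region presence is kept
configurable rather than mandatory because three of the packaged core ITS
haplotypes are not observed in any listed core reference region — presence
cannot be a necessary condition — so only the explicit packaged sets
reproduce the published delimitation. One packaged core COI haplotype
(H51) participates in no core combination because its only observed partner
is a non-core ITS haplotype; the classifier carries it without effect.

## Tree machinery

The phylogeny module exists solely to derive clade maps on self-contained
(e.g. synthetic) datasets: uncorrected p-distance (sites with non-ACGT
characters in either sequence are excluded from numerator and denominator),
Saitou–Nei neighbor joining, column-resampling bootstrap, and minimal
edge-cut clade extraction on the unrooted tree. NJ ties in the Q-criterion
are broken by the lexicographically smallest cluster-key pair (a cluster's
key is its smallest leaf label), so results are independent of input order;
negative branch lengths are clamped to zero and flagged. On additive
matrices the tree reproduces all pairwise path lengths to 1e-9 (tested
against independently constructed random additive trees, and cross-checked
topologically against dendropy's NJ). Model-based inference (ML, Bayesian)
and model-corrected distances are out of scope; clade membership for real
data is consumed as configuration because no published leaf-to-clade table
exists for this system, making those clades irreproducible from first
principles here. Haplotype sequences of one marker share a single length in
this system, so no aligner is provided; unequal lengths are rejected.

## Synthetic data generator

The generator emulates the reference collection's structure so every
pipeline stage is testable without external downloads:

* **Geography:** 75 counties in 5 provinces (43 Xizang, 14 Qinghai,
  13 Sichuan, 3 Gansu, 2 Yunnan) with the reference per-county sample sizes
  (total n = 215, from 1 to 57 per county).
* **Sequences:** ITS 580 bp, COI 1009 bp. Haplotype pools are derived from
  one random ancestor per marker; each haplotype carries a private marker
  substitution (guaranteeing pairwise distinctness) plus extra substitutions
  at 0.003/site, a rate giving within-marker divergences of a few sites to
  ~1%, comparable to shallow intraspecific barcode variation.
* **Spectra:** ITS mass 123/215 (57.2%) and 44/215 (20.5%) on the two
  dominant haplotypes, 22 further haplotypes with 1–10 specimens; COI
  45/34/17/14 on the four dominant haplotypes, 15 mid-rank haplotypes with
  2–8, and 59 of 78 haplotypes (75.6%) singletons. Within-county haplotype
  frequencies of the real collection are unpublished, so the non-dominant
  masses are fixed plausible vectors calibrated once to these global
  statistics.
* **Modes:** `default_profile()` draws each specimen's two marker codes
  independently from the global spectra (counties unrestricted), so the
  leading-haplotype frequency is Binomial(215, 0.572)-calibrated by
  construction. `fixture_profile()` restricts each county to its published
  combined haplotypes, weights them by the global spectra renormalised to
  the county composition, and draws every allowed (county, haplotype) pair
  at least once, so the generated incidence table equals the reference
  incidence deterministically while counts remain stochastic.

Everything is driven by one `numpy` generator seed; generation is
byte-deterministic given the seed. The truth set records per-specimen codes,
the haplotype pools (usable as numbering references so the pipeline
reproduces truth codes, not merely a relabelling) and the true incidence
table.

What passing the round-trip tests shows: the pipeline inverts the generator
exactly — partition identity, code identity given the reference, incidence
identity. What it does not show: robustness to the failure modes of real
data (sequencing error, length variation from indel-bearing markers, ITS
paralogs/pseudogenes, incomplete sampling of county compositions), none of
which the generator simulates.

## Numerical and design choices

* Primer trimming searches the forward primer (Hamming distance, no indels,
  default max 2 mismatches) with its start in the first 30% of the read and
  the reverse-complemented reverse primer with its end in the last 30%;
  ties prefer the outermost hit; an absent primer leaves that end untouched
  and is flagged, making trimming idempotent. This is conservative plumbing
  for pre-assembled reads, not an adapter-trimming algorithm.
* Specimens missing either marker are excluded at load with a logged
  reason: combined haplotypes are undefined for them.
* All tabular outputs sort province → prefecture → county for reproducible
  diffs.
* Problem sizes in tests and in the acceptance script are the study's own
  (75 counties, 215 specimens, trees of ≤ 9 leaves, bootstraps of ≤ 25
  replicates) — the pipeline is combinatorial, not asymptotic, and these
  sizes exercise every code path.

## Known limitations

* Authentication is only as strong as the reference database; a haplotype
  absent from the reference cannot be traced, and single substitutions
  create new haplotypes by design.
* The incidence table stores presence, not abundance; counties sampled with
  one specimen contribute one haplotype regardless of their true diversity,
  and sampling imbalance (1–57 specimens per county) biases which
  haplotypes appear shared.
* The core delimitation is a formalisation of a trade consensus, not a
  quality measurement; nothing in the package links haplotypes to
  metabolite or contaminant levels.
* The bootstrap transplants column resampling onto NJ trees; supports are
  comparable between runs of this package but not to published ML/Bayesian
  support values.
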