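# Methods

`its2barcode` evaluates how well the short ITS2 spacer performs as a DNA
"minibarcode" relative to the full-length nuclear ribosomal ITS region
(ITS1 + 5.8S + ITS2). The package implements the desk half of a
two-locus barcode evaluation: corpus curation, ITS2 excision from
full-length records, pairwise genetic distances, barcode-gap summary
statistics with a paired signed-rank locus comparison, and leave-one-out
species identification under three criteria. Because the GenBank corpora
such studies are run on are not redistributable, a synthetic-corpus
generator with known ground truth is a first-class component: every
downstream stage can be validated against planted structure.

## Synthetic corpora

A corpus is grown on a three-level hierarchy: per-genus root sequences,
per-species ancestors derived from the root, and per-sample sequences
derived from the species ancestor. Each record is the concatenation

    [18S tail, 60 nt] ITS1 [5.8S, 160 nt] ITS2 [28S head, 60 nt]

where the spacers (ITS1, ITS2) of each genus root are uniform random
nucleotides and the conserved segments are copied from fixed synthetic
reference motifs (`REF_5_8S`, `REF_FLANK_18S`, `REF_FLANK_28S`). The
motifs are arbitrary fixed sequences, not real rRNA; they exist so that
region annotation can be exercised without any database download, and
profiles built from them must not be used for biological data.

Substitutions are per-site independent with a fixed transition bias
(default ts:tv = 2:1); there is no rate heterogeneity across sites, no
indel length spectrum (indels are single-base, spacers only, applied
after substitutions), and no coalescent genealogy. The divergence
parameters are calibrated as expected *pairwise* distances: two tips
whose branches each mutate sites with probability d/2 differ at
approximately `2m − 1.375 m²` of sites with `m = d/2` under the 2:1
model, i.e. ≈ d for small d. Concretely:

| parameter | meaning | default |
|---|---|---|
| `d_intra` | expected pairwise divergence between conspecific samples (spacer sites) | 0.015 |
| `d_inter` | expected pairwise divergence between congeneric species ancestors (spacer sites) | 0.07 |
| `conserved_rate_5_8s` | same, for 5.8S and flank sites | 0.002 |
| `indel_rate` | per-site single-base indel probability, spacers only | 0.001 |
| `len_its1`, `len_5_8s`, `len_its2`, `len_flank` | segment length ranges | centred so full ITS ≈ 634 nt, ITS2 ≈ 233 nt |
| `ts_tv_ratio` | transition:transversion bias | 2.0 |

The length defaults match the average lengths reported for plant ITS
(~634 nt) and ITS2 (~233 nt) in large surveys; the divergence defaults
sit in the regime of published ITS barcode-gap tables (mean
intraspecific distance near 0.015, congeneric interspecific near 0.07).
Sampling defaults (2–8 species per genus, 1–4 samples per species)
reproduce the skew of real barcode corpora, where many species are
singletons. Because real ITS data additionally carry rate heterogeneity,
paralogous copies, chimeras and mislabelled taxonomy, passing tests on
these corpora demonstrate correctness of the *computations*, not
expected performance on any particular biological dataset.

## Region annotation

Full-length records are annotated by placing two conserved motifs — the
5.8S gene and the 5' flank of 28S — with per-motif profile models:
position-specific log-odds emissions (bits, against a uniform 0.25
background) with affine insert/delete penalties, decoded by a Viterbi
dynamic programme that is global over the profile and local over the
sequence. ITS2 is the interval between the end of the 5.8S placement
and the start of the 28S-flank placement. Numerical choices:

* profile emissions: `(count + pseudocount) / (n + 4·pseudocount)` per
  alignment column, columns with >50% gaps dropped; default pseudocount
  0.5;
* penalties: insert/delete open −6 bits, extend −1 bit; score threshold
  10 bits per motif (a random placement scores far below 0; an intact
  160-nt motif scores ≈ 2 bits/position);
* ties: the earliest placement end wins, then the latest compatible
  start (both resolved deterministically inside the DP);
* orientation: both strands are scored; the record is flipped only when
  the reverse complement wins for *both* motifs;
* conflicts: if the two placements overlap or are out of order, the
  lower-scoring motif is rejected (status `NO_FLANK` when the flank is
  rejected); a missing flank truncates ITS2 to the sequence end
  (`TRUNCATED`); a missing 5.8S makes excision impossible (`NO_5_8S`).

The ITS1 interval starts at position 0 and therefore includes any
leading 18S tail; only the 5.8S placement delimits regions on the 5'
side. Consequently the "ITS" locus used in two-locus comparisons is
everything up to the 28S-flank start. Both conventions are recorded in
the annotation table (0-based, half-open, like all coordinates here).

## Distances

Each pair of sequences is aligned once by global Needleman–Wunsch with
affine gaps (match +1, mismatch −1, gap open −5, extend −2; a gap of
length L costs `open + (L−1)·extend`). Columns with a gap or any
non-ACGT symbol in either row are excluded (pairwise deletion); the
remaining columns yield transition/transversion counts, from which both
distances derive:

* p-distance: `(ts + tv) / n_compared`;
* Kimura 2-parameter: `−½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)` with
  `P = ts/n`, `Q = tv/n`; undefined (NaN) at saturation, counted and
  excluded from all summaries.

K2P is the default for divergence summaries (the convention of the
barcoding literature the six parameters come from); uncorrected
p-distance drives the nearest-neighbour identification criteria (the
convention of the TaxonDNA-style programs they mirror). Distances are
pairwise, not from a multiple alignment; per-pair optimal alignment is
tractable at desk scale and avoids an MSA-tool dependency.

## Divergence summaries and locus comparison

Six parameters summarize a labelled distance matrix. Intraspecific
(species with ≥2 samples): the mean over species of per-species mean
conspecific distance (`avg_intra_avg`, "average intraspecific
difference"); the mean over species of per-species maximum
(`avg_intra_max`, "average coalescent depth"); the pooled mean over all
conspecific pairs (`avg_intra_between_intra_species`, the theta
analogue). Interspecific (congeneric heterospecific pairs only): mean
over genera of per-genus means (`avg_interbyG_avg`, theta prime); mean
over species of each species' nearest heterospecific congener
(`avg_interbyG_min`, smallest interspecific distance); the pooled mean
(`avg_between_interbyGenus`, average interspecific distance). The ± 
values are sample standard deviations over the corresponding averaging
units, unweighted (no sample-size weighting of species or genera),
reported to 4 decimals.

The two loci are compared with a Wilcoxon signed-rank test paired at the
level of individual sequence pairs — the same pair of records measured
on each locus — separately for conspecific and congeneric-heterospecific
pairs. This pairing unit is chosen because it yields the large n values
such comparisons report, far exceeding species or genus counts. Zero
differences are dropped; midranks are used for ties; the two-sided
p-value is exact for n ≤ 25 (the null rank-sum distribution built by
convolution, equivalent to enumerating all 2ⁿ sign vectors) and a normal
approximation with tie correction (−Σ(t³−t)/48 on the variance) and 0.5
continuity correction beyond.

## Identification criteria

Every record is queried once against all others in its corpus;
leave-one-out excludes only the query's own record ID. Three criteria:

* **best hit** — exhaustive optimal local alignment (match +1, mismatch
  −3, gap open −5, extend −2) against every reference; the top score
  wins. This is an exact re-creation of what a heuristic nucleotide
  search is used for in such evaluations: with corpora at desk scale,
  exact search is feasible, reproducible, and needs no E-value model.
* **best match** — the minimum p-distance neighbour, however distant.
* **best close match** — best match gated by a distance threshold,
  default 0.03 (the 97% similarity rule), *inclusive* at the boundary;
  beyond it the query is unidentified (`NO_MATCH`).

Ties use exact equality for integer alignment scores and a 1e−9
relative tolerance for real-valued distances, so `AMBIGUOUS` calls are
reproducible. At a given rank the tied best taxa are collapsed to that
rank first: a tie between two congeneric species is ambiguous at species
rank but correct at genus rank. Singleton-species queries stay in the
denominator by default (they can never be correct under the
nearest-neighbour criteria and depress the correct rate, as in the
programs this mirrors); `include_singletons=False` excludes them. The
per-genus report counts any non-`CORRECT` outcome as unidentified and by
default restricts to genera with ≥ 20 species.

## Pipeline and determinism

`run_pipeline` chains curate → annotate/excise → distances → divergence
(+ Wilcoxon in BOTH mode) → identification, writing every intermediate
as TSV/FASTA plus a manifest containing a hash of the scientific
configuration (output directory and log level excluded). All randomness
flows from the single config seed through `numpy.random.default_rng`;
re-running a config reproduces every output byte for byte. Stage
subcommands of the CLI read the serialized intermediates, so any stage
can be re-run in isolation.

Problem sizes in the shipped tests and the acceptance script are chosen
to exercise every code path at desk scale: toy corpora of ≤ 30 records
for oracle-equivalence checks, a 300-record corpus (20 genera × 5
species × 3 samples) for barcode-gap recovery, and ~40–60-record
corpora for the two-locus pipeline runs.

## Known limitations

* The generator has no rate heterogeneity, no multi-copy ITS paralogy,
  no chimeric or mislabelled records — the failure modes that dominate
  real GenBank corpora. Identification rates on synthetic corpora are
  therefore upper bounds, not forecasts.
* The shipped motif profiles are synthetic stand-ins; biological use
  requires profiles built from a real annotated reference alignment
  (`build_profile` accepts any gapped alignment).
* K2P saturation produces NaN rather than a clamped estimate; heavily
  saturated corpora will see many excluded pairs (counted in reports).
* "Partial sequence" screening is represented only by the minimum-length
  filter; database-driven completeness or contaminant screening is out
  of scope, and taxonomy labels are taken as ground truth.
* Wet-lab recovery rates (PCR/sequencing success of the two loci) are a
  laboratory property and are not modelled.
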