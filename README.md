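# its2barcode

Evaluate the short **ITS2** spacer as a DNA *minibarcode* against the
full-length nuclear ribosomal **ITS** region (ITS1 + 5.8S + ITS2).

Archival plant material — herbarium vouchers, dried medicinal products —
usually yields degraded DNA from which the ~634 nt ITS amplifies poorly,
while the ~233 nt ITS2 amplifies readily. Whether ITS2 can replace ITS
then hinges on a desk question: how much species-discriminating signal
does the short spacer retain? This package implements that desk
evaluation end to end, for researchers comparing barcode loci on
labelled sequence corpora:

* **Corpus handling** — FASTA + taxonomy-TSV I/O, curation filters
  (minimum length, default 100 bp; unlabelled records).
* **ITS2 excision** — profile-based annotation of the conserved 5.8S
  and 28S-flank motifs (position-specific log-odds with affine
  insert/delete penalties, glocal Viterbi decoding, both orientations).
* **Distances** — pairwise global alignment with pairwise deletion;
  Kimura 2-parameter for divergence summaries,

      d = −½·ln(1 − 2P − Q) − ¼·ln(1 − 2Q),

  with P and Q the transition and transversion proportions, and
  uncorrected p-distance for identification.
* **Barcode-gap statistics** — the six standard parameters
  (average/maximum/pooled intraspecific; per-genus mean, per-species
  nearest-congener, and pooled congeneric interspecific), each as
  mean ± SD, plus a Wilcoxon signed-rank comparison of two loci paired
  per sequence pair (exact p for n ≤ 25, tie- and continuity-corrected
  normal approximation beyond).
* **Species identification** — leave-one-out *best hit* (exhaustive
  Smith–Waterman), *best match* (nearest neighbour) and *best close
  match* (nearest neighbour gated at 3% distance, the 97% rule), scored
  correct / ambiguous / incorrect / no-match at species and genus rank,
  with per-genus failure-rate tables.
* **Synthetic corpora** — a seeded generator producing genus/species/
  sample hierarchies with a planted conserved 5.8S, known region
  boundaries and a controlled barcode gap, so the whole pipeline is
  testable without downloading anything.

## Worked example

Run the full two-locus comparison on a seeded synthetic corpus (5
genera, 2–4 species each, 2–3 samples per species; full-length ITS
records are annotated and ITS2 excised by the pipeline itself):

```python
import its2barcode as ib

config = ib.PipelineConfig(
    out_dir="demo",
    simulation=ib.SimulationConfig(
        n_genera=5, species_per_genus=(2, 4), samples_per_species=(2, 3),
    ),
    region_mode=ib.RegionMode.BOTH,
    per_genus_min_species=2,
    seed=13,
)
result = ib.run_pipeline(config)
print(open("demo/comparison.tsv").read())
```

which prints:

```
section	parameter	ITS	ITS2
divergence	avg_intra_avg	0.0109 ± 0.0033	0.0144 ± 0.0073
divergence	avg_intra_max	0.0123 ± 0.0037	0.0167 ± 0.0087
divergence	avg_intra_between_intra_species	0.0107 ± 0.0038	0.0145 ± 0.0085
divergence	avg_interbyG_avg	0.0563 ± 0.0066	0.0885 ± 0.0192
divergence	avg_interbyG_min	0.0478 ± 0.0056	0.0738 ± 0.0172
divergence	avg_between_interbyGenus	0.0564 ± 0.0087	0.0905 ± 0.0224
wilcoxon	intraspecific	W+=476.0, W-=154.0, n=35, P=0.00857	ITS2 > ITS
wilcoxon	interspecific	W+=8515.0, W-=0.0, n=130, P=4.51e-23	ITS2 > ITS
identification	BEST_HIT_SPECIES_pct_correct	100.00	100.00
identification	BEST_HIT_GENUS_pct_correct	100.00	100.00
identification	BEST_MATCH_SPECIES_pct_correct	100.00	100.00
identification	BEST_MATCH_GENUS_pct_correct	100.00	100.00
identification	BEST_CLOSE_MATCH_SPECIES_pct_correct	100.00	93.02
identification	BEST_CLOSE_MATCH_GENUS_pct_correct	100.00	93.02
```

Reading it: every K2P divergence parameter is larger on the excised
ITS2 than on full ITS — the invariant 5.8S block inside ITS dilutes its
per-site divergence — and the signed-rank tests confirm the direction
(`ITS2 > ITS`) for both the 130 congeneric-heterospecific and the 35
conspecific sequence pairs. Identification is near-perfect on this
clean corpus; the 93.02% best-close-match rate on ITS2 reflects three
queries whose nearest conspecific sits beyond the 3% gate (`NO_MATCH`),
a price the threshold criterion pays that best match does not.

The same run leaves every intermediate on disk: `annotation.tsv`
(per-record 5.8S/ITS2 boundaries, scores, status), per-locus distance
matrices, `divergence.tsv`, per-query outcome tables, `per_genus.tsv`
and a `manifest.json` whose config hash makes reruns verifiable —
identical config and seed reproduce every file byte for byte.

The same stages are available as CLI subcommands for shell use:

```bash
its2barcode simulate --seed 3 --n-genera 5 --out-prefix demo
its2barcode annotate demo.fasta demo.taxonomy.tsv --out-prefix demo
its2barcode identify demo.its2.fasta demo.its2.taxonomy.tsv \
    --criterion BEST_CLOSE_MATCH --out-prefix demo
its2barcode run-all config.json --seed 13
```

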