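# hairpinforge

A tested, reusable pipeline for small-RNA sequencing analysis: read cleaning
and population profiling, conserved-miRNA identification against known
hairpin precursors, novel-miRNA discovery by hairpin excision with
structure-based annotation criteria (including the minimal folding free
energy index, MFEI), penalty-score miRNA target prediction, 2^-ddCq qPCR
expression analysis with stress-response calls, and strand-aware organelle
genome coverage. A first-class synthetic-data module plants hairpins, decoys
and Cq effects with full ground truth so every stage can be validated.

## Package layout

| Module | Role |
| --- | --- |
| `hairpinforge.synthetic_data` | transcriptomes with planted hairpins/decoys, simulated reads, Cq tables |
| `hairpinforge.preprocess` | adapter trimming, quality/length filters, tag collapsing, size and 5'-base profiles |
| `hairpinforge.conserved_id` | <=2-mismatch mapping to known precursors, mature/star/other classification, family abundance |
| `hairpinforge.folding` | pluggable secondary-structure engines, dot-bracket pair tables |
| `hairpinforge.hairpin_discovery` | exact mapping, window excision, duplex statistics, annotation criteria, cluster/multi-mature/antisense features |
| `hairpinforge.target_prediction` | seed-weighted penalty scoring, target scanning, predicted cleavage sites, shared targets |
| `hairpinforge.expression` | 2^-ddCq fold changes, >2-fold stress calls, crosstalk |
| `hairpinforge.genome_mapping` | strand-resolved exact-match coverage and coverage clusters |
| `hairpinforge.reporting` | percentage arithmetic, packaged annotation fixtures, run reports |

### Annotation criteria (discovery)

A candidate hairpin is accepted only if all of the following hold at the
default `DiscoveryParams`: supporting reads >= 2; dG < -30 kcal/mol; at most
4 unpaired mature bases in the miRNA/miRNA* duplex; at most 2 asymmetric
bulges; MFEI >= 0.85 — plus the structural excision bounds (>= 16 paired
mature bases, mature bulge <= 3 nt, duplex asymmetry <= 4 nt, mature/star
spacing in [5, 450] nt, mature length 18–26 nt). MFEI is
(|dG| / length x 100) / (GC fraction x 100).

## CLI

```bash
hairpinforge simulate   --config sim.yaml --outdir sim/
hairpinforge preprocess --fastq sim/reads.fastq --out-prefix out/clean
hairpinforge conserved  --tags out/clean.collapsed.fasta \
                        --precursor-fasta known.fasta --annotation known.tsv \
                        --out-prefix out/conserved
hairpinforge discover   --tags out/clean.collapsed.fasta \
                        --transcripts sim/transcripts.fasta --out-prefix out/disc
hairpinforge targets    --mirnas mature.fasta --transcripts unigenes.fasta \
                        --cutoff 3.0 --out out/sites.tsv
hairpinforge express    --cq cq.tsv --reference 5.8S --calibrator leaves \
                        --out-prefix out/expr
hairpinforge genomecov  --tags out/clean.collapsed.fasta --genome plastid.fasta \
                        --out-prefix out/cov
hairpinforge report     --section "target sites" out/sites.tsv --out report.md
```

File conventions: FASTQ is Sanger Phred+33 (gzip accepted); collapsed tags
are FASTA with headers `tag<N>_x<count>`; the truth table TSV columns match
the `TruthRecord` dataclass fields (name, transcript_id, strand,
precursor_id, precursor/mature/star intervals as 0-based half-open
coordinates, arm, planted_depth, is_decoy, cluster_id, antisense_partner,
decoy_tag); the Cq table TSV has columns condition, assay, replicate, cq.
Reports and GFF3 use 1-based inclusive coordinates; internal coordinates are
0-based half-open. Sequences may be given as DNA or RNA; the internal
alphabet is RNA.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests for the
pipeline invariants (count conservation, acceptance monotonicity, strand
symmetry), brute-force oracle cross-checks for duplex statistics and penalty
scoring, and `tests/test_acceptance.py` with the end-to-end parameter
recovery run (50 planted miRNAs including clusters, multi-mature precursors
and antisense pairs, plus 50 decoys).

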