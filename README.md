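# metanno

Metabolic-reaction-network based recursive metabolite annotation for
untargeted LC-MS metabolomics.

Untargeted metabolomics detects thousands of MS1 features, but spectral
libraries of authentic standards identify only a few hundred metabolites.
`metanno` extends annotation beyond the library by exploiting the
observation that substrate–product pairs of enzymatic reactions (KEGG-style
*reaction pairs*) are structurally similar and tend to share MS2
fragmentation. Library-identified metabolites become *seeds*; each seed
lends its experimental MS2 spectrum to its reaction-paired neighbors as a
surrogate reference, neighbors matched on m/z, predicted retention time and
spectral similarity are annotated and become seeds themselves, and
annotation propagates through the metabolic reaction network until no new
metabolite appears.

The core score for a neighbor candidate is

    Score_iden = 0.25·Score_mz + 0.25·Score_RT + 0.50·Score_spec

where each component ramps linearly from 1 (perfect match) to 0 at its
tolerance (±25 ppm m/z; ±30% predicted RT; spectral dot product gated at
0.5 on precursor-trimmed spectra). Per peak the top five candidates with
scores above 0.4 are reported. The pipeline also annotates isotope
envelopes ([M]..[M+4], computed exactly from the formula) and adduct peaks,
grades every annotation's supporting evidence (1 = library match,
2 = isotope-supported, 3 = reliable adduct, 4 = bare), removes redundant
hypotheses recursively, predicts retention times from molecular descriptors
with a tuned random forest (QSRR), and finishes with hypergeometric pathway
enrichment and Pareto-scaled pathway quantification.

## Quick start

Generate a synthetic demo study with known ground truth, then run the full
pipeline on it:

```
$ metanno make-demo --out demo_data --seed 42 --n-metabolites 50
$ metanno run \
    --peak-table demo_data/peak_table.csv \
    --sample-sheet demo_data/sample_sheet.csv \
    --ms2 demo_data/spectra.mgf \
    --library demo_data/library.msp \
    --reaction-pairs demo_data/reaction_pairs.csv \
    --compounds demo_data/compounds.csv \
    --descriptors demo_data/descriptors.csv \
    --pathways demo_data/pathways.csv \
    --out demo_results --seed 42
50 metabolite annotations (10 initial seeds, 8 rounds) -> demo_results
```

Ten of the fifty metabolites are covered by the demo library; recursive
propagation annotates the remaining forty over eight rounds. The output
directory contains `Annotation.result.csv` (one row per retained
annotation):

```
peak_id,metabolite_id,metabolite_name,adduct,role,...,total_score,round,grade,rank
P00001,M0000,metabolite 0,[M+H]+,monoisotope,...,0.830,2,2,1
P00002,M0000,metabolite 0,[M+H]+,isotope,...,0.962,2,2,1
```

— peak P00001 is annotated as metabolite M0000 in round 2 with score 0.83
and grade 2 (isotope-supported: its [M+1] peak P00002 matched the
theoretical envelope). `round_log.csv` traces the propagation
(`1,10,39,16,16`: round 1 started from 10 seeds, retrieved 39 neighbors,
annotated 16, promoted 16 new seeds), and
`Pathway.enrichment.analysis.csv`, `Quantitative.pathway.metabolite.result.csv`
and `Quantitative.pathway.result.csv` carry the dysregulated-pathway
analysis.

Real studies substitute their own peak table (CSV columns `name, mz, rt`
plus one intensity column per sample), MGF/MSP MS2 files, an MSP spectral
library, reaction-pair/compound tables (`metanno convert-kegg` normalizes
third-party column layouts), a molecular-descriptor table and a pathway
table. The library API mirrors the stages: `metanno.msio`,
`metanno.spectra`, `metanno.mrn`, `metanno.seeds`, `metanno.isotopes`,
`metanno.recursion`, `metanno.confidence`, `metanno.rtpred`,
`metanno.pathway`, with `metanno.pipeline.run_pipeline` wiring them
together.

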