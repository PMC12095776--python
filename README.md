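# gradr

Predict the protein interactome of every expressed RNA from a single set
of gradient co-sedimentation (Grad-seq), RNA-binding-proteome (OOPS) and
subcellular fractionation experiments.

## The problem

RNA-centric interactome methods (ChIRP-MS, RAP-MS, CLIP) interrogate one
transcript per experiment. Gradient profiling offers a shortcut: when a
cell lysate is separated on a linear glycerol gradient and each of the 22
fractions is profiled by RNA-seq and mass spectrometry, molecules that
travel in the same ribonucleoprotein complex co-sediment, so their
abundance profiles across fractions correlate. `gradr` turns that signal
into per-RNA interactor predictions by combining three evidence layers:

1. **Co-sedimentation.** For a query RNA with sedimentation profile
   *x* and a protein with profile *y* over the gradient fractions, the
   Pearson correlation *r*(x, y) scores co-sedimentation. Candidates
   with *r* ≥ 0.5 are retained, ranked by descending *r*.
2. **RNA binding.** Only proteins that behave as RNA-binding proteins in
   OOPS (orthogonal organic phase separation) qualify: RNase+/− elution
   fold-change ≥ 2 at two-tailed Student's-t *p* ≤ 0.05 over 3 replicates
   of label-free (LFQ) abundances.
3. **Shared compartment.** An interactor must be detectable where the RNA
   lives. RNAs are assigned cytoplasmic/nuclear from spike-in-normalized
   fractionation RNA-seq (majority of signal); a protein is eligible for
   a compartment if it is detected there in all three replicates and is
   not ≥ 60% in the opposing compartment in all three. For nuclear RNAs,
   mitochondrial proteins are additionally removed.

The package also ships:

* a **lncRNA conservation scorer**: from BLASTN tabular hits against a
  target genome it keeps hits with ≥ 20 matched bases, selects the ≤ 100 kb
  orthologous window maximizing query coverage (synteny hints take
  precedence), and reports percent base conservation of the query;
* a **synthetic co-sedimentome simulator** that plants RNA–protein
  complexes as shared Gaussian peaks, OOPS enrichment for true RBPs,
  compartment-restricted signal and E. coli spike-in read shares, with a
  serialized ground truth — so the whole pipeline is testable without any
  downloads;
* an enrichment module for **ChIRP-MS-style volcano tables**, including
  the all-zero-control imputation (control mean set to 100) that keeps
  capture-exclusive proteins plottable.

## Worked example

```python
from gradr import Config, interactome_all
from gradr.simulate import (SimulationSpec, simulate_cosedimentome,
                            score_predictions)

cfg = Config()                      # the published thresholds
sim = simulate_cosedimentome(SimulationSpec(rng_seed=7))
ds = sim.combined_dataset(cfg)      # spike-normalize, call RBPs, localize
predictions, summary = interactome_all(ds, cfg)
print(summary.to_string(index=False))
```

```
  rna_id compartment  n_candidates  n_passed note
RNA_C1_1 cytoplasmic             9         5
RNA_C1_2 cytoplasmic             9         5
RNA_C1_3 cytoplasmic             9         5
RNA_C2_1     nuclear             8         4
RNA_C2_2     nuclear             8         4
RNA_C2_3     nuclear             8         4
```

Each planted RNA gets a handful of candidates (RBP-called,
compartment-eligible proteins) of which those with *r* ≥ 0.5 pass. The
top of one RNA's table:

```python
top = predictions[predictions["rna_id"] == "RNA_C1_1"].head(5)
print(top[["protein_id", "pearson_r", "oops_fc", "oops_p", "passed",
           "rank"]].to_string(index=False))
```

```
protein_id  pearson_r  oops_fc   oops_p  passed  rank
 PROT_C1_4   0.995453 7.834968 0.000006    True     1
 PROT_C1_3   0.994278 8.727654 0.000054    True     2
 PROT_C1_1   0.991913 6.937698 0.000002    True     3
 PROT_C1_2   0.984124 8.148744 0.000002    True     4
PROT_BG_26   0.903069 8.397135 0.000259    True     5
```

The four planted partners of `RNA_C1_1` top the list with *r* > 0.98;
one background RBP happens to co-sediment and is (correctly, given the
evidence) also predicted. Scoring against the planted truth:

```python
print(score_predictions(predictions, sim.truth))
# {'precision': 0.889, 'recall': 1.0, 'f1': 0.941, 'n_predicted': 27,
#  'n_true': 24, 'true_positives': 24, 'empty_prediction': False}
```

All 24 planted interactions are recovered.

## Command line

Every stage is a subcommand over TSV files; each run writes a
`manifest.json` (command line, config snapshot, input SHA-256 digests)
for reproducibility:

```bash
gradr simulate --seed 7 --out sim/
gradr oops-call --treat sim/oops_treat.tsv --ctrl sim/oops_ctrl.tsv --out oops/
gradr predict \
    --rna-profiles sim/rna_profiles.tsv --protein-profiles sim/protein_profiles.tsv \
    --oops oops/enrichment.tsv \
    --rna-cyt sim/rna_cyt_rpkm.tsv --rna-nuc sim/rna_nuc_rpkm.tsv \
    --spike sim/spike_samples.tsv \
    --prot-cyt sim/protein_cyt.tsv --prot-nuc sim/protein_nuc.tsv \
    --mito-list sim/mito_proteins.txt --out pred/
gradr score --pred pred/predictions_long.tsv --truth-dir sim/ --out scores/
```

Other subcommands: `filter-expressed` (expressed-RNA filter: RPKM ≥ 0.5
in all replicates of ≥ 1 condition and ≥ 10 reads), `localize`,
`chirp-volcano`, `conserve`.

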