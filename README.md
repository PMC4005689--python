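# hrfseq

Termination-based RNA accessibility profiling from massively parallel
sequencing readout, with saturation-corrected unique-fragment counting and
structure-derived validation metrics.

Hydroxyl radicals cleave the solvent-exposed RNA backbone; reverse
transcription stops one nucleotide short of each break, so accessibility can
be read out by counting termination sites. This package implements the
computational side of such an experiment:

- **`barcode_model`** — estimates the (unequal) frequencies of a degenerate
  ligation barcode from the data, derives per-barcode probabilities under
  positional independence, and inverts the occupancy expectation
  `E[k] = Σᵢ (1 − (1 − Pᵢ)ⁿ)` to turn an observed number of distinct
  barcodes `k` into an estimated unique count (EUC) `n`, correcting both
  PCR duplication and barcode saturation.
- **`fragment_extraction`** — turns paired sense-strand alignments into
  canonical fragments (termination site, priming site, barcode), including
  barcode splitting, untemplated-nucleotide trimming at the cDNA 3′ end and
  the minimum-span filter.
- **`reactivity`** — per-position termination counts, effective coverage
  (with the ≥ 100 nt priming-distance rule), termination-coverage ratio
  (TCR), treated-minus-control ΔTCR, a detection-probability coverage
  cutoff, and the 3-nt moving average offset one position upstream.
- **`structure_metrics`** — ribose bead positions (mean of C1′/C2′/C3′/C4′/O4′),
  through-space contact counts within 14 Å, per-residue ribose
  solvent-accessible surface area from a deterministic dot lattice, and
  windowed/offset Pearson correlations against a reactivity profile.
- **`synthetic_data`** — a fully specified simulator (known cleavage
  probabilities, spontaneous termination background, unequal barcode pool,
  length-biased PCR, size selection) producing fragment tables, paired SAM
  and ground truth, so the entire pipeline is testable offline.
- **`io` / `cli` / `pipeline`** — TSV/FASTA/SAM readers and writers, run
  configuration, and the `hrfseq` subcommand CLI.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (worked-example
targets, Monte-Carlo oracle equivalence for the occupancy formula,
saturation-correction behaviour, end-to-end parameter recovery on the
synthetic experiment, PCR-bias correction, coverage-cutoff closed form,
SASA/contact oracles, and lossless round trips).

## CLI

```bash
# simulate a synthetic experiment (fragments, SAM, truth, reference FASTA)
hrfseq simulate --out scratch/sim --seed 17

# alignments -> fragment table
hrfseq fragments --bam scratch/sim.treated.sam --fasta scratch/sim.fasta \
    --min-span 100 --out scratch/treated.fragments.tsv

# barcode model + estimated unique counts
hrfseq euc --fragments scratch/treated.fragments.tsv --out scratch/treated

# reactivity profile from two EUC tables
hrfseq reactivity --treated scratch/treated.euc.tsv --control scratch/control.euc.tsv \
    --length 300 --min-priming-distance 100 --out scratch/profile

# structure metrics and correlation
hrfseq structure --pdb structure.pdb --probe-radius 1.4 --out scratch/metrics.tsv
hrfseq correlate --reactivity scratch/profile.reactivity.tsv \
    --metrics scratch/metrics.tsv --offsets -15:15 --out scratch/offsets.tsv

# end to end: SAM pairs -> reactivity profile + summary sidecar
hrfseq run --treated-sam t.sam --control-sam c.sam --fasta ref.fa --out scratch/run
```

All outputs are tab-separated text with `#`-prefixed headers carrying the
tool version, configuration hash and seed; coordinates are 1-based and
inclusive.

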