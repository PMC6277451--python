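# chromalib

Peptide-centric DIA (data-independent acquisition) search and quantification
with chromatogram libraries.

chromalib takes centroided DIA runs (mzML) and a spectrum library (NIST MSP
or its own SQLite format) and produces validated peptide detections,
parsimonious protein groups at controlled FDR, and interference-screened
peptide/protein quantity matrices. Along the way it:

* **demultiplexes** 50%-overlapped isolation windows into half-width
  pseudo-spectra using the previous/next half cycles;
* **scores** every library entry (and a paired reversed-sequence decoy) at
  its best retention-time point with a factorial-boosted, correlation-
  weighted dot product plus 15 auxiliary match features;
* **calibrates retention time** non-parametrically with a 2-D kernel density
  ridge walk and a Gaussian/uniform EM mixture model that flags and
  reconsiders outliers (up to five times);
* **controls FDR** with a self-contained semi-supervised linear re-scorer,
  global peptide q-values/PEPs, and greedy protein parsimony;
* **builds chromatogram libraries** from narrow-window (gas-phase
  fractionated) runs: run-specific retention times, apex fragment
  intensities, and per-fragment peak-shape correlations, keeping only
  +1H/+2H B/Y ions and the best-scoring charge state per peptide;
* **quantifies** by Savitzky-Golay-smoothed fragment chromatograms refined
  against the median peak shape, trapezoidal integration with background
  subtraction, study-wide transition selection (top 5, ≥3 quantitative,
  interference score ≤ 0.2), CV/completeness filters, and unique-peptide
  protein sums.

A fully deterministic synthetic-data module generates ground-truth-labeled
libraries, runs, and multi-run studies (Gaussian elution, overlapped window
cycles, coeluting interference, monotone RT warps, condition fold changes),
so the entire pipeline is testable without external data.

## CLI

```bash
# write a synthetic study (library.sqlite, *.mzML, design.csv, truth.json)
chromalib simulate --n-peptides 100 --n-runs 3 --seed 1 --out sim/

# build a chromatogram library from narrow-window runs
chromalib build-library --narrow n1.mzML --narrow n2.mzML \
    --lib dda.sqlite --out chromlib.sqlite --fdr 0.01

# search wide-window runs; writes a feature TSV (one row per target/decoy)
chromalib search --run wide1.mzML --lib chromlib.sqlite \
    --ptol 10 --ftol 10 --ltol 10 --out wide1.features.tsv

# full search + validation + quantification
chromalib quantify --run wide1.mzML --run wide2.mzML \
    --lib chromlib.sqlite --study design.csv --out quant/
```

`--demultiplex {auto,on,off}` controls overlap deconvolution; `auto`
(default) triggers when a 50%-staggered window scheme is detected. Exit
codes: 0 ok, 1 input error, 2 stage failure.

## Layout

```
src/chromalib/
  masses.py          residue masses, B/Y fragment m/z, isotope envelopes
  models.py          Spectrum, DIARun, LibraryEntry, ScoredMatch, ...
  msdata_io.py       mzML read/write, MSP, SQLite libraries, FASTA digest
  demultiplex.py     overlapped-window deconvolution
  library_builder.py decoys, background ion frequencies, chromatogram libs
  search_engine.py   primary score + 15 features, best-RT search
  rt_alignment.py    KDE ridge, EM mixture, outlier reconsideration,
                     cross-experiment alignment
  validation.py      re-scorer, q-values/PEPs, protein parsimony + FDR
  quantification.py  trace extraction, refinement, integration, matrices
  synthetic_data.py  ground-truth generator (libraries, runs, studies)
  pipeline.py        end-to-end workflows and StudyConfig
  cli.py             click CLI
```

### Notes on file formats

The SQLite library schema is self-defined (documented in
`msdata_io.py`): `meta`, `entries` (arrays as little-endian float64 BLOBs),
and `peptide_protein` tables. It is not byte-compatible with any vendor
format. Modifications are encoded as bracketed delta masses
(`M[+15.994915]`); cysteine carbamidomethylation is a fixed modification.
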