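# paskscan

Compositional detection of **PASK motifs** — polyacidic serine- and
lysine-rich protein subsequences — in single sequences and whole proteomes,
with the companion analyses used to characterize them: threshold sweeps,
per-proteome statistics, residue-range composition reports, in-silico
substitution mutants, and disorder-score consensus profiles.

PASK motifs are the canonical protein-binding sites of inorganic
polyphosphate (polyP): lysines embedded in an acidic, serine-rich context.
A window of `W = 20` residues qualifies as a PASK motif when

```
#{i : s_i ∈ {D, E, S, K}} ≥ ⌈f·W⌉   and   #{i : s_i = K} ≥ 1
```

with composition threshold `f = 0.75` by default (so ⌈0.75·20⌉ = 15 of 20
residues), evaluated by a sliding window over every position of every
protein. Thresholds are handled as exact rationals — never floating-point
comparisons — so 75% of 20 is exactly 15. Overlapping or abutting qualifying
windows are merged into maximal motif regions for reporting (raw windows
remain available via `--windows`). Relaxed thresholds (60%, 50%) recover
"PASK-like" regions that miss the strict definition; positive sets at lower
thresholds always contain those at higher ones.

The package is aimed at researchers mapping polyanion-binding regions:
scan a UniProt proteome FASTA, count motif-positive proteins normalized by
proteome size, count lysines in a domain of interest, design K→R / S→A /
D→N,E→Q / D→A,E→L mutants of a region, and average per-residue disorder
predictor outputs into a mean ± SE consensus with calls at mean > 0.5.

## Worked example

Generate a synthetic proteome with one planted motif, scan it, and sweep
thresholds:

```bash
$ paskscan simulate --out toy.fasta --truth truth.tsv \
    --n-proteins 5 --plant 1:50 --plant 3:20 --seed 7
wrote 5 proteins to toy.fasta

$ paskscan scan --in toy.fasta --threshold 0.75
protein_id      start   end     length  window_support  threshold       window_length
synthetic_0002  49      71      23      4       3/4     20
synthetic_0004  19      40      22      3       3/4     20

$ paskscan sweep --in toy.fasta --thresholds 0.75,0.60,0.50
source  n_entries       n_with_motif    fraction        threshold
toy.fasta       5       2       0.4     3/4
toy.fasta       5       2       0.4     3/5
toy.fasta       5       2       0.4     1/2
```

The scan reports the two planted carriers and nothing else: each planted
20-residue window (15/20 D/E/S/K with one K, dropped at positions 50 and 20
of proteins 2 and 4) is recovered as a merged region a few residues wider
than the plant, because neighbouring windows that still contain all fifteen
counted residues also qualify. `window_support` is the number of qualifying
windows merged into each region. The sweep shows the motif-positive count
per threshold (here constant; on real proteomes it grows steeply as the
threshold drops).

The same definition applied via the library:

```python
>>> from paskscan import MotifConfig, min_composition_count
>>> min_composition_count(0.75, 20)
15
>>> from paskscan.standins import synthetic_yihi
>>> from paskscan import scan_sequence, merge_windows
>>> cfg = MotifConfig(fraction_threshold=0.50)
>>> [(r.start, r.end) for r in merge_windows(scan_sequence(synthetic_yihi(), cfg))]
[(5, 35), (142, 169)]
```

`paskscan.standins` provides clearly labelled synthetic sequences that
reproduce published compositional statistics (region-wise lysine counts and
threshold behaviour) for demonstration and offline testing; they are not
database sequences.

Other subcommands: `summarize` (per-proteome fractions), `compose`
(residue-range counts, e.g. `--range 644-813`), `mutate`
(`--scheme K-R|S-A|D-N/E-Q|D-A/E-L`), `disorder-consensus` (mean ± SE over
predictor score tables), `fetch-proteome` (network convenience), and output
as TSV or GFF3 (`compositional_bias` features in protein coordinates).

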