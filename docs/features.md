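# Feature reference

The extractor emits exactly 139 named features per hairpin, in a frozen
global order: 81 sequence features, 49 structure features, 9 energy
features.  `L` is the sequence length in nucleotides; "fraction" means a
value in [0, 1].  Zero-denominator conventions are listed at the end.

## Sequence features (81)

| Feature | Count | Formula |
|---|---|---|
| `XY%` for X,Y ∈ {A,C,G,U} | 16 | count of the overlapping dinucleotide XY over the L−1 windows, divided by L−1 |
| `G+C%` | 1 | (number of G or C bases) / L |
| `XYZ%` for X,Y,Z ∈ {A,C,G,U} | 64 | count of the overlapping trinucleotide XYZ over the L−2 windows, divided by L−2 |

Both k-mer groups are probability distributions (each sums to 1).
Dinucleotide and trinucleotide names are ordered lexicographically over
the alphabet A, C, G, U.

## Structure features (49)

### Topology scalars (8)

Taken directly from the fold object (computed by the folding backend, a
fold sidecar file, or the synthetic generator):

| Feature | Meaning |
|---|---|
| `Diversity` | ensemble mean base-pair distance (partition function) |
| `Freq` | frequency of the MFE structure in the thermodynamic ensemble, exp((EFE − MFE)/kT) |
| `dS`, `dS/L` | structural entropy (cal·mol⁻¹·K⁻¹) and its per-nucleotide value |
| `dH`, `dH/L` | structural enthalpy (kcal/mol) and its per-nucleotide value |
| `dQ` | mean positional Shannon entropy (bits) of the base-pairing probabilities |
| `dF` | compactness of topology, 1 − dQ/log₂L (1 = single well-defined structure) |

When the backend computes folds itself, `dH` is the sum of
nearest-neighbor stack enthalpies over the stacked pairs of the MFE
structure, `dS = (dH − dG)·1000/310.15`, and `Tm = 1000·dH/dS − 273.15`.

### Base-pair statistics (9)

Base pairs come from the dot-bracket structure; a pair joining an X and
a Y counts toward `|X−Y|` regardless of which arm carries which base.
A *stem* is a maximal run of ≥ 3 contiguously stacked pairs
((i,j) stacked on (i+1,j−1)); `n_stems` is the number of such runs.

| Feature | Formula |
|---|---|
| `\|A−U\|/L`, `\|G−C\|/L`, `\|G−U\|/L` | pair-class count / L |
| `\|A−U\|%/n_stems` etc. | (pair-class count within stems / total pairs) / n_stems |
| `Avg_BP_Stem` | total base pairs / n_stems |
| `dD` | length-normalized ensemble base-pair distance (Diversity/L) |
| `dP` | base-pairing tendency: MFE base pairs / L |

### Structure triplets (32)

`)` is remapped to `(`, so every position reads "paired" `(` or
"unpaired" `.`.  Each of the L−2 windows of 3 positions is classified by
its pairedness pattern (8 possibilities) × the middle nucleotide
(A/C/G/U); the features are window-count fractions and sum to 1.  Names
have the form `pattern_middle`, e.g. `((._A`.  Patterns are ordered
`...`, `..(`, `.(.`, `.((`, `(..`, `(.(`, `((.`, `(((`; middle
nucleotides A, C, G, U within each pattern.

## Energy features (9)

`n_loops` counts hairpin loops (innermost pairs enclosing only unpaired
bases); `n_bp` is the total base-pair count.

| Feature | Formula |
|---|---|
| `dG` | minimum free energy of the MFE structure, kcal/mol |
| `MFEI1` | (dG/L) / GC-fraction |
| `MFEI2` | (dG/L) / n_stems |
| `MFEI3` | (dG/L) / n_loops |
| `MFEI4` | dG / n_bp |
| `NEFE` | EFE / L (normalized ensemble free energy) |
| `Diff` | \|dG − EFE\| / L |
| `Tm`, `Tm/L` | melting temperature (°C) and its per-nucleotide value |

## Zero-denominator conventions

Degenerate hairpins keep finite feature vectors (a warning is logged):

* no stem (`n_stems = 0`): `|X−Y|%/n_stems`, `Avg_BP_Stem`, `MFEI2` → 0;
* no hairpin loop: `MFEI3` → 0;
* no base pair: `MFEI4` and all pair-class fractions → 0;
* `G+C% = 0`: `MFEI1` → 0.
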