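# codonlogo

Codon-level sequence logos from multiple sequence alignments of
protein-coding nucleotide sequences.

A per-nucleotide logo can suggest that a codon is common at a position
when in fact it never occurs there — only the individual bases are
frequent. `codonlogo` works on whole codons instead: it tokenizes an
aligned FASTA file into frame-0 triplets, builds a position × codon
probability matrix, transforms it into an information-content (bit)
matrix via Shannon entropy

```
Rseq(l)   = Smax − H(l),        Smax = log2(alphabet size)
H(l)      = −Σ f(n,l)·log2 f(n,l)
Height(n,l) = f(n,l)·Rseq(l)
```

and renders the per-position codon stacks as a PNG or PDF logo, with
glyphs colored by amino-acid property palettes.

## CLI

```sh
codonlogo aln.fasta \
    [--prefixFileName OUT] [--imageTitle TITLE] \
    [--matrixLogoType bit|probability] \
    [--alphaColor weblogo_protein|charge|chemistry|hydrophobicity] \
    [--degreeOfUncertainty 0-100] \
    [--datasetType redundant|nonredundant] \
    [--logoFormat png|pdf] \
    [--smaxSymbols N] [--dropEmptyPositions] [--dpi DPI]
```

The input must be an aligned nucleotide FASTA (equal lengths, length a
multiple of three, starting in frame). IUPAC ambiguity codes and `-`
gaps are accepted; RNA (`U`) is normalized to DNA.

Each run writes exactly two files: the matrix CSV
(`<prefix>.bitMatrix.csv` or `<prefix>.probabilityMatrix.csv`) and the
logo figure (`<prefix>.png` or `<prefix>.pdf`).

Key behaviors:

- `--degreeOfUncertainty X` removes sequences whose percentage of
  ambiguous nucleotides (among non-gap characters) is strictly greater
  than X. Default 100 keeps everything.
- `--datasetType nonredundant` removes exact duplicate sequences
  (first occurrence kept) before anything else.
- Smax defaults to `log2(64) = 6` bits; if ambiguity codes survive
  filtering into the counted codons, the alphabet automatically widens
  to the 15³ = 3375 IUPAC triplets (override with `--smaxSymbols`).
- Gap-containing triplets are excluded from counting; a position where
  every sequence has a gap triplet is an error unless
  `--dropEmptyPositions` is given.
- Fewer than 40 sequences triggers a warning (entropy is
  underestimated at low depth), not an error.

## Python API

```python
from codonlogo import (
    read_fasta_alignment, count_codons, to_probability, to_bits,
    compute_smax, AlphabetSpec, layout_logo, render, RenderSpec,
    get_palette,
)

aln = read_fasta_alignment("aln.fasta")
prob = to_probability(count_codons(aln))
bits = to_bits(prob, compute_smax(AlphabetSpec.unambiguous()))
layout = layout_logo(bits, get_palette("weblogo_protein"))
render(layout, RenderSpec(title="my logo"), "logo.png")
```

`codonlogo.fixture_gen.ProfileSpec` / `generate_alignment` produce
seeded synthetic alignments with controlled per-position codon
distributions, duplicate injection and ambiguity injection — all test
inputs are generated, no external data is needed.

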