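# dualgene

Exact design of **fully overlapping genes**: given two (or three) target
protein sequences, find homologous sequences that can be encoded by one DNA
segment in overlapping reading frames — on the same strand or on opposite
strands — while *provably* maximizing a conservation-weighted Blosum
similarity score to the targets.

Overlapping coding regions are common in viruses, arise transiently during
gene creation by overprinting, and are attractive for compressing or
constraining synthetic genomes. The obstacle is that every nucleotide in the
overlap belongs to two (or three) codons at once. `dualgene` is for protein
engineers and synthetic biologists who want the best possible dual/triple
gene for arbitrary targets, and for anyone studying why some overlap
geometries work so much better than others.

## The model

For targets X, Y and candidate homologs X′, Y′ the design score is

```
S(X′, Y′) = Σ_i p_i B(X_i, X′_i)  +  Σ_j q_j B(Y_j, Y′_j)
```

where `B` is a Blosum matrix (Blosum62 by default) and `p_i`, `q_j` are
per-position conservation weights. Weights come from a family alignment:
each column's Shannon entropy `S_i` (nats) is computed over six amino-acid
classes — {LVIMC}, {FYW}, {G}, {ASTP}, {EDNQ}, {KRH} — so `e^{S_i}` ranges
from 1 to 6, and the weight is `p_i = e^{-S_i}` (1 for perfectly conserved
columns, 1/6 for maximally variable ones). Without an alignment all weights
are 1 and `S` is a plain Blosum sum.

The second protein can sit in five frames relative to the first: two
sense-strand shifts and three antisense frames. Three are supported
directly (the rest follow by swapping the proteins' roles):

* `F = 0` — antisense, codons fully base-paired. Each codon pair is
  independent, so the optimum is a per-position comparison of the 64 codons.
* `F = -2` — antisense, each codon's middle base opposite the other frame's
  wobble base. The overlap is a chain of linked 4-nucleotide *quartets*
  (consecutive quartets share one nucleotide), and the optimum is found by
  dynamic programming over a 4 × N table whose state is the quartet's last
  nucleotide, followed by a traceback. Cost is linear in the overlap length.
* `F = +1` — same strand, codon grid shifted one nucleotide; same quartet
  machinery.

The same DP designs **triple genes** (default: X sense, Y antisense in
`F = -2`, Z sense in `F = +1`), with each quartet scoring three codons.
Stop codons in any encoded frame are excluded outright; ties are broken
toward the lexicographically smallest DNA, so designs are deterministic.
The shorter protein's coding region is always completely embedded in the
longer one's; the longer protein's flanks are copied unchanged and
back-translated, and only the overlap is optimized (and scored).

A brute-force enumerator over all `4^L` overlap sequences ships as an
independent oracle; the test suite checks DP-vs-enumeration equality on
hundreds of random instances per scheme.

## Coding capacity of the genetic code

`dualgene.capacity` explains the empirical frame ranking. Under the
standard code, the fully base-paired `F = 0` geometry can realize only
**26** of the 210 amino-acid type pairs. In `F = -2`, classifying residues
into four classes (large/small × polar/nonpolar; C and W unclassified),
**15 of the 16** (sense class, antisense class) combinations can be
guaranteed on both strands regardless of the wobble bases — only
(small-polar, small-polar) cannot, and even it is guaranteed on one strand.

## Worked example

```python
import dualgene as dg

x = dg.ProteinSeq("X", "MAGICSEQVENCE")     # 13 residues
y = dg.ProteinSeq("Y", "WILDTYPEDESIGNS")   # 15 residues
scheme = dg.build_scheme(["ref", "-2"])
for p in dg.enumerate_placements(len(y), len(x), "ends"):
    r = dg.design_dp([x, y], scheme, p)
    print(p.offset, r.score, r.identity, r.dna.nucleotides)
```

prints (Blosum62, unit weights):

```
F=-2 offset=0 score=87  identity=30.8%/61.5%
     dna TTCCAAGGGATTTGTCCTCAGGATATAGATCAATGCACCA
     X'  FQGICPQDIDQCT   Y' WCIDLYPEDKSLG
F=-2 offset=2 score=109 identity=61.5%/76.9%
     dna ATGAGTGGCCTATGCTCTCATCAGGTGGATAACTGTCAAG
     X'  MSGLCSHQVDNCQ   Y' LDSYPPDESIGHS
```

Each line is one placement of X′ inside Y′'s coding sequence: the overlap
DNA (40 nt = 3·13 + 1; the shifted frame needs one extra nucleotide), the
optimized score `S`, and each designed homolog's percent identity to its
target over the overlap. Reading the DNA's sense codons gives X′; reading
its reverse complement in the `F = -2` grid gives Y′ — one segment, two
proteins. The end-aligned placement here scores 109 of the
diagonal-sum upper bound (score if both homologs were exact copies), with
the designed homologs 62% and 77% identical to their targets.

The same is available from the shell:

```
dualgene design-pair X.fasta Y.fasta --frame all -o out/   # 3 frames x 2 runs
dualgene design-triple X.fasta Y.fasta Z.fasta -o out/
dualgene screen proteins.fasta --plan                       # run arithmetic
dualgene capacity -o out/                                   # capacity tables
dualgene weights family.sto --target-id X                   # entropy weights
dualgene fixtures --seed 1 -o fixtures/                     # synthetic data
```

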