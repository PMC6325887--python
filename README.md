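# lincatlas

Computational companion analyses for a *C. elegans* lincRNA knockout screen:
given a nine-stage expression atlas (embryo, L1–L4, young adult, dauer,
starved mix, male), genome annotation, miRNA sequences and TF ChIP-seq peaks,
`lincatlas` performs

- **genomic-feature comparison** — spliced length, exon number and phastCons
  conservation (mean score plus "base coverage", the fraction of annotated
  bases) of lincRNAs against randomly sampled mRNAs (*n* = 200), compared by
  the two-sided Mann–Whitney *U* test;
- **stage-specificity classification** — a lincRNA is *stage-exclusive* when
  it is expressed (RPKM above a small floor) in exactly one stage, and
  *ubiquitous* when it is expressed at every stage with a highest/lowest
  ratio within tenfold;
- **profile clustering** — k-means (default *k* = 10) on expression
  normalized to the embryonic stage, `log2((v + 0.01)/(v_embryo + 0.01))`,
  after filtering to genes with RPKM > 1;
- **neighbor-gene analysis** — coding genes within ±100 kb of each lincRNA,
  with signed distances, position ranks, Pearson correlation of log2(RPKM +
  0.01) profiles, and log2 fold changes clamped to [−5, 5];
- **ceRNA network inference** — a lincRNA–miRNA edge requires ≥ 2 exact
  matches of the miRNA seed site (reverse complement of miRNA nucleotides
  2–8) in the spliced lincRNA transcript *and* Pearson *R* < −0.1 across the
  nine stages;
- **TF regulation mapping** — a ChIP-seq peak regulates a lincRNA when it
  overlaps the promoter window [TSS − 1 kb, TSS + 200 bp) in transcription
  orientation; per-stage TF→lincRNA maps, regulator-count comparisons and
  shared targets of TF pairs (e.g. UNC-30/UNC-55) follow.

Because the real inputs (ce11, miRBase, GEO expression tables, modENCODE
peaks) are large external downloads, the package ships a first-class
**synthetic data generator** that plants all of these structures — named
stage-exclusive genes, ubiquitous-within-tenfold genes, separated temporal
profiles, seed-site insertions with target anti-correlations, promoter-window
peaks and decoys — and records every planted fact in a ground-truth manifest,
so the entire pipeline is tested closed-loop without any download.

## Worked example

```python
import lincatlas as la

bundle = la.simulate_paper_shape(seed=1)   # 170 lincRNAs, 1000 mRNAs, 50 miRNAs

calls = la.classify_specificity(bundle["expr_linc"])
print(la.specificity_counts(calls))
# {'exclusive': 8, 'ubiquitous': 12, 'broad_variable': 150, 'not_expressed': 0}

edges = la.build_network(bundle["transcripts"], bundle["mirnas"],
                         bundle["expr_linc"], bundle["expr_mir"])
print(len(edges))                           # 13
e = edges[0]
print(e.linc_id, e.mirna_id, e.match_count, round(e.pearson_r, 3))
# linc-112 mir-3 2 -0.846

maps = la.assign_peaks(bundle["peaks"], bundle["windows"])
emb = maps["embryo"]
print(len(emb.tf_names), len(emb.regulated_genes()))   # 20 169
```

The specificity counts show the planted atlas structure recovered exactly: 8
stage-exclusive lincRNAs (three embryo-only, one L2, one young-adult, two
dauer, one male) and 12 ubiquitous ones within the tenfold band.  The ceRNA
network contains every planted lincRNA–miRNA pair (two seed sites each,
strong anti-correlation) plus a few chance edges, which is expected: under
independent expression the probability of *R* < −0.1 at *n* = 9 stages is
about 0.4, so pairs with two accidental seed matches occasionally qualify.
The embryo regulation map reports how many of the 20 simulated TFs bind at
least one lincRNA promoter window and how many lincRNAs are bound.

The same stages are available as a command-line pipeline:

```sh
lincatlas simulate --seed 1 --out data/
lincatlas specificity --in data/ --out out/
lincatlas cerna       --in data/ --out out/
lincatlas tf          --in data/ --out out/
```

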