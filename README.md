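# srna — small RNA transcriptome analysis toolkit

`srna` re-implements, as a tested and reusable pipeline, the computational
workflow used to characterize the small RNA component of plant
transcriptomes — the kind of study that sequences adapter-ligated 18–30 nt
RNA libraries from several related species (here modeled on four cucurbits:
bottle gourd, *Cucurbita moschata*, *C. pepo* and watermelon) and asks:

1. What is in the libraries? Reads are collapsed to unique sequences and
   classified hierarchically into five categories — non-coding RNA
   fragments, known mature miRNAs, mRNA fragments, repeats, and
   genome-matched-but-unannotated — so that per-category unique/total
   counts partition the library exactly.
2. Which conserved miRNA families are expressed, and how much? Counts are
   normalized to transcripts per million (tpm = count / library total × 10⁶)
   and binned into abundance tiers (> 1000 tpm abundant, 100–1000 moderate,
   < 100 low), with cross-library fold-change comparisons.
3. Are there novel miRNAs? Unannotated genome-matched reads of 20–24 nt
   with ≤ 10 genomic loci are folded in their 160-nt genomic flanks with an
   internal maximum-base-pairing (Nussinov) folder; candidates must sit on
   one arm of a stem-loop with ≥ 16 of their bases paired to a compact
   opposing arm, and must be recovered in libraries of at least two genera.
4. Are there trans-acting siRNA (TAS3) loci? Transcripts are scanned for
   dual miR390-complementary sites 200–300 nt apart (penalty: mismatch 1,
   G:U wobble ½, seed positions 2–13 doubled). Cleavage between trigger
   positions 10/11 at the 3′ site sets a 21-nt phase; reads are assigned
   to registers D2(+), D3(+), … and an in-phase fraction is reported,
   along with the rank correlation between trigger and tasiRNA abundance.
5. What do the miRNAs target? Every transcript window is scored against
   each miRNA with the flat plant-target penalty (mismatch 1, G:U ½,
   ungapped) at the conventional 3.5 cutoff.
6. Do qPCR measurements agree? Delta-Ct relative expression
   (2^−(Ct_target − Ct_reference)) with two-sided Student's t-tests and
   `*`/`**` significance stars.

A first-class synthetic-data module (`srna.simulate`) builds toy genomes
with embedded precursor hairpins, a TAS3 locus with phased tandem repeats,
tRNA/rRNA/repeat decoys and adapter-ligated reads — with machine-readable
truth tables — so every stage can be validated end-to-end against ground
truth.

## Worked example

Summary arithmetic on a classified library (the bottle gourd library of the
four-cucurbit study; the `Total` row is always computed, never copied):

```python
>>> from srna.annotate import AnnotationSummary
>>> from srna.pipeline import render_table1
>>> rows = {"ncRNA": (249_263, 12_135_459), "miRBase": (27_287, 726_073),
...         "mRNA": (80_675, 338_251), "repeats": (222_416, 2_156_450),
...         "genome": (1_017_622, 14_284_275)}
>>> print(render_table1({"bottle_gourd": AnnotationSummary("bottle_gourd", rows)}))
         bottle_gourd Unique  bottle_gourd Total
ncRNAs                249263            12135459
miRBase                27287              726073
mRNAs                  80675              338251
Repeats               222416             2156450
Genome               1017622            14284275
Total                1597263            29640508
```

The computed totals (1,597,263 unique / 29,640,508 total) are the library's
size; the miRBase category normalizes to

```python
>>> from srna.abundance import tpm, tier
>>> v = tpm(726_073, 29_640_508); round(v, 1), tier(v)
(24496.0, 'abundant')
```

End-to-end on synthetic data:

```bash
srna simulate --out study/ --seed 1      # 4-library preset + truth tables
srna run-all --config study/config.yaml  # all stages, reports under study/reports/
srna tas --transcripts study/ref_mRNA.fa --out tas.tsv
```

The last command prints `1 TAS loci detected` and writes

```
transcript  site5_start  site3_start  spacing  canonical
TAS3_1      0            271          250      True
```

i.e. one dual-site locus whose sites are 250 nt apart, with a cleavable 3′
site and a non-cleavable 5′ site (the canonical TAS3 configuration).

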