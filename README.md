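# dynamark

Dynamic histone-mark pattern analysis for multi-condition ChIP-seq.

`dynamark` is for epigenomics analysts who have binned ChIP and Input
coverage for three related conditions — a healthy reference, a disease
state, and a genetic or pharmacological rescue — and want to know which
genes or peak regions gain or lose a histone mark in disease, and whether
the rescue restores them. Typical use: repressive H3K27me3 or activating
H3K27ac domains profiled in macrophages from a disease model and its
receptor-knockout rescue.

## The method

For each unit (a gene's proximal window, by default −5 kb to +1 kb around
the gene body, strand-aware; or a peak interval) and each condition, the
per-bin ChIP intensity (CPM) is compared with the matched Input by a
one-sided Mann–Whitney U-test. The unit is **Increased (I)** in that
condition when

    p < 0.05   and   fold-change = (mean ChIP + c) / (mean Input + c) > 1.5

(pseudocount c = 0.25 CPM), and **Unchanged (U)** otherwise. The three
letters, in (reference, disease, rescue) order, form one of 2³ = 8 codes;
the four codes whose mark flips between reference and disease are the
dynamic classes

| class | code | reading |
|-------|------|---------|
| GP1/PP1 | IUI | lost in disease, restored by rescue |
| GP2/PP2 | IUU | lost in disease, not restored |
| GP3/PP3 | UII | gained in disease, not reverted |
| GP4/PP4 | UIU | gained in disease, reverted by rescue |

and the other four codes are static. Peak-mode calling adds a consistency
filter: the per-bin log2 fold-change of every I-condition must
stochastically exceed every U-condition's (one-sided Mann–Whitney
p < 0.05), otherwise the peak is demoted to static.

Gene-set enrichment of a pattern pt in a list of n genes with k carrying
pt uses the binomial survival test

    P = P(X > k),  X ~ Binomial(n, p_b),

where the background p_b is the genome-wide fraction of assessed genes
carrying pt.

A negative-binomial coverage simulator with planted I/U structure
(`dynamark.synthetic_data`) makes the whole pipeline testable end to end
without any external data.

## Worked example

Simulate a 60-gene dataset, call gene patterns, and score recovery against
the planted truth:

```python
import dynamark as dm

cfg = dm.SimulationConfig(seed=7, n_genes=60, n_chroms=1, chrom_length=1_000_000)
tracks, genes, truth, sizes = dm.simulate_dataset(cfg, outdir="demo")
cpm = {c: {ch: dm.normalize_cpm(t) for ch, t in chs.items()}
       for c, chs in tracks.items()}
tab = dm.call_gene_patterns(cpm, genes, dm.WindowSpec(), dm.CallParameters(),
                            sizes, conditions=list(cfg.conditions))
print(tab[["unit_id", "code", "class_label", "p_disease", "fc_disease"]].head())
print(dm.summarize_patterns(tab))
print(dm.evaluate_recovery(tab, truth)[2])
```

prints

```
unit_id code class_label    p_disease  fc_disease
  g0001  UII         GP3 8.719622e-14    2.199423
  g0002  IUU         GP2 9.971432e-01    0.757046
  g0003  IUI         GP1 9.986624e-01    0.775235
  g0004  IUU         GP2 9.999983e-01    0.635019
  g0005  UII         GP3 5.257533e-13    2.014350

class_label  count  percent
        GP1     12       25
        GP2     12       25
        GP3     12       25
        GP4     12       25
      total     48      100

1.0
```

`g0001` gains the mark in disease without reversion (UII → GP3: disease
fold-change 2.2 at p ≈ 9e-14), `g0003` loses it in disease and regains it
in rescue (IUI → GP1). The summary counts the dynamic classes (48 of the
60 genes were planted dynamic, 12 per class) and the final `1.0` is the
classification accuracy against the planted truth.

The same workflow is available from the shell:

```sh
dynamark simulate --out demo --seed 7 --n-genes 60
dynamark call --config demo.yaml --out results   # tracks/genes/chrom.sizes paths
dynamark enrich --config demo.yaml --out results # + a GMT of gene sets
dynamark compare --config demo.yaml --out results
```

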