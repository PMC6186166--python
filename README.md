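# sigdepth

**How much sequencing depth does a drug-repurposing gene signature
need?** `sigdepth` answers that question for connectivity-mapping
workflows on bulk RNA-seq. It simulates reduced cDNA library depth by
binomially thinning gene-level counts, re-derives the
differential-expression (DE) signature at each depth, scores it against
a library of compound-induced expression profiles, and quantifies how
stable the significant compound connections are as reads are removed.
It is written for bioinformaticians who build disease gene signatures
(e.g. tumour-progression contrasts) and need to know whether their
compound hits would survive a shallower — or merely noisier —
sequencing run.

## The analysis

Starting from a gene × sample count matrix with a two-group contrast
and a reference library of per-gene differential-expression scores
z<sub>g</sub> per perturbagen × cell line:

1. **Thinning.** Each count *n* is replaced by Binomial(*n*, *f*) for a
   grid of retention fractions *f* ∈ (0, 1], *K* independent iterations
   per fraction (default *K* = 25); *f* = 1 is the single reference run.
2. **DE and signature.** Relative-log-expression (median-of-ratios)
   size factors; NB dispersions by method of moments, shrunk to a fitted
   mean–dispersion trend α(μ) = α₀ + α₁/μ; Wald test on
   log₂FC = log₂((μ̂_B + ½)/(μ̂_A + ½)); Benjamini–Hochberg adjustment;
   signature = up/down genes with padj ≤ 0.05 and |log₂FC| ≥ 1, capped
   at 100 per direction.
3. **Connectivity.** For each profile,
   score = [Σ_up z(g) − Σ_down z(g)] / (sum of the k largest |z|) ∈ [−1, 1];
   negative = the compound **rev**erses the signature (therapeutic
   direction), positive = it **prog**resses it. Significance by a
   permutation null of random same-sized signatures (shared across
   profiles; enumerated exhaustively when feasible), aggregated to
   perturbagen level and BH-adjusted.
4. **Stability statistics.** Per fraction: DEG/connection counts with
   percentile CIs; *relative FDR* = |S_f \ S₁| / |S_f| (connections not
   supported by the full data, counted as false positives);
   per-connection *frequency* over the K iterations; Venn partition of
   consensus sets across fractions with lost/gained/consistent views;
   top-k reverser ranking overlap.

A synthetic-data module generates the whole study with planted truth —
NB counts with a known DE fraction, a profile library with planted
reversers, progressors and nulls across cell lines (optionally tagged,
e.g. `neuronal`), and GO-like gene categories with optional gene-length
bias for the Wallenius enrichment stage — so every stage is testable
offline. See `docs/methods.md` for models, defaults and limitations.

## Worked example

```python
import sigdepth as sd

config = sd.SimConfig(seed=7)                      # 2,000 genes, 6 vs 6
counts, truth = sd.generate_counts(config)
library, truth = sd.generate_reference_library(truth, config)

summary = sd.run_grid(
    counts, library,
    sd.FractionGrid(fractions=(0.01, 0.1, 0.5, 1.0), iterations=25),
    conn_config=sd.ConnectivityConfig(M=2000),
    master_seed=7, top_k=10,
)
for f in summary.fractions:
    n_deg = summary.per_fraction[f]["n_deg"]
    n_rev = summary.per_fraction[f]["n_sig_rev"]
    fdr = summary.per_fraction[f]["fdr_rev"]
    print(f"f={f:<5g} DEGs {n_deg[0]:6.1f}  rev {n_rev[0]:4.1f}  "
          f"relative FDR {fdr[0]:.3f} [{fdr[1]:.3f}, {fdr[2]:.3f}]")
print("reversers found at every fraction:", sorted(summary.consistent))
```

prints

```
f=0.01  DEGs    6.9  rev  8.2  relative FDR 0.022 [0.000, 0.111]
f=0.1   DEGs  114.8  rev  8.0  relative FDR 0.000 [0.000, 0.000]
f=0.5   DEGs  176.1  rev  8.0  relative FDR 0.000 [0.000, 0.000]
f=1     DEGs  185.0  rev  8.0  relative FDR 0.000 [0.000, 0.000]
reversers found at every fraction: ['pert02', 'pert05', 'pert17', 'pert24', 'pert27', 'pert29', 'pert33', 'pert35']
```

Reading this: with full data the pipeline recovers all 8 planted
reversers (mean rev count 8.0) and, by construction, zero relative FDR.
At 1% of reads the signature is nearly destroyed (6.9 DEGs on average
against ~185 at full depth); the few surviving genes still point at the
strongly planted reversers on most iterations, but spurious connections
now appear that the full data never supported — the mean relative FDR
is nonzero and reaches 11% on the worst iterations, and the rev count
overshoots 8 for the same reason. On other master seeds the f = 0.01
signature empties entirely on some iterations and planted compounds
drop out of the consensus — both failure modes the tool is meant to
expose.

The same pipeline is scriptable from the shell:

```bash
sigdepth simulate --seed 7 --out study/
sigdepth thin --f 0.5 --seed 3 --in study/counts.tsv --groups study/groups.tsv --out thinned.tsv
sigdepth de --in study/counts.tsv --groups study/groups.tsv --out de.tsv --sig sig.gmt
sigdepth connect --sig sig.gmt --lib study/library.tsv --m 10000 --seed 1 --out connections.tsv
sigdepth grid --config run.yaml --out results/
sigdepth report --kind fdr --summary results/summary.json
```

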