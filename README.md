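# oralsite

Comparative analysis of paired **saliva / buccal-mucosa 16S microbiota** for
forensic source attribution and personal identification, built as a tested,
reusable Python pipeline with a synthetic paired-cohort generator so every
stage can be exercised end to end without sequencing data.

The scientific questions the pipeline addresses, for a cohort of subjects
each contributing one saliva and one buccal-mucosa sample:

1. **Do the two oral habitats differ?** α diversity (Shannon, Chao1,
   Gini-Simpson), Bray–Curtis β diversity with NMDS ordination, and
   per-taxon Welch *t* contrasts of genus/phylum relative abundances.
2. **How are the communities assembled?** Sloan's neutral community model
   relates a taxon's metacommunity relative abundance *p* to its occurrence
   frequency through Beta(*Nm·p*, *Nm·(1−p)*) local abundances, with the
   migration parameter *Nm* fitted by least squares and an occupancy band
   partitioning taxa into above / fit / below the neutral expectation.
   A fixed-fixed null model (curveball randomization preserving sample
   richness, sample totals and taxon occupancy) yields
   `ses.beta = (obs.beta − mean.null.beta) / sd.null.beta` and a
   deterministic-strength percentage
   `DS = 100 · mean(max(0, relative departure of each pair from its null))`.
3. **Can a stain be traced to a habitat?** A random forest on ASV relative
   abundances: stratified 70/30 split, importance ranking on the training
   set, refit on the top-30 ASVs, train/test accuracy and confusion counts.
4. **Can a sample be traced to a person?** Species ranked outside the
   top-100 by mean relative abundance that occur in exactly one individual
   ("unique species", discriminated fraction), the core genera present in
   every subject, and the **microbial code** — each individual's
   relative-abundance profile renormalized over the core genera — matched
   by Bray–Curtis distance against a reference panel.

## Worked example

```python
import oralsite as o

# a paired cohort of 20 subjects with the package's default habitat profiles
cfg = o.SimulationConfig(n_individuals=20, reads=(20_000, 30_000), seed=7)
table, taxonomy, metadata = o.generate_paired_study(cfg)

table = o.remove_singletons(table)
depth = o.rarefaction_depth(table)          # 95% of the minimum sample total
prepared = o.rarefy(table, depth, seed=7)

shannon = o.alpha_diversity(prepared, "shannon")
test = o.compare_groups(shannon, metadata)
print(f"depth={depth}  saliva={test.means[1]:.3f}  "
      f"mucosa={test.means[0]:.3f}  p={test.pvalue:.2e}")

report = o.classify_habitat(prepared, metadata, seed=7)
print(f"RF train {report.train_accuracy:.1f}%  test {report.test_accuracy:.1f}%")
```

prints

```
depth=19189  saliva=4.525  mucosa=3.381  p=6.92e-23
RF train 100.0%  test 100.0%
```

i.e. at this depth the saliva community is about one bit more diverse per
sample than the buccal mucosa (a richer, more even community), the contrast
is overwhelming at n=20/habitat, and the two habitats are perfectly
separable from relative abundances at these effect sizes.

The same stages are scriptable from the shell:

```bash
oralsite simulate --out study/ --seed 7
oralsite run --config config.yaml --out results/ --seed 7   # all six stages
```

`oralsite run` writes one directory per stage (simulate, prepare,
diversity, assembly, classify, discriminate) plus a manifest with SHA-256
digests of every output; two runs from the same config and seed are
byte-identical.

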