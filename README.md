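# pathreach

Mutation-frequency-free prioritization of candidate cancer driver genes by
**pathway and reach resemblance**.

Most driver-gene catalogues are built from mutation recurrence, which misses
oncogenes activated by overexpression, tumor suppressors silenced by
methylation, and drivers of rare cancers. `pathreach` takes a
*guilty-by-resemblance* approach instead: a gene is a candidate driver if its
**pathway membership** and its **network connectivity level** look like those
of a reference set of well-established driver genes. It is aimed at
computational biologists who have a gene interaction network (STRING,
BioGrid, Pathway Commons style edge lists), pathway gene sets (Reactome-style
GMT), and one or more curated driver lists, and who want a ranked list of
novel candidates from a pathway of interest.

## The method

For a candidate gene *r* and a reference driver *c*:

* **Pathway similarity** — the Jaccard similarity index of their pathway
  membership lists,
  `JSI = |Lr ∩ Lc| / (|Lr| + |Lc| − |Lr ∩ Lc|)`,
  thresholded at a cutoff (default 0.0036, i.e. "share at least one pathway"
  under a Reactome-scale listing) to give the binary matrix **P**.
* **Reach similarity** — the *m*-reach of a gene is the fraction of network
  nodes reachable within *m* steps (default *m* = 2). Sorting the full
  network by 2-reach and cutting into four equal-count quantiles gives
  connectivity levels (Level 1 = hubs … Level 4 = periphery); matrix **R**
  flags candidate/driver pairs on the same level.
* **Resampled Fisher tests** — for each candidate, its P-row and R-row over
  a random subset of reference drivers (default 50 of them, 1,000 subsets)
  are cross-tabulated into a 2×2 table counting the (1,1), (1,0), (0,1),
  (0,0) combinations, and tested with Fisher's exact test. The genes ×
  replicates p-value matrix is Benjamini–Hochberg adjusted per replicate.
* **Gene score** — `GS = count(p > 0.05)/reps + mean(p)` on the adjusted
  p-values; GS ∈ [0, 2], lower is more driver-like, GS ≤ 1 defines
  candidacy. Candidates are ranked ascending; known reference drivers are
  flagged and the remainder is the novel list.

A synthetic-data module generates degree-skewed interaction networks,
overlapping pathway sets, and planted driver sets with a tunable
`enrichment` knob coupling both resemblance channels, so the entire pipeline
is testable without any database downloads. Classifier evaluation (confusion
metrics, MCC, ROC/AUC) and a reach-order comparison (*m* = 1, 2, 3) are
included.

## Worked example

```sh
python examples/01_end_to_end_synthetic.py
```

```
60 genes pass the gene-score threshold (GS <= 1); 20 are novel (not reference drivers).

top 10 candidates (lower GS = stronger resemblance to the reference set):
           gs  freq_gt_alpha  mean_p  known_driver  rank
gene
G00000 0.0000         0.0000  0.0000          True     1
G00011 0.0000         0.0000  0.0000          True     2
...
20 / 20 planted drivers recovered in the novel candidate list.
```

The scenario plants 20 drivers that copy the pathway memberships and 2-reach
level of reference templates; all 20 end up in the novel candidate list with
gene scores near 0, while unrelated genes score near 2 (their adjusted
p-values sit at 1). `examples/04_compare_reach_orders.py` repeats the run
with *m* = 1, 2, 3 and prints ROC AUCs (0.71 / 1.00 / 0.94 on the default
scenario): 2-reach separates planted drivers best, degree (1-reach) is too
coarse and 3-reach saturates on a small-world network. The other examples
show reach-level tables and reference-set Venn algebra.

The same pipeline runs from the shell on real files:

```sh
pathreach run --network string.tsv --score-column 3 --min-score 400 \
    --gmt reactome.gmt --cd-pathway "Signal Transduction" \
    --drivers dr3genes.txt --seed 1 --outdir out/
```

writing `candidates.csv`, `pvalues.csv`, `levels.tsv`, `stats.json` and a
run manifest. Subcommands `reach`, `jsi`, `evaluate`, `simulate` and `venn`
expose the individual stages.

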