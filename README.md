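# lsed — localization-specific centrality for essential protein prediction

Essential proteins tend to be topologically central in protein–protein
interaction networks (PINs) — the centrality-lethality rule — so ranking
proteins by a centrality score is a standard way to nominate essentiality
candidates. A global PIN, however, pools interactions from every subcellular
context, and a protein's global centrality mixes roles it plays in different
compartments. `lsed` implements the localization-specific alternative:

1. **PSLIN construction.** Given localization annotations `Loc(i)`, the
   global PIN `G = (V, E)` is split into one Protein Subcellular Localization
   Interaction Network per compartment: `S_i = (V_i, E_i)` with
   `V_i = V ∩ Loc(i)` and `E_i` the global edges with both endpoints in
   `V_i`. Multi-localized proteins appear in several PSLINs.
2. **Confidence levels.** Each PSLIN is weighted by
   `C(S_i) = |S_i| / |S_Max|` — its protein count over the largest PSLIN's —
   in (0, 1].
3. **Per-PSLIN centrality.** Any of seven centralities (DC, BC, CC, SC, EC,
   IC, NC — degree, betweenness, closeness, subgraph, eigenvector,
   information, edge-clustering-coefficient) is computed inside each PSLIN;
   `Ess(p, S_i) = 0` where `p ∉ S_i`. Externally computed scores (e.g.
   orthology-based methods) plug in through score tables.
4. **LCS combination.** Scanning PSLINs in descending confidence order, each
   protein's Localization-specific Centrality Score starts at 0 and, whenever
   `Ess(p, S_i) > LCS(p)`, moves toward it by the confidence fraction:
   `LCS(p) ← LCS(p) + (Ess(p, S_i) − LCS(p)) · C(S_i)`.
5. **Ranking & evaluation.** Proteins are ranked by descending LCS, and
   rankings are scored against a benchmark essential set: `Acc` (percentage
   of true essentials in the top c%), `IAcc` (relative improvement over a
   baseline ranking), `AIAcc` (mean IAcc over cutoffs), `AKAcc` (mean Acc
   over species), plus a top-k difference analysis between two rankings.

The package also ships a synthetic-data generator that plants the structure
the method exploits — per-compartment scale-free subnetworks with
essentiality enriched among within-compartment hubs — so the whole pipeline
is testable without database downloads.

## Worked example

```sh
lsed simulate --seed 1 --out data/
lsed rank --network data/network.tsv --annotations data/annotations.tsv \
     --method DC --lsed --out data/lsed_dc.tsv
lsed rank --network data/network.tsv --method DC --global --out data/dc.tsv
lsed evaluate data/lsed_dc.tsv data/dc.tsv \
     --essentials data/essentials.txt --top 1,5,10,15,20,25 --out data/report/
```

The evaluate step prints, for this seed:

```
    ranking  cutoff_pct  n_selected  n_essential  acc_pct
lsed_dc.tsv         1.0          15            9  60.0000
lsed_dc.tsv         5.0          75           48  64.0000
lsed_dc.tsv        10.0         150           86  57.3333
lsed_dc.tsv        15.0         225           99  44.0000
lsed_dc.tsv        20.0         300          111  37.0000
lsed_dc.tsv        25.0         375          120  32.0000
     dc.tsv         1.0          15           11  73.3333
     dc.tsv         5.0          75           48  64.0000
     dc.tsv        10.0         150           78  52.0000
     dc.tsv        15.0         225          103  45.7778
     dc.tsv        20.0         300          115  38.3333
     dc.tsv        25.0         375          121  32.2667

IAcc of lsed_dc.tsv over dc.tsv:
 cutoff_pct  iacc_pct
        1.0  -18.1818
        5.0    0.0000
       10.0   10.2564
       15.0   -3.8835
       20.0   -3.4783
       25.0   -0.8264
AIAcc: -2.69%
top-100 difference: 25 proteins per side; essential 68.0% (lsed_dc.tsv) vs 48.0% (dc.tsv)
```

Read: of the 150 proteins in the top 10% by localization-aware degree, 57.3%
are truly essential versus 52.0% for plain global degree, against an overall
essential prevalence of ~16% in this dataset — a 3.5× enrichment. Among the
25 top-100 proteins the two methods disagree on, the localization-aware
picks are essential far more often (68% vs 48%). Single-seed per-cutoff
IAcc values are noisy — at the 1% cutoff only 15 proteins are selected, so
one protein swings the value by ±7 points — which is why the package's own
end-to-end check averages the top-10% accuracy over 10 generator replicates
(see below) rather than judging one draw.

`lsed simulate --seed N` is deterministic: the same seed always yields
byte-identical files. Every ranking is written next to a `*.manifest.yaml`
recording the configuration and input checksums that produced it.

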