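# betasurrogacy

Evaluate **β diversity as a conservation surrogate**: if species have unimodal
distributions along environmental gradients, then a set of sites chosen to
*span* compositional (β-diversity) space should capture many distinct
assemblages — and therefore many species — without knowing where any
individual species lives. This package implements that evaluation pipeline
end to end and provides a synthetic-community generator with exactly the
niche structure the argument assumes, so every stage can be validated
in silico.

The pipeline, for a site × species presence/absence matrix:

1. **β diversity** — pairwise Jaccard dissimilarity
   `d_ij = 1 − |A_i ∩ A_j| / |A_i ∪ A_j|` between site assemblages.
2. **Ordination** — nonmetric MDS (Kruskal stress-1, isotonic disparities,
   primary tie handling, majorization updates) and hybrid MDS (adds a metric
   least-squares term for pairs below a dissimilarity threshold, countering
   the saturation of Jaccard distance at 1); 10 starts each, up to 1,000
   iterations per start, lowest stress kept.
3. **Selection** — a regular grid of 10,000 demand points over ordination
   space; a hybrid heuristic (multistart randomized greedy + vertex
   substitution + path-relinking) picks the *p* sites minimizing total
   demand-point-to-nearest-site distance (the p-median problem), i.e. the
   network that best spans β-diversity space.
4. **Scoring** — the **Species Accumulation Index**

   `SAI = (S − R) / (O − R)`

   where `S` = species represented in the selected network, `R` = mean over
   1,000 random networks of the same size, and `O` = best achievable
   representation (forward greedy coverage combined with a backward
   "core-area" cell-removal ranking). SAI is 1 for an optimal surrogate, 0
   for a random-equivalent one, negative when worse than random. It is
   evaluated with 15%, 20%, 25%, 30% and 35% of sites retained, and a
   fraction is flagged significant when `S` exceeds the upper 95% confidence
   bound on the mean `R`.

## Worked example

```python
import betasurrogacy as bs

community = bs.generate_unimodal(seed=1)          # 300 sites x 150 species
m = bs.clean_matrix(community.occurrences)
report = bs.evaluate_surrogacy(m, seed=1)
print(f"stress {report.stress:.3f} ({report.method}); "
      f"mean SAI {report.mean_sai:+.3f}")
for pt, v, sig in zip(report.points, report.sai_values, report.significant):
    print(f"{pt.fraction:.2f} of sites (p={pt.p}): S={pt.S} R={pt.R:.1f} "
          f"O={pt.O:.0f}  SAI={v:+.3f}{' *' if sig else ''}")
```

prints

```
stress 0.127 (nmds); mean SAI +0.276
0.15 of sites (p=45): S=130 R=133.4 O=150  SAI=-0.207
0.20 of sites (p=60): S=143 R=139.6 O=150  SAI=+0.329 *
0.25 of sites (p=75): S=141 R=143.2 O=150  SAI=-0.319
0.30 of sites (p=90): S=148 R=145.3 O=150  SAI=+0.576 *
0.35 of sites (p=105): S=150 R=146.7 O=150  SAI=+1.000 *
```

Read: at 20% of the landscape the β-diversity-selected network represents
143 species, random networks average 139.6, the best possible is 150, so the
surrogate realised 33% of the achievable improvement over random selection
(and is significantly above random, `*`). The mean over the five fractions,
+0.28, is this community's overall surrogacy score.
Environment-independent null communities provide the negative control; see
`docs/methods.md` for what they do — and surprisingly do not — calibrate
away.

The `analysis/` scripts run the study as a narrative: `01` simulates the
communities, `02` ordinates them, `03` selects site networks, `04` scores
surrogacy, `05` sweeps seeds to give the cross-dataset distribution of SAI.
A `betasurrogacy` command-line tool wraps the same pipeline (`run`,
`simulate`, and the stage tools `ordinate`, `select`, `baseline`).

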