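# savor

Flavor-chemistry scoring and transcriptome screening for live-preservation
studies of soft-shell crustaceans.

Soft-shell mud crabs (*Scylla paramamosain*) are harvested in the brief
window after molting, and the preservation method (ambient seawater,
ice-chilled storage, low-temperature acidified seawater, ...) changes both
how fast the new shell hardens and the taste chemistry of the edible
hepatopancreas. `savor` implements the quantitative layer such studies need
to rank preservation methods:

* **Taste activity values.** For a compound at concentration *C* (mg/100 g
  tissue) with sensory threshold *T*, `TAV = C/T`; TAV ≥ 1 marks a
  perceptible taste contributor. Free amino acids are aggregated into umami
  (UAA: Glu, Asp), sweet (SAA: Ala, Gly, Pro, Ser, Thr), bitter (BAA) and
  total (TAA) pools.
* **Equivalent umami concentration** (Yamaguchi synergy model). With amino
  acid concentrations *aᵢ* and coefficients *bᵢ* (Glu 1, Asp 0.077) and
  nucleotide concentrations *aⱼ*, coefficients *bⱼ* (IMP 1, GMP 2.3,
  AMP 0.18), all in g/100 g:

  `EUC = Σaᵢbᵢ + 1218 (Σaᵢbᵢ)(Σaⱼbⱼ)`

  in grams of monosodium-glutamate equivalent per 100 g.
* **Group comparisons with compact letter displays.** Kruskal–Wallis omnibus
  plus exact pairwise rank-sum tests with Benjamini–Hochberg correction, or
  one-way ANOVA followed by Duncan's multiple range test; groups sharing a
  letter are not significantly different at α.
* **DEG screening.** Threshold filtering of differential-expression tables
  (|log₂FC| ≥ 1, FDR ≤ 0.05, boundaries inclusive), upset/Venn set algebra
  and cross-contrast sign-consistency counts.
* **Co-expression networks.** All-pairs correlation graphs filtered at
  |r| > 0.8 and BH q < 0.05, greedy-modularity module detection, and
  Guimerà–Amaral node cartography: within-module degree z-score
  `Zᵢ = (kᵢ − ⟨k⟩ₛ)/σₛ` and participation coefficient
  `Pᵢ = 1 − Σₛ (kᵢₛ/kᵢ)²`, with module hubs at Z > 2.5, connectors at
  P > 0.62, plus the annotation-based module quality filters.
* **Synthetic data.** Truncated-normal compound panels around a mean ± SD
  grid, planted-module latent-factor expression matrices and planted DEG
  tables, so every stage is testable without raw measurements.

The package ships the published compound panel (20 free amino acids and 3
flavor nucleotides × 3 storage groups, mean ± SD at n = 6) as its default
fixture.

## Worked example

```python
import savor

reference = savor.load_reference()
records = savor.load_panel_summary().rename(columns={"mean": "concentration"})

for row in savor.euc_by_group(records, reference).itertuples():
    print(f"{row.group}: EUC = {row.euc:.2f} g/100 g")
```

prints

```
CK48: EUC = 21.61 g/100 g
ICE48: EUC = 47.38 g/100 g
LTA48: EUC = 16.24 g/100 g
```

i.e. ice-chilled storage (ICE48) roughly doubles the umami equivalence of
the seawater control (CK48) — driven by higher IMP, AMP and Asp — while
acidified seawater (LTA48) lowers it. `savor.compute_tav(540.15, 60)` gives
9.00, alanine's taste activity under ice-chilled storage, up from 4.16 in
the control: a sweeter profile. The `examples/` scripts walk through each
capability (taste scoring, letter displays, DEG screening, network roles)
end to end.

A thin CLI mirrors the library: `savor report` writes `tav.csv`,
`categories.csv`, `euc.csv` and a `report.json` of recomputed headline
values with pass/fail flags; `savor tav|euc|compare|degs|network|simulate`
expose the individual stages.

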