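# agomg

Trajectory analysis of Mg²⁺ effects on an Argonaute–miRNA–target-RNA
complex: duplex base-pairing energetics by region with factorial contrast
tests, RMSF-based two-state conformational entropy, ion-binding counts
under periodic boundaries, and domain superposition metrics.

## The problem

Argonaute (Ago2) loads a miRNA guide strand and slices target mRNAs that
pair with it; the slicing cycle (loading → nucleation → propagation →
cleavage → release) requires both duplex stability and protein
flexibility. Intracellular Mg²⁺ shifts that balance: extra cations
stabilise the guide–target duplex but stiffen the protein. This package
implements the quantitative side of that analysis for two conditions — a
low-Mg²⁺ system ("low": only the two catalytic ions buried in the PIWI
domain) and a high-Mg²⁺ system ("high": ten additional ions, ≈5 mM in a
152 Å cubic periodic box) — with four replicates each.

The statistics it computes:

- **Regional pairing energy.** The 15-bp duplex is split into three
  contiguous regions indexed from the target 5′ end (pairs 1–4, 5–11,
  12–15). Per-frame, per-base-pair nonbonded energies
  `E = Σ kₑ qᵢqⱼ/(εᵣ rᵢⱼ) + εᵢⱼ[(Rᵢⱼ/rᵢⱼ)¹² − 2(Rᵢⱼ/rᵢⱼ)⁶]`
  are averaged per region, and the long-format observations are fitted
  with the full OLS model `Energy ~ Region + Group + Region×Group`; each
  region's low-minus-high difference ΔE is tested as a linear contrast
  against the full-model residual variance.
- **Conformational entropy.** Per-residue Cα RMSF over the aligned
  trajectory is binned into ordered (RMSF < 3 Å) and disordered states;
  `S = −Σ pᵢ ln pᵢ` (so 0 ≤ S ≤ ln 2 nats). Higher S means a more
  flexible backbone.
- **Ion contacts.** An ion is bound when its minimum-image distance to
  any complex (or duplex) atom is strictly below 5 Å.
- **Superposition.** Kabsch least-squares rigid fits (reflections
  suppressed) give per-domain RMSDs (PAZ, MID, PIWI, whole protein) and
  closest-residue-pair traces between the PAZ subdomains.

Because the analysis is meant to be testable without molecular dynamics,
`agomg.synthetic_data` generates seeded stand-in systems with known ground
truth: a 682-residue coarse protein with 18 unresolved residues (664
resolved Cα), the miR-21 guide `3′-GUCAGACUAUUCGAU-5′` paired perfectly
antiparallel with target `5′-CAGUCUGAUAAGCUA-3′`, inner and diffusing
ions, group-dependent fluctuation profiles, and per-cell energy
observations.

## Worked example

```python
import agomg, json

report = agomg.run_pipeline(agomg.RunConfig(seed=42))
print(json.dumps(report.summary, indent=1, sort_keys=True))
```

prints (abridged):

```
"delta_e": {
 "Region1": 1.8074900692867313,
 "Region2": 1.745245727859674,
 "Region3": -1.1698652418972892
},
"entropy_S_high": 0.2398661752964437,
"entropy_S_low": 0.2783277617172362,
"ion_concentration_mM_high": 4.728444912631462,
"paired_rmsf_t": {"df": 663, "p": 1.65e-56, "t": 17.41}
```

Read this as: the low-Mg²⁺ duplex sits ~1.8 kcal/mol above the high-Mg²⁺
duplex in the terminal and central regions (positive ΔE: extra ions
stabilise those pairings) but ~1.2 kcal/mol below it in the target-3′
region; the low-Mg²⁺ protein backbone carries more conformational entropy
(0.278 vs 0.240 nats) and its per-residue RMSF exceeds the high-Mg²⁺
profile essentially everywhere (paired t = 17.4 on 663 df); and the ten
extra ions in the 152 Å box correspond to 4.73 ≈ 5 mM. The report also
carries per-condition tables (RMSD series, RMSF profiles, ion-binding
series, pair-energy matrices, a regional summary table, and the
per-domain superposition report), all written as TSV by
`report.write(out_dir)`.

The same run is available from a shell:

```sh
agomg compare --seed 42 --out results/run42
agomg report --out results/run42
```

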