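# vinlock

Computational analysis of the two-step unlocking of vinculin.

Vinculin, a core mechanosensitive component of focal adhesions (FAs),
autoinhibits by docking its tail domain (Vt) against two of its head
domains: a large, mostly hydrophobic Vt–D1 contact and a smaller, largely
electrostatic Vt–D4 contact. This package implements, end to end, the
computational side of showing that activation proceeds through a discrete
*semi-open* intermediate — the Vt–D4 lock breaks first — and that the
closed (C), semi-open (SO) and open (O) conformers differentially control
FA growth and stability. It covers four vinculin forms: wild type, the
muscle splice isoform metavinculin (a 68-residue acidic insert between
hinge and tail), the tail mutant T12 (D974A/K975A/R976A/R978A) and
T12-A974K.

## What it computes

- **Crystal-interface anatomy** (`vinlock.structio`): PDB/mmCIF reading,
  domain partitioning, Shrake–Rupley SASA, buried interface areas
  (half-buried-SASA convention, `(SASA(a)+SASA(b)−SASA(a∪b))/2` per
  chain), a two-tier hydrogen-bond census (short < 3.5 Å, long ≤ 4.0 Å on
  donor/acceptor heavy atoms) and cross-variant bond matching with the
  +68 metavinculin numbering offset.
- **Anchoring spots** (`vinlock.anchors`): ray-cast cavity detection plus
  seeded rigid side-chain probes (K/R/E/N/T/I/P/F, from Cβ; Cα kept for
  Thr/Ile) scored by ΔG = vdW + solvation + screened electrostatics;
  spots with ΔG ≤ −3 kcal/mol are "strong". Anchor *identities* are the
  supported claim, not ΔG magnitudes.
- **Theoretical CCS and opening models** (`vinlock.ccs3d`): projection-
  approximation collision cross sections (orientation-averaged rasterised
  shadow area), rigid displacement of the tail under a hinge tether, CCS
  vs. tail–head separation scans, and one-to-many matching of candidate
  geometries to experimental state CCS values.
- **Native IM-MS** (`vinlock.imms`): charge-state envelope detection with
  harmonic-safe charge-ladder inference, traveling-wave power-law CCS
  calibration (`Ω = a t'ᵇ z √(1/m + 1/m_gas)`), drift→CCS conversion with
  replicate errors, and compact/extended ensemble splitting.
- **CIU fingerprints** (`vinlock.ciu`): voltage × CCS fingerprints of the
  charge-reduced 17+ ion on the 50–240 V grid (5 V steps), a
  shared-component Gaussian-mixture fit whose per-voltage weights give the
  C/SO/O occupancy trajectories, transition onset/completion at a 10%
  presence threshold, and gradual-vs-abrupt classification
  (coexistence ≥ 15 V = gradual).
- **FA morphometry** (`vinlock.famorph`): per-FA area/length/intensity
  from labelled masks, log-normal size fits with 95% CIs, photobleaching
  correction against a reference channel, and plateau-exponential decay
  fits `I(t) = p + (1−p)e^(−kt)` with initial slope `100·k·(1−p)` %/min.
- **Synthetic data** (`vinlock.synthgen`): fully seeded generators for
  spectra, calibrant tables, CIU records, conformer ensembles and FA
  image time-lapses whose defaults transcribe the published observations;
  every generator truth is recoverable by its consumer module.
- **Orchestration** (`vinlock.pipeline`): `reproduce(seed, out_dir)` runs
  the whole desk-scale analysis with stage isolation and a JSON report.

There is no command-line interface: the importable API plus the short
narrative scripts in `examples/` are the intended surface.

## Worked example

`python examples/05_ciu_fingerprint.py` generates CIU records for all
four variants, fits the shared three-state mixture and prints:

```
vinculin     : C  6266 / SO  6967 / O  7264 A^2
               C->SO onset 140 V, completion 180 V -> gradual; SO->O onset 190 V
               semi-open dwell 85 V
metavinculin : C  6281 / SO  7057 / O  7362 A^2
               C->SO onset 140 V, completion 145 V -> abrupt; SO->O onset 185 V
               semi-open dwell 80 V
t12          : C  6107 / SO  6851 / O  7172 A^2
               C->SO onset 120 V, completion 125 V -> abrupt; SO->O onset 185 V
               semi-open dwell 100 V
t12_a974k    : C  6163 / SO  6849 / O  7279 A^2
               C->SO onset 120 V, completion 125 V -> abrupt; SO->O onset 140 V
               semi-open dwell 45 V
```

Read: every variant passes through the same three conformer states
(centroids in Å²). Weakening the Vt–D4 lock (T12, T12-A974K) lowers the
first unlocking step to 120 V; wild type opens gradually over 140–180 V
while metavinculin switches abruptly; the extra lysine of T12-A974K makes
its semi-open state much shorter-lived (45 V dwell) than T12's (100 V).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the desk-scale headline numbers from scratch by running the
packaged generators through the analysis pipeline: the closed-state CIU
centroid and C→SO onset for wild-type vinculin, the T12 onset, the
T12-A974K major-charge-state count, the metavinculin extended-population
percentage, and the bleaching-corrected initial FA decay slope. The
`--seed` argument drives every source of randomness; results are written
as JSON to `--out`.
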