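# flowspps

Analytics for in-line UV monitoring of flow solid-phase peptide synthesis
(flow-SPPS): per-residue Fmoc-deprotection peak metrics, the **aggregation
factor (AF)**, aggregation-onset calling, UHPLC crude-purity integration,
and monoisotopic-mass verification of C-terminal hexaarginine ("ArgTag")
removal.

## The problem

During SPPS the growing protected chain can aggregate on the resin
(β-sheet association), which ruins coupling and deprotection efficiency.
Flow synthesizers watch every Fmoc deprotection through an in-line UV–vis
detector at 310 nm: the released fluorenyl chromophore passes the flow
cell as a transient peak.  On a well-solvated resin the peak is tall and
narrow; on an aggregated resin it broadens and flattens.  Appending six
C-terminal arginines (the ArgTag) suppresses aggregation; the tag is
later removed enzymatically by Carboxypeptidase B, which is verified by
mass (−156.10111 Da per arginine).

For each residue *i* (synthesis order, C→N) the deprotection peak is
summarized by its height *hᵢ* and full width at half maximum *wᵢ*, and
the aggregation factor combines them relative to a reference residue
*r* chosen before any aggregation:

```
AFᵢ = wᵢ/w_r − hᵢ/h_r
```

AF is dimensionless, exactly 0 at the reference, invariant under any
uniform rescaling of the absorbance or time axes, and rises when peaks
broaden and flatten.  Aggregation **onset** is the first residue whose
AF exceeds a threshold θ for m consecutive residues (defaults θ = 0.2,
m = 2, with the first 3 residues reserved as baseline); the persistence
requirement rejects single-cycle artifacts such as a deliberately cold,
slow cysteine coupling.  Synthesis quality is read out independently as
**crude purity**: the product peak's share of total integrated area in
the crude UHPLC chromatogram at 214 nm.

Because raw instrument archives are not bundled, the package ships a
first-class synthetic-data generator (`flowspps.synthetic_data`) that
emulates deprotection traces — exponentially modified Gaussian peaks
whose width grows geometrically and whose area attenuates after a
programmable onset residue, plus noise and baseline drift — and UHPLC
chromatograms with known component fractions, each with an exact
ground-truth sidecar.

## Worked example

```python
import flowspps as f

# a 16-residue fragment, parent numbering 75–90 (synthetic placeholder
# sequence), synthesized C→N starting from residue 90
labels = f.synthesis_labels("KKAVINGEQIRSISDL", 75)
cfg = f.SimulationConfig.preset(
    "afps", labels, onset_index=7, broadening_rate=0.15,
    yield_per_residue=0.97, noise_sd_au=0.02, seed=11,
)
trace, schedule, truth = f.simulate_deprotection_trace(cfg)

res = f.AggregationMonitor(trace, schedule, reference_label=labels[0]).fit()
print(res.summary())
```

prints (abridged):

```
Aggregation monitoring summary
==============================
run:            sim-seed11
residues:       16 analyzed, 0 failed
reference:      L90
onset rule:     theta=0.2, m=2, baseline_n=3
onset residue:  Q83

residue_label  height_au  fwhm_s  area_au_s      af flags
          L90     1.0351  6.8320    15.3193  0.0000
          ...
          I84     1.0580  6.6882    16.3419 -0.0432
          Q83     0.8912  7.7665    15.0174  0.2758
          E82     0.7535  9.1509    15.2035  0.6115
          ...
          K75     0.2701 27.8982    15.3015  3.8225
```

The first seven residues sit at AF ≈ 0 (no aggregation); from Q83 on the
peaks broaden (fwhm_s grows ~15% per residue) and flatten, AF rises
steeply and persistently, and the onset call Q83 matches the generator's
ground truth.  `res.plot()` draws the AF-vs-residue profile with the
onset region shaded.

Mass bookkeeping for the built-in GLP-1[7–37] fixture:

```python
rep = f.mass_report(f.parse_sequence(f.synthetic_data.GLP1_7_37))
# {'length': 31, 'c_terminus': 'acid',
#  'monoisotopic_da': 3353.668, 'average_da': 3355.71}
```

The same pipeline is available from the shell:

```bash
flowspps simulate --sequence KKAVINGEQIRSISDL --first-residue-number 75 \
    --onset-index 7 --noise-sd 0.02 --seed 11 --outdir run1
flowspps analyze run1/trace.csv run1/schedule.csv --reference L90 --outdir run1/out
flowspps mass HAEGTFTSDVSSYLEGQAAKEFIAWLVKGRG --c-term acid
flowspps detag-check --mass-before 4290.2748 --mass-after 3353.6681 --n-expected 6
```

## Layout

| module | contents |
| --- | --- |
| `flowspps.model` | `AggregationMonitor`/`PurityModel` with `.fit()` → results objects |
| `flowspps.peak_analysis` | baseline correction, peak h/w/area measurement |
| `flowspps.aggregation_factor` | AF computation, onset calling, profile comparison |
| `flowspps.purity` | chromatogram integration, crude purity |
| `flowspps.peptide_mass` | sequences, monoisotopic/average masses, ArgTag ops |
| `flowspps.synthetic_data` | seeded generators with exact ground truth |
| `flowspps.trace_io` | CSV/FASTA/JSON readers and writers |
| `flowspps.cli` | `flowspps` command (simulate/analyze/compare/purity/mass/detag-check) |

See `docs/methods.md` for the model, parameter and estimator details.
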