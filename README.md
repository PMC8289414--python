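# syncscope

Quantitative analysis of synchronized intracellular Ca²⁺ oscillations in
pancreatic islets of Langerhans, together with a ground-truthed simulator of
islet architectures and intravital fluorescence movies.

Islets secrete insulin in pulses because their β cells oscillate Ca²⁺ in
near-perfect synchrony, coupled through Cx36 gap junctions at homotypic
β–β contacts. When the islet's spatial architecture is disturbed — β cells
intermixed with α and δ cells, fewer homotypic contacts — synchrony degrades
even though every individual β cell still oscillates. `syncscope` implements
the measurements used to characterise that phenotype from time-lapse
recordings, for researchers analysing intravital or slice Ca²⁺ imaging and
for anyone validating such analyses against simulations with known truth:

- **Coordinated-area analysis** — movies are smoothed (5×5), masked,
  detrended and motion-gated; 5×5-pixel subregions whose detrended traces
  have peaks >1.5× the noise background are *active*, and active regions with
  pairwise Pearson R > 0.7 merge (transitively) into coordinated regions.
  Headline statistics: active fraction and the largest coordinated fraction
  (pixels of the largest region / active pixels).
- **Wave dynamics** — the islet-average power spectrum sets the peak
  frequency f; each subregion gets a phase φ from its Fourier component at
  f; the extreme-phase regions give a time lag, reported both with the
  literal published conversion `dt = (1/f_s)·arctan(φ₁ − φ₂)` (f_s the
  sampling rate) and with the standard `dt = (φ₁ − φ₂)/(2πf)`, and wave
  speed = centroid distance / dt. Speed is gated on >80% coordinated area
  and a planar phase gradient (R² ≥ 0.5).
- **Functional networks** — cells are linked when the Pearson correlation of
  their traces is ≥ R_th (0.95; a power-law calibration scan around 0.98 is
  included). Metrics: R_avg and its SD, percent-links distributions, hub
  fraction (cells linked to ≥25% of the islet), the published clustering
  coefficient C_i = degree/(n−1), characteristic path length
  L = Σ L_jk /(n(n−1)) and global efficiency E_glob = Σ 1/L_jk /(n(n−1)).
- **Architecture** — nearest-neighbour contact probabilities over four
  categories (β–β, β–α/δ, αα/δδ, α–δ) from typed cell maps.
- **Perfusion** — glucose-analog bolus arrival: arrival frame (first >5-unit
  mean-image jump), near/far ROI classes around vessels (10 µm cut), F/F_max
  normalisation over −5..+10 s, AUC, and across-ROI dispersion at +3 s.
- **Statistics** — the two-group decision tree (Shapiro–Wilk → F-test →
  Student/Welch t or Mann–Whitney) and ROUT outlier flagging at Q = 0.1%.
- **Simulation** — jittered-lattice elliptical islets with tunable β/α/δ
  intermixing, calcium movies with K phase-separated synchronization
  domains or planar travelling waves, mosaic sensor expression, noise,
  bleaching and saturation, and perfusion movies with per-pixel arrival
  delays — every latent variable returned as ground truth.

## Worked example

Simulate a two-domain islet (the signature of partially desynchronized
Ca²⁺ activity) and run the whole chain:

```python
import json
from syncscope import RunConfig, SimulationConfig
from syncscope.pipeline import run_pipeline

cfg = RunConfig(seed=7, simulation=SimulationConfig(seed=7, n_domains=2))
res = run_pipeline(cfg)
print(json.dumps(res.results["coordination"], indent=2, sort_keys=True))
```

prints

```json
{
  "active_fraction": 0.9078544712682761,
  "largest_coordinated_fraction": 0.5052434456928839,
  "n_regions": 2,
  "n_regions_ge_10pct": 2
}
```

Nearly all kept pixels are active (0.91), but the largest synchronized
region holds only half of the active area (0.505) and exactly two regions
each hold ≥10% of it — the analysis recovered the two ground-truth
synchronization domains. The same run reports the contact probabilities of
the generated architecture (`beta_homotypic` 0.742 at intermix 0.1,
control-like) and the network metrics of the per-cell traces. A fully
synchronized islet (`n_domains=1`) instead returns a largest coordinated
fraction of 1.0, and a planar-wave simulation yields an eligible phase map
whose recovered speed matches the configured one within a few percent.

The same steps are available from the shell:

```bash
syncscope simulate --seed 7 --out scratch/islet
syncscope architecture scratch/islet/cells.csv --out scratch/probs.json
syncscope run --config run.yaml
```

## Layout

- `src/syncscope/simulate.py` — architecture/movie/perfusion generators
- `src/syncscope/preprocess.py` — smoothing, masking, detrending, motion gate
- `src/syncscope/coordination.py` — activity and coordinated-region merging
- `src/syncscope/wave.py` — spectral peak, phase lag, wave speed
- `src/syncscope/network.py` — thresholded networks, hubs, small-world metrics
- `src/syncscope/architecture.py` — contact-category probabilities
- `src/syncscope/perfusion.py` — bolus-arrival kinetics
- `src/syncscope/stats.py` — decision tree, ROUT, validation suite
- `src/syncscope/{io,pipeline,cli,plotting}.py` — formats, driver, CLI, figures

See `docs/methods.md` for the model, parameter and design details.
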