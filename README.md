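# specstack

Reduction and chemical-state mapping of scanning-probe X-ray
fluorescence / XANES energy stacks.

Nano-focused hard X-ray probes map a sample's fluorescence at many
incident energies across an absorption edge, producing a 3D **energy
stack** (energy × Y × X) of element-line intensities per element. The
near-edge structure at each pixel encodes oxidation state and local
coordination, so the stack can be reduced to 2D *chemical-state maps* —
which mineral phase or oxidation state sits where, and in what proportion.
`specstack` implements that reduction for spectromicroscopy users
(biologists, geochemists, materials and environmental scientists working
at nanoprobe beamlines):

* frame **alignment** (subpixel cross-correlation against a reference
  frame, with validity masking),
* XANES **normalization** (pre-edge line, post-edge polynomial, edge-step
  division),
* component estimation and **matrix factorization**: the flattened stack
  `V (E × P)` is modeled as `V ≈ W H` with `k ≪ E` components — NMF (with
  a k-means-seeded, restart-protected solver) plus PCA / ICA / factor
  analysis / truncated SVD / dictionary learning; component spectra are
  matched to a reference library by Pearson correlation,
* **linear-combination fitting** by non-negative least squares:
  `d(E) ≈ Σᵢ cᵢ rᵢ(E)`, `cᵢ ≥ 0`, against normalized reference standards;
  per-pixel chemical maps, r-factor / reduced-χ² statistics, and
  **combinatorial screening** of every reference subset (sizes 1–5) with
  parsimony tie-breaks and flagging of few-percent components,
* **elemental correlation** analysis: per-pixel scatter of two element
  maps, deterministic region selection (box / polygon / line-band), and
  back-projection to binary pixel masks,
* a seeded **phantom generator** with exact ground truth (synthetic XANES
  standards, aggregate geometries, Poisson noise, beam drift) so every
  stage is testable without measured data.

## Worked example

Run the full workflow on the built-in 4-phase model phantom (73 energies
across the Fe K edge, Poisson noise at 10⁴ edge-jump counts, ground-truth
spectral fractions 0.50 / 0.20 / 0.12 / 0.18):

```python
from specstack.pipeline import RunConfig, run_pipeline

config = RunConfig(
    phantom=True,
    phantom_overrides={"spatial_shape": [64, 64]},
    seed=0,
    align=False,   # the phantom preset injects no drift
    k=4,           # component count, as read off the scree plot
)
results = run_pipeline(config, "demo_run")
print(open("demo_run/report.md").read())
```

prints (abridged):

```
## Component / reference correlation
- component_1: best match std_01
- component_2: best match std_02
- component_3: best match std_04
- component_4: best match std_03

## Combinatorial fitting
1023 subsets evaluated; selected rank 6:

| subset | normalized coefficients | r-factor | reduced chi2 |
|---|---|---|---|
| std_01, std_02, std_03, std_04 | (0.49, 0.20, 0.12, 0.18) | 1.03e-06 | 8.22e-07 |

## Chemical maps
Global spectral fractions (std_01: 0.49, std_02: 0.20, std_03: 0.12, std_04: 0.19); sum = 1.00

## Ground truth (phantom)
std_01: 0.49, std_02: 0.20, std_03: 0.12, std_04: 0.19
```

Reading this: all 1023 subsets of the 11-standard library (sizes 1–5) were
fitted to the stack's mean spectrum; the top-ranked rows are 5-component
supersets whose extra member contributes ~1% (flagged for inspection), and
the suggested clean solution — rank 6 — is exactly the generating
4-standard subset with coefficients matching the ground truth. The
per-pixel chemical maps integrate to the same global fractions, agreeing
with the ground truth to ±0.01. The output directory also holds the
component maps and spectra (TIFF/CSV), the correlation matrix, the scree
table, the ranking CSV, and a run log with the config hash.

The same steps are available from the shell:

```bash
specstack phantom --seed 0 --out phantom.h5
specstack align --stack phantom.h5 --ref -1 --upsample 10 --out aligned.h5
specstack decompose --stack aligned.h5 --method nmf --k 4 --out comps/
specstack fit --stack aligned.h5 --refs refs/ --out chem/
specstack run --config run.toml --out out/
```

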