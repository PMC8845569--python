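# polsarseg

Segmentation of **multi-temporal polarimetric SAR (PolSAR) time series into
crop/farmland parcel objects**, for users who need whole-parcel units — not
super-pixels — from radar imagery: crop mapping, parcel-level time-series
analysis, agricultural monitoring.

Crops that are indistinguishable on one acquisition date (same growth
stage, similar canopy) often separate clearly on another. Single-date
segmentation therefore merges neighbouring parcels that happen to look
alike; this package fuses the evidence of all dates:

1. **Per-date over-segmentation** — joint spatial–range mean-shift on the
   Pauli scattering amplitudes `(|S_hh+S_vv|, |S_hh−S_vv|, 2|S_hv|)/√2`,
   iterating `M_h(x) = Σᵢ G((xᵢ−x)/h) xᵢ / Σᵢ G((xᵢ−x)/h)` with a separable
   Gaussian kernel (bandwidths `h_s`, `h_r`), followed by mode grouping and
   a minimum-region-size pass `M`.
2. **Cross-date merging** — the per-date label maps are intersected; the
   result is a common refinement (regions never straddle a boundary that
   *any* date can see).
3. **Wishart edge detection** — for two pixel populations with sample-mean
   covariances Σ̂ᵢ, Σ̂ⱼ (Nᵢ, Nⱼ samples) and pooled Σ̂, the likelihood-ratio
   edge strength is
   `D(Sᵢ,Sⱼ) = (Nᵢ+Nⱼ)ln|Σ̂| − Nᵢln|Σ̂ᵢ| − Nⱼln|Σ̂ⱼ| ≥ 0`,
   evaluated in four directional half-windows per pixel; the per-pixel
   maximum `D_max` and its orientation θ\* are thinned by oriented
   non-maximal suppression and fused across dates by a pointwise maximum.
4. **Region graph + normalized cuts** — each merged region is represented
   by its extensibility centre (`E(p∈S) = Π L(α·i)`, the product of
   ray-cast distances to the region boundary); the pairwise dissimilarity
   `D_c(x,y)` is the maximum thinned edge strength on the line between
   centres, the affinity `W(x,y) = exp(−D_c²/2σ_C²)`, and the graph is cut
   into `k` segments by minimising the normalized cut
   `Ncut(A,B) = cut(A,B)/assoc(A,V) + cut(B,A)/assoc(B,V)`
   via the standard spectral relaxation (bottom eigenvectors of the
   normalised Laplacian + k-means).
5. **Evaluation** — USR-limited maximum-overlap accuracy: a reference
   region scores `|A∩SS|/|SS|` if its best-overlapping candidate `A` has
   under-segmentation ratio `USR = 1 − |A∩SS|/|A|` below a threshold, else 0.

A complex-Wishart **scene simulator** with known parcel ground truth makes
every stage testable without satellite data.

## Worked example

```bash
polsarseg simulate --height 120 --width 120 --parcels 4x4 --dates 3 \
    --looks 4 --seed 1 --out scene/
polsarseg segment --in scene/c3_date0.tif --in scene/c3_date1.tif \
    --in scene/c3_date2.tif --hs 2 --hr 0.3 --min-region 40 --max-iter 30 \
    --k 16 --looks 4 --seed 0 --out run/
polsarseg evaluate --reference scene/ground_truth.tif \
    --candidate run/segmentation.tif --usr 0.3
```

The `segment` command logs the region count after every stage and prints

```
per-date regions [125, 147, 147] -> 1430 merged -> 16 segments
```

i.e. each date is first split into ~130 small homogeneous regions, their
intersection yields 1,430 merged regions, and the normalized cut groups
them into the requested 16 parcels. `evaluate` then reports the
per-parcel and overall USR-limited accuracies (ending `overall: 0.99` for
this scene/seed): the 16 recovered segments cover their ground-truth
parcels almost completely. Running `segment` with a single `--in` date
instead yields overall accuracies near 0.44–0.48, because parcel pairs that
share a signature on that date are returned as one object and rejected by
the USR test — the quantitative version of the multi-temporal argument.

Each run directory contains every intermediate (per-date labels and edge
maps, merged labels, fused edges, region centres CSV, affinity matrix in
Matrix Market form) plus `manifest.json` with all parameters, seeds and
per-stage counts needed to reproduce the run. Every CLI flag can also be
given through a YAML config file (`--config cfg.yaml`, explicit flags take
precedence) with keys named exactly like `PipelineParams` fields
(`hs, hr, min_region, max_iter, tol, window, alpha_deg, sigma_c, k,
multilook_window, prefilter, method, seed`).

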