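# mcsquant

Quantitative analysis of ER–plasma-membrane contact sites, for cell
biologists working with electron cryo-tomography, correlative microscopy and
high-throughput yeast genetics.

In budding yeast, the cortical ER (cER) is held 10–30 nm from the plasma
membrane (PM) by three families of bridging proteins (VAPs, Ist2, and the
tricalbins — Extended-Synaptotagmin orthologs). Characterizing these
contacts quantitatively requires a set of measurements that are simple to
state but fiddly to get right on real tomographic data:

* **Intermembrane distance per contact site.** Points are clicked along the
  cytosolic leaflets of PM and ER in a tomogram (~every 10 nm in x/y, every
  5.5 nm across slices). The PM cloud is fitted with a total-least-squares
  plane, rotated into the plane frame, and interpolated with a biharmonic
  spline (Green's function g(r) = r²(ln r − 1)) onto a regular 20×20 grid.
  Per site, every ER point's minimum distance to the triangulated grid gives
  mean, SD, min and max distance in nm (one measurement N per site).
* **Tilt of membrane-bridging particles.** Each rod-shaped bridging density
  is picked with 4 points (ER base A, PM end B, auxiliary membrane points C
  and D ~10 nm away). After projection onto the common best-fit plane, the
  deviation from perpendicular to the PM is α = |90° − ∠(B−A, D−B)|.
* **Collapsed-2D subtomogram averaging.** Subvolumes are extracted in
  overlapping boxes along a membrane spline (or centred between the A–B
  points of particle picks, 444 Å box), sum-projected ("collapsed") into 2D
  images, and aligned/classified by multi-reference normalized
  cross-correlation with the rotation search restrained to a ±15° window
  around each box's orientation prior. Coat-layer thickness is the FWHM of
  the density band on the cytosolic PM leaflet of a class average; rod
  length is the distance between the cytosolic-leaflet peaks of PM and ER
  on a 15-pixel-wide line profile along the particle axis.
* **Coat coverage.** Ratio of segmented coat-layer volume to cER volume.
* **SGA interaction scoring.** 16×24 colony plates are normalized per
  plate, row and column (multiplicative median polish); the per-gene score
  is log2(query/control mean normalized size), with score < −1.00 (strict)
  calling a synthetic sick hit.
* **Cortical line profiles.** Two-channel fluorescence signal straightened
  along the cell cortex and compared across channels by Pearson correlation.

Because the real inputs (tomograms, colony plates, micrographs) are large
and partly manual, the package ships a first-class synthetic-data module
(`mcsquant.synthetic`) that generates every input with known ground truth:
clicked membrane point clouds with Gaussian click jitter, density volumes
with double-leaflet membranes, tilted bridging rods and coat slabs, 4-point
picks, colony plates with planted multiplicative effects, and two-channel
cortical ring images. Every measurement above is validated by parameter
recovery against these truths.

## Worked example

Reconstruct a flat contact site with 21.9 nm true separation and 1 nm click
jitter, and measure it:

```python
from mcsquant.synthetic import SiteTruth, gen_membrane_site
from mcsquant.surface import site_distance_stats

truth = SiteTruth(separation_nm=21.9, jitter_sd_nm=1.0, seed=7, site_id="demo")
pm, er = gen_membrane_site(truth, extent_nm=200.0)
st = site_distance_stats(pm, er)
print(f"mean {st.mean_nm:.2f} nm, SD {st.sd_nm:.2f}, "
      f"min {st.min_nm:.2f}, max {st.max_nm:.2f}, n={st.n_er_points}")
```

prints

```
mean 21.82 nm, SD 1.15, min 18.82, max 25.56, n=777
```

i.e. the chain recovers the planted 21.9 nm separation to within ~0.1 nm on
this site, with the spread reflecting the 1 nm click jitter on both
membranes. The `analysis/` scripts run the same chains as small narrative
studies (numbered in pipeline order) and write their tables under
`results/`; for example `python analysis/01_membrane_distances.py` surveys
three cohorts of sites at the separations reported for the three
bridging-protein families and prints the recovered grand means
(21.70 / 19.61 / 20.61 nm for truths 21.9 / 19.8 / 20.8 nm).

A CLI wraps the file-based entry points: `mcsquant distances`, `angles`,
`score`, `coverage`, `cortex`, `measure-rod`, `measure-layer`.

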