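# memthick

Analysis toolkit for measuring **local membrane thinning around membrane
proteins** in coarse-grained or atomistic ensembles, with companion tools
for model validation (RMSD/RMSF), helix geometry (spans, crossing angles),
water density maps, and signal-peptide **cleavage-efficiency statistics**
from gel densitometry.

## The scientific problem

Signal peptidase complexes (SPCs) cleave signal peptides at the ER
membrane, and substrate selection depends on how the transmembrane helix of
a substrate matches the *local* membrane thickness in the enzyme's
lipid-exposed "TM window". The central measurement is therefore not the
average bilayer thickness but the thickness of the small membrane patch
lining the protein:

1. select the phosphate headgroup beads (Martini `PO4` or atomistic `P`)
   within a cutoff (default 6 Å) of any protein bead, **re-evaluated every
   frame** since lipids exchange;
2. histogram their positions along the membrane normal (z) into a number
   density profile, in beads·Å⁻³;
3. fit a sum of Gaussians A·exp(−(z−μ)²/2σ²) — **two** components for a
   protein-free bulk reference membrane, **three** for the TM window,
   where the central component absorbs headgroups drawn deep into the
   thinned zone;
4. read the thickness as the separation of the two *outermost* component
   means, and aggregate replicate simulations as mean ± SEM.

Derived quantities follow: relative thinning (bulk−window)/bulk·100 %, and
differences between window thicknesses of protein variants with SEMs
combined in quadrature. Hydrophobic matching is quantified by the
canonical helix span n·1.5 Å. Cleavage efficiency is computed from band
intensities as cleaved·100/(cleaved+full-length) and profiles are compared
point-by-point with two-tailed Student or Welch t tests
(n.s. > 0.05 ≥ * ≥ ** ≥ *** ≥ ****).

Because μs-scale cluster simulations cannot be rerun at desk scale, the
package ships first-class **synthetic generators with planted ground
truth**: a two-leaflet bilayer whose thickness follows a radial funnel
T(ρ) = T_win + (T_bulk−T_win)(1−exp(−max(0,ρ−r_p)²/2w²)) around an embedded
protein cylinder, optional ER-like 10-species lipid composition, Gaussian
vertical noise, water slabs, ideal helices, and lognormal-noise band
tables. Every analysis stage is validated by parameter recovery against
this planted truth.

## Worked example

```python
from memthick import (BilayerSpec, generate_bilayer, thickness_pipeline,
                      relative_thinning)

# five replicate "simulations" with a planted 20.1 Å window in a 38.1 Å bilayer
window = [generate_bilayer(BilayerSpec(
    bulk_thickness=38.1, window_thickness=20.1, protein_radius=10.0,
    window_radius=16.0, seed=s))[0] for s in range(5)]
bulk = [generate_bilayer(BilayerSpec(seed=s + 100))[0] for s in range(5)]

w = thickness_pipeline(window, region="tm_window")   # triple-Gaussian fit
b = thickness_pipeline(bulk, region="bulk")          # double-Gaussian fit
print(f"window: {w.mean:.2f} +/- {w.sem:.2f} A")
print(f"bulk:   {b.mean:.2f} +/- {b.sem:.2f} A")
print(f"thinning: {relative_thinning(b.mean, w.mean):.1f} %")
```

prints (seeds as above):

```
window: 20.22 +/- 0.10 A
bulk:   38.08 +/- 0.01 A
thinning: 46.9 %
```

i.e. the pipeline recovers the planted 20.1/38.1 Å geometry within a few
hundredths of an Å and reports the ~47 % local thinning that a 14-residue
TM helix (span 14 × 1.5 = 21 Å) would hydrophobically match.

The same analyses are available from a CLI:

```bash
memthick simulate --window-thickness 20.1 --protein-radius 10 --out rep1.gro
memthick thickness rep1.gro --region tm_window --out thick.tsv
memthick validate --seed 1 --out out/        # three-system recovery study
```

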