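# neurofrac

Box-counting fractal analysis of 2D neuronal images.

Quantitative neuromorphology often needs a single number that captures how
complex a neuron's dendritic arbor is. The box dimension delivers that: cover
a binary drawing of the cell with a square grid of cell side *r* pixels,
count the cells *N*(*r*) that contain any ink, and repeat over a range of
sizes. The counts follow a power law

    N(r) = const · r^(−D_B)

and the box dimension *D_B* is the magnitude of the slope of the ordinary
least-squares line through (log₁₀ *r*, log₁₀ *N*). A filled region gives
*D_B* = 2, a smooth curve gives 1, and dendritic arbors land in between:
higher values mean denser plane coverage, more irregular borders, or more
elaborate branching, depending on how the image is presented.

`neurofrac` implements the full protocol used to compare neuron cohorts this
way, for anatomists and image analysts working from digitised drawings:

- **Three representations** of each drawing, each probing one property:
  the **binary** image (space filling), its one-pixel **outline** (shape
  irregularity), and its Zhang–Suen **skeleton** (branching complexity).
- **Two box-size schedules**: the *standard* mixed list used by common
  box-counting tools ({2, 3, 4, 6, 8, 12, 16, 32, 64}) and the *modified*
  geometric schedule 2⁰, 2¹, …, 2^k, terminated when one box covers the
  whole pattern — which keeps log-log points evenly spaced and makes exactly
  self-similar patterns fit with *R*² = 1.
- **Rotation averaging** for asymmetric cells: the apparent *D_B* drifts with
  orientation relative to the grid, so the *precise* value is the mean of the
  apparent values at 45°, 135°, 225° and 315°, rotating about the midpoint of
  the dendritic-field diameter (the most distant pair of foreground pixels).
- **Resolution sweeps** verifying that *D_B* is insensitive to digitisation
  scale (the fitted slope of *D_B* versus dpi is ~10⁻⁴ per dpi or below).
- **Small-sample statistics** for cohort comparison: skewness *a₃* and excess
  *e* with their standard errors σ₃, σ₄ as a normality screen, then paired or
  pooled two-sample Student *t* tests reported against the tabulated critical
  values at α = 0.05, 0.01, 0.001.
- **Synthetic fixtures** with known dimension (filled squares, digital lines,
  the Sierpinski sieve, disks) and seeded random branching trees that emulate
  sparsely branching neurons, so every stage is testable without proprietary
  image data.

## Worked example

```python
import neurofrac as nf

# a seeded random branching tree standing in for a neuron drawing
tree = nf.make_random_neuron(nf.TreeParams(seed=7))

res = nf.BoxCountModel(tree, representation="skeleton", schedule="modified").fit()
print(res.summary())
```

```
Box dimension fit
=================
representation : skeleton
schedule       : modified (10 sizes)
D_B            : 1.329
R              : 0.9963
R^2            : 0.9926
slope stderr   : 0.04063
log10 const    : 3.7227
curve          : (1,3349), (2,1923), (4,961), (8,427), (16,175), (32,66), (64,23), (128,8), (256,3), (512,1)
```

The skeleton of this tree has a box dimension of 1.329: its branching
pattern fills the plane distinctly more than a smooth curve (1.0) and far
less than a solid region (2.0), with a near-perfect log-log fit (*R* =
0.996) across ten doublings of box size.

Because the tree is asymmetric, the orientation-independent value comes from
the rotation protocol:

```python
print(nf.rotation_averaged_db(tree, method="modified", rep="binary").summary())
```

```
Rotation-averaged box dimension
===============================
    45.0 deg : D_B = 1.314
   135.0 deg : D_B = 1.313
   225.0 deg : D_B = 1.336
   315.0 deg : D_B = 1.314
  precise D_B (mean of 4) = 1.319
```

Cohorts are compared with the statistics layer. Two groups of trees with
sparse (branch probability 0.2, n = 9) versus dense (0.6, n = 15) branching:

```python
sparse = [nf.box_dimension(t).D_B
          for t in nf.make_group(3, 9, nf.TreeParams(branch_prob=0.2, canvas_px=256))]
dense = [nf.box_dimension(t).D_B
         for t in nf.make_group(3, 15, nf.TreeParams(branch_prob=0.6, canvas_px=256))]
print(nf.two_sample_t(sparse, dense).summary())
```

```
two_sample t test
  t_c = -19.268, df = 22
  critical values: t_0.05 = 2.074, t_0.01 = 2.819, t_0.001 = 3.792
  p < 0.001
```

The pooled *t* of −19.3 on 22 degrees of freedom far exceeds the α = 0.001
critical value: the denser cohort has a significantly higher binary box
dimension.

## Command line

```bash
neurofrac fixtures fixtures/            # materialise synthetic fixture PNGs
neurofrac analyze fixtures/*.png --rep binary --rep skeleton \
    --method modified --out results.csv
neurofrac rotate fixtures/tree_000.png --out rotation.csv
neurofrac resolution fixtures/tree_000.png --dpi 100:1100:100 --out sweep.csv
neurofrac compare --group-a cohortA/ --group-b cohortB/ \
    --design two-sample --out stats.csv
```

Each `analyze` run writes a `.config.json` echo of the schedule, grid
anchoring and statistical conventions next to its results.

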