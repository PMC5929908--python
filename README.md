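# limblineage

Quantitative cell-lineage analysis for developing arthropod limbs tracked
in light-sheet microscopy.

Crustacean limbs arise from a small grid of ectodermal *founder cells*
(identified by parasegment, row letter and column number, e.g. `E4c5`)
whose descendants are tracked nucleus-by-nucleus over days of
development.  Given such tracking annotations — MaMuT/TrackMate XML
exports or flat CSV track tables — this package answers the questions a
lineage study asks of them: how long are the cell cycles and where are
the fast cells, how similar are the division programs of two founders or
of homologous founders in two limbs, how do replicate limbs growing at
different tempos register onto one another, and how are mitotic divisions
oriented relative to the compartment boundary.  It is aimed at
developmental biologists and image analysts working downstream of
lineaging tools.

## The lineage distance

Each founder's tree is reduced to the multiset *L* of its division times
(hours, relative to a common anchor, truncated at a cut time).  Two trees
*Lx*, *Ly* are compared through

- δn(Lx, Ly) = |Card(Lx) − Card(Ly)| — difference in division counts,
- δt(Lx, Ly) = min over one-to-one pairings P covering the smaller set of
  (1/|P|) Σ |tix − tjy| — the optimally paired mean absolute
  division-time difference, solved exactly by rectangular linear
  assignment,

normalized by the maxima nt, nn over the batch of comparisons and
combined into

    Δ(Lx, Ly) = sqrt( (δt/nt)² + (δn/nn)² )

(an arithmetic-mean combination is also provided as an alternative
reading of the normalization).  Δ matrices feed Ward hierarchical
clustering of founders, homologous-vs-non-homologous comparisons across
limbs (two-sample Kolmogorov–Smirnov), and union-average trees pooling a
founder's divisions from two registered limbs.  Replicate limbs are
registered in time by a linear scale factor fitted to their cell-count
growth curves; division orientations are measured in 3D against a
reference axis and summarized in 15° rose-diagram bins.

Lineage reconstructions of this kind derive from multi-terabyte
recordings whose tracking annotations are rarely available in
machine-readable form, so the package includes a first-class synthetic
generator (`limblineage.simulate`) of grid-organized limb lineages —
three proliferation classes, staged division-orientation program,
frame-snapped tracking emulation, replicate limbs at a programmed tempo
factor — with full ground truth.  See `docs/methods.md` for the models,
parameter defaults and their rationale, and known limitations.

## Worked example

Simulate a 34-founder limb plus a 1.6×-faster replicate, then run the
analysis end to end (the `limblineage` console script wraps the library):

```sh
limblineage simulate --seed 1 --founders 34 --t-end 50 \
    --replicate-scale 1.6 --out-dir demo
# limb1: 18638 detections, 568 divisions
# limb2: 12185 detections, 568 divisions

limblineage distances demo/limb1.xml --t-cut 50 --out demo/d.csv
# wrote demo/d.csv (34x34; nt=3.133, nn=24)

limblineage cluster demo/d.csv -k 3 \
    --out-newick demo/t.nwk --out-labels demo/cl.csv
# wrote demo/t.nwk and demo/cl.csv (k=3)

limblineage growth demo/limb1.xml --out demo/g1.csv   # final count 602
limblineage growth demo/limb2.xml --out demo/g2.csv
limblineage register demo/g1.csv demo/g2.csv --out demo/fit.json
# temporal scale 1.542 (residual 40.5); wrote demo/fit.json

limblineage compare-limbs demo/limb1.xml demo/limb2.xml \
    --t-cut 35 --scale 1.6 --out demo/cmp.json --out-matrix demo/x.csv
# homolog median 18.0% vs non-homolog 53.8% (KS p=1.91e-20); wrote demo/cmp.json
```

What the numbers mean: the 34×34 matrix holds pairwise lineage distances
Δ with batch maxima nt = 3.13 h (timing) and nn = 24 divisions (counts).
Cutting the Ward dendrogram at k = 3 splits the founders 10/11/13 —
exactly the fast central, mixed lateral and slow ventral classes the
generator programmed.  The fitted temporal scale 1.54 recovers the
programmed 1.6 tempo factor within the jitter-limited accuracy (±0.1).
Homologous founder pairs across the two limbs sit at a median distance of
18 % of the batch maximum versus 54 % for non-homologous pairs, and the
KS test rejects equality of the two distributions — homologous cells
divide similarly, but not identically, across limbs.

Other subcommands: `validate`, `convert` (XML↔CSV), `ccl`,
`birth-times`, `angles` (rose-diagram tables per stage window), `clone`
(digital clones).  Every library feature is importable directly:

```python
import limblineage as ll
forest = ll.read_mamut_xml("demo/limb1.xml")
sets = [ll.build_division_time_set(forest, r.id, t_cut_hours=50.0)
        for r in forest.roots()]
matrix, norms = ll.distance_matrix(sets)
```

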