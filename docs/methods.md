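# Methods

`gangliomics` models the computational chain of a comparative ganglioside
(GG) profiling study: enumerate the molecular-species space of the
ganglio-series, annotate observed ions by exact mass, turn SRM peak areas
into per-class molecular-species proportions, quantify classes from HPTLC
standard curves, and compare tissues with compositional statistics. This
note records the models, the parameters that matter, and the choices made
where the design was genuinely open.

## Structural model and masses

A ganglioside is a ceramide — a dihydroxy long-chain base (LCB, `dC:D`)
amide-linked to a fatty acyl (FA, `C:D`) — carrying a glycan head group.
Compositions are assembled from residue formulas (Hex C6H10O5, HexNAc
C8H13NO5, NeuAc C11H17NO8, O-acetyl C2H2O, each already dehydrated for the
glycosidic bond); the ceramide contributes `C_T H_{2T+1-2D} N O3` for total
carbons T and double bonds D, independent of the LCB/FA split. Masses are
monoisotopic, from IUPAC atomic masses hard-coded to >= 9 decimals in
`chem.py`; charge arithmetic uses the proton mass (1.00727646688 Da), not
the H-atom mass, so `[M-xH]x-` m/z is `(M - x*m_p)/x`. The diagnostic
sialic-acid fragment anion (dehydrated, deprotonated NeuAc) computes to
m/z 290.088 — the nominal-290 reporter of negative-mode precursor-ion
scanning.

Deprotonation charge is capped at the NeuAc count: each sialic carboxyl is
one acidic site, so GM classes are singly charged and GQ classes reach 4-.
Positive-mode protonation and sodiation (`[M+xNa]x+`, cation mass corrected
for the electron) are both available because high-resolution full scans may
use either; neither is asserted as the instrument's actual adduct.

The Svennerholm parser covers the 0/a/b/c ganglio-series grid through the
quadrisialylated row, LacCer and the asialo precursors, gala-series GM4 and
a case-sensitive `Ac` prefix for one O-acetyl group (position not modelled;
the classes are distinguished compositionally only). Series membership is
the number of sialic acids on the inner galactose; `GM1b`/`GD1c` resolve to
the 0-series because their sialic acids sit on the terminal galactose.
Digit-1 names other than GM1 require an explicit series letter. The
biosynthesis graph has the four series columns rooted at LacCer, GM3, GD3
and GT3, edge labels naming the transferases; GM4 hangs off a GalCer
precursor node because the gala-series does not pass through
lactosylceramide. O-acetylated variants attach to their parents behind an
opt-in flag so the core graph stays the canonical grid.

The default LCB registry is {d16:1, d17:0, d17:1, d18:1, d18:2, d20:1} —
the bases observed in the tissues modelled here; d18:0 and d20:0 are
excluded by default because they were specifically not detected, and the
registry is user-extendable. The ceramide panel spans 32–44 carbons with
1–3 double bonds (19 species).

## Annotation and detection gates

Exact-mass matching ranks candidates by absolute ppm error (default
tolerance 5 ppm for high-resolution data, configurable; the QqQ SRM channel
identity uses 0.3 Da absolute); ties break toward fewer ceramide double
bonds, then simpler glycans. Ceramide decomposition follows the
identify-the-base, deduce-the-acid logic: for each registry LCB the FA is
the C/D difference, kept when it falls in the 14–26 C / 0–2 DB window. The
"major" structure is the sphingosine (d18:1) combination, reflecting its
dominance among mammalian sphingolipids.

S/N gates: detected above 3, quantifiable at or above 10. The boundary
semantics (S/N = 3 -> non-detected, S/N = 10 -> quantified) take the
conservative side for detection and the inclusive side for quantification;
the source thresholds are stated as strict inequalities and leave the
boundaries open.

## Proportion quantification

Within each (tissue, subject, injection, class), the proportion of a
species is its peak area over the summed areas of all **detected** species
of that class — every class closed independently. The detected (S/N > 3)
denominator follows the stated formula for this analysis ("all detected
peak areas"); a quantified-only (S/N >= 10) denominator is available via
`denominator="quantified"`. Display outputs still mark species between the
gates as `<LOQ` and undetected ones as `N.D.`.

Aggregation is sequential — arithmetic mean over the three injections,
then over subjects — never pooled, which matters on unbalanced designs
(the test suite asserts the two differ where they should). Species under
1% of a class mean are pooled into `others` for the colorscale display,
preserving closure exactly.

HPTLC curves are ordinary least squares with free intercept (the simplest
defensible model for "a standard curve"; r² is surfaced for audit).
Densities are assumed background-corrected. Band densities convert to
sialic-acid nmol by inverse prediction, then to ganglioside nmol by
dividing by the class's sialic-residue count, then normalise per mg
protein (tissues) or per mL (plasma). Out-of-range densities carry an
extrapolation flag rather than an error.

## Compositional statistics

Seven derived variables summarise each per-class composition: 36:1+38:1,
34:1, 40:1+42:2+42:1, 1-unsaturated, 2-unsaturated, <=34 C, >=42 C.
Amalgamation is plain summation on the real compositional scale (zeros kept
as zeros) — the high frequency of below-detection zeros rules out
log-ratio amalgamation.

Each variable v is treated as the two-part composition (v, 1-v) and mapped
to its first clr coordinate, `log(v/(1-v))/2` — the only reading of "clr of
each variable" consistent with a univariate ANOVA response. Boundary values
go through multiplicative simple replacement with delta = half the smallest
nonzero part observed for that variable across the dataset, capped at 0.01
so that degenerate all-or-nothing variables are perturbed, not destroyed;
replacements are flagged.

The ANOVA is additive fixed-effects (tissue + subject, no interaction),
with Type II sums of squares computed by model comparison — the natural
choice for an unbalanced additive design (n = 7/7/7/6/4/4); subjects align
by donor id across tissues and missing cells are tolerated. A
rank-deficient design raises an explicit error. Type II equals sequential
SS on balanced data and matches `statsmodels.anova_lm(typ=2)` (asserted in
the tests).

Newman-Keuls runs on the tissue means of the clr response: means sorted
descending, each stretch of r ordered means tested against the studentized
range critical value for r means at the residual df, the harmonic mean of
the pair's group sizes standing in for unequal n, and stepwise protection
(pairs inside a non-significant stretch are not tested). Because of the
protection rule, non-significance is interval-structured, so the compact
letters are exactly the maximal non-significant stretches, with "a" on the
stretch containing the highest mean. Critical values are cached — the
studentized-range quantile is numerically expensive.

Ternary coordinates close three-part amalgamations to 1 and map (a, b, c)
to x = b + c/2, y = (sqrt3/2)c; vertex order is (variable 1, variable 2,
remainder), declared in each output record. Confidence ellipses are for the
**group mean**: compositions go to 2-D isometric log-ratio coordinates
(same zero replacement), and the mean's chi-square(2) region with
covariance/n scaling is traced and back-transformed point-wise. The
chi-square (rather than Hotelling-T²) scaling slightly under-covers at very
small n; at the simulation sizes used for validation (hundreds of draws)
the difference is negligible. Whether the original figures show mean or
data ellipses is unknowable from the text; the mean-region choice is
flagged here.

## Synthetic data generator

The generator emulates the measurement design: six tissues with 7/7/7/6/4/4
subjects, three injections, 14 SRM classes, the 19-species panel. Subject
compositions are Dirichlet draws around tissue/class mean profiles
(precision 200 by default, giving between-subject SDs of a few percentage
points); injection areas get multiplicative lognormal noise (sigma 0.15 —
between-injection CVs are not reported anywhere, so this is a documented
guess surfaced in `GeneratorConfig`); the per-injection class total is
lognormal around 1e6 area units (sigma 0.3); S/N is area over a lognormal
noise floor (300 area units, sigma 0.3), so species around 0.3% fall below
the quantification gate and species below ~0.1% below detection —
reproducing the heavy-zeros structure the statistics must survive.

The built-in profiles encode the qualitative tissue pattern, not measured
numbers: nervous tissues dominated by 36:1/38:1 (~60% in the hematosides
GM3/GD3/AcGD3, >= 85% in tetraosyl classes), plasma and ciliary body rich
in 34:1, optic nerve carrying 43:1/44:2, GT3/AcGT3 only in retina and brain
with the retinal forms shifted toward 40:1/42:2/42:1 (~54%, ~19%
2-unsaturated, ~31% >= 42 C), and ceramide 42:3 absent from retina and
brain. Profiles live in one editable structure so measured values can be
substituted.

What passing tests show — and do not. The generator draws independent
Dirichlet compositions per class and lognormal noise per transition; real
data add correlated ionisation drift, retention-time interference between
co-eluting isobars, and batch effects, none of which are modelled. Recovery
tests therefore validate the pipeline's arithmetic and its behaviour under
dropout, not instrument robustness. Recovery is assessed against the
realised subject compositions the generator actually drew: against the
profile means the group-mean error is dominated by irreducible
between-subject sampling noise (SE up to ~0.017 at n = 4), which no
pipeline can remove.

## Problem sizes used in validation

The replicate counts in the test suite and acceptance script (200 seeded
replicates for the tissue-separation and ellipse-coverage checks, 200 for
ANOVA power, 150 random species for mass additivity, 1000 samples for
closure) are the package's chosen simulation sizes; they give Monte-Carlo
standard errors comfortably below the margins being asserted.

## Known limitations

- Glycan linkage/anomericity, isotope patterns and retention prediction are
  out of scope; inputs are peak-reduced tables.
- Absolute cross-class MS quantification is deliberately unsupported — the
  LC/MS intensities are not comparable across classes.
- Subject is a fixed factor, as in the original analysis; a mixed-effects
  treatment would change the residual structure.
- O-acetyl position and count beyond one are not modelled without
  configuration.
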