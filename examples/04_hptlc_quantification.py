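"""HPTLC standard-curve quantification of ganglioside-bound sialic acid.

Simulates a plate (per-class calibration lanes of known sialic-acid nmol,
plus tissue bands from known ganglioside loadings), fits per-class linear
standard curves, and recovers the loadings: band density -> sialic nmol by
inverse prediction -> ganglioside nmol by dividing by the class's
sialic-residue count -> normalised per mg protein.
"""

from gangliomics.quantify import fit_standard_curve, quantify_tissue
from gangliomics.simulate import generate_calibration_plate

cal, bands, truth = generate_calibration_plate(
    seed=2, loadings_gg_nmol={"GM1": 3.0, "GD3": 2.0, "GT1b": 1.0},
    protein_mg=2.0, density_sigma=0.05)

curves = {c: fit_standard_curve(c, sub["nmol"].tolist(), sub["density"].tolist())
          for c, sub in cal.groupby("gclass")}
for c, curve in sorted(curves.items()):
    print(f"{c:5s} curve: slope={curve.slope:.3f}, r2={curve.r_squared:.4f}")

print()
for q in quantify_tissue(bands, curves, normalizer=truth["protein_mg"]):
    true = truth["loadings_gg_nmol"][q.gclass]
    print(f"{q.gclass:5s} sialic {q.sialic_nmol:5.2f} nmol -> "
          f"{q.gg_nmol:4.2f} nmol GG (true {true:.2f}) -> "
          f"{q.value:.2f} {q.unit}")
# GD3 carries two sialic residues, so its band reads twice the ganglioside
# amount in sialic equivalents; GM1 reads one-to-one.
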