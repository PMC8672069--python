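# heterodont

Quantifying size–shape differentiation (**heterodonty**) along the toothrow
of Palaeozoic synapsids, for palaeobiologists working on the origin of the
mammalian-style regionalized dentition.

Heterodonty — the differentiation of a toothrow into incisor-, canine- and
postcanine-like regions — is a hallmark of synapsid evolution. This package
implements the full quantitative chain used to measure it from 2-D crown
outlines:

1. **Semi-landmark morphometrics.** Each crown outline (mesial base → apex
   → distal base) is reduced to 2 fixed landmarks at the crown base plus 28
   semi-landmarks at equal arc-length fractions; configurations are
   superimposed by generalized Procrustes analysis (translation, unit
   centroid-size scaling, rotation-only fitting, optional tangent sliding
   of semi-landmarks).
2. **Shape-space PCA and the heterodonty index.** A joint PCA of the
   aligned coordinates yields PC1 ≈ crown aspect ratio (short/stout
   positive, tall/slender negative) and PC2 ≈ curvature distribution. The
   heterodonty index of a specimen is the sample variance (n − 1
   denominator) of its teeth's PC1 scores: a homodont row scores 0.
3. **Body-mass scaling.** `mass = a · FL^b` fitted by least squares on
   log10 axes to a femur-length/mass reference table, then stage-binned,
   diet-partitioned mean mass and mean heterodonty time series.
4. **Maximum parsimony.** A compact engine for the accompanying
   morphological matrices: NEXUS input, Fitch (unordered) tree length,
   exact branch-and-bound and heuristic (random addition + SPR) search,
   ensemble consistency index CI = ΣM/S and retention index
   RI = (ΣG − S)/(ΣG − ΣM), and strict consensus trees.

Because no per-tooth landmark data are publicly deposited for the fossil
specimens this kind of analysis samples, the package includes a
first-class synthetic generator: parametric crown
outlines (height, base width, recurvature, apex sharpness), *homodont* and
*caniniform* toothrow profiles (three anterior teeth consecutively
increasing, a short diastema, an enlarged caniniform at least twice the
median postcanine height), whole labelled assemblages, and discrete
character matrices evolved on known trees — all pure functions of a seed,
so every downstream stage is testable against ground truth.

## Worked example

```python
import heterodont as hd

asm = hd.simulate_assemblage(40, mix=0.5, seed=7)      # 20 caniniform + 20 homodont
configs = [hd.resample_to_configuration(o) for o in asm.all_outlines()]
aligned = hd.gpa(configs)                              # generalized Procrustes
space = hd.fit_pca(aligned)                            # joint shape-space PCA
het = hd.heterodonty_table(space)                      # PC1 variance per specimen

profiles = {s.metadata.specimen_id: s.profile.profile_name for s in asm.specimens}
can = het[het.specimen_id.map(profiles) == "caniniform"].pc1_variance
hom = het[het.specimen_id.map(profiles) == "homodont"].pc1_variance
ratio = space.pca.explained_variance_ratio_

print(f"teeth aligned:        {aligned.n}")
print(f"PC1 variance:         {100 * ratio[0]:.1f}%")
print(f"PC1+PC2 variance:     {100 * ratio[:2].sum():.1f}%")
print(f"caniniform heterodonty (median PC1 variance): {can.median():.4f}")
print(f"homodont heterodonty  (median PC1 variance): {hom.median():.4f}")

model = hd.fit_power_law(hd.make_reference_masses(n=200, log10_sd=0.1, seed=11))
print(f"mass = {model.coef_a_:.3g} * FL^{model.coef_b_:.3f}  (r2={model.r2_:.3f})")
```

prints:

```
teeth aligned:        480
PC1 variance:         98.2%
PC1+PC2 variance:     99.1%
caniniform heterodonty (median PC1 variance): 0.0404
homodont heterodonty  (median PC1 variance): 0.0001
mass = 1.1e-05 * FL^2.983  (r2=0.992)
```

PC1 absorbs almost all variation here because the synthetic world varies
crowns along a single tall↔stout axis; the caniniform/homodont contrast in
the index (0.0404 vs 0.0001) is the regionalization signal the index is
designed to capture, and the fitted exponent recovers the generating cube
law (b = 3) from noisy data.

The same chain is scriptable from a shell:

```bash
hetero simulate --n 40 --mix 0.5 --seed 7 --out run/inputs
hetero resample run/inputs/outlines.tps --semis 28 --out run/configs.json
hetero gpa run/configs.json --out run/aligned.csv
hetero pca run/aligned.csv --out run/space
hetero index run/space/scores.csv --out run/heterodonty.csv
hetero pars matrix.nex --mode bb --out run/pars
hetero run --simulate-n 40 --seed 7 --out run/full   # everything at once
```

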