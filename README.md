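# capsidarch

Predicting the capsid architecture (icosahedral T-number) of tailed
bacteriophages from genomic information.

Tailed phages protect their double-stranded DNA genome in icosahedral
protein shells whose surface lattice is indexed by the triangulation
number. On the classic hexagonal lattice T₀(h,k) = h² + hk + k², with
60·T₀ copies of the major capsid protein (MCP); the trihexagonal lattice
additionally carries 60·T₀ minor capsid proteins as trimers, giving an
effective T = (4/3)·T₀ (1.33, 5.33, 9.33, …). Because the packaged genome
fills the shell at near-constant density while each capsid protein covers a
near-constant patch of surface, T scales allometrically with genome length
G:

    ln T = a · ln(G / G₀) + ln b,   G₀ = 1 kbp

with a theoretical exponent a = 2/3 (surface ∝ R², volume ∝ R³). Fitted to
a packaged table of 37 phages with solved capsid structures, the model
predicts T from genome length with a held-out mean relative error (MRE)
near 9%, which sets the assignment margin ΔT = T·MRE. A predicted T inside
the margin of a valid lattice T-number is assigned that architecture; a
prediction matching no icosahedral T is called "elongated".

On top of this genome-to-T (G2T) core, the package provides:

- **`lattice`** — enumeration of hexagonal/trihexagonal architectures with
  exact rational T-values and protein stoichiometry;
- **`g2t`** — the allometric model (statsmodels-style
  `GenomeToTModel.fit()` → `GenomeToTResults`), alternative-model quality
  control, the MRE-vs-training-size curve and its exponential-decay fit
  `MRE(n) = p·e^(−qn) + w`, architecture assignment, and the inverse
  T → genome-range map;
- **`density`** — multi-region Gaussian KDE of genome-length distributions
  with cross-validated per-region bandwidths, peak finding, and
  architecture frequency tallies;
- **`library`** — MCP/T library construction from annotated genomes
  (keyword extraction, function-score filtering, dereplication, structural
  vs model labels);
- **`pm`** — nearest-neighbour T prediction from pairwise sequence
  similarity (blastp tabular input or a built-in BLOSUM62 local aligner),
  evaluated over repeated 80/20 splits across similarity thresholds;
- **`rf`** — a random-forest classifier over 22 sequence features (length,
  isoelectric point, amino-acid composition) with merged T classes, a
  jumbo (T ≥ 25) class, accuracy-scaling fit `ACC(n) = g·log₁₀n + h`, and
  permutation/dropout/clade feature diagnostics;
- **`simulate`** — seeded generators for power-law capsid records, genome
  mixtures, and synthetic MCP classes/families, plus the packaged
  high-resolution table;
- **`survey`** / **`cli`** — a metagenome survey front end and the
  `capsid-arch` command-line interface.

## Worked example

```python
import capsidarch as ca

records = ca.load_highres_fixture()      # 37 solved capsid structures
fit = ca.fit_g2t(records)
print(fit.summary())

mre = ca.mre_curve(records, [30], reps=10_000, seed=1)["mre"].item()
print(f"MRE (30-train/7-test, 10,000 splits): {mre:.3f}")

asg = fit.assign(39.7, 0.09)             # phage HK97's genome length
print(asg.label, round(asg.t_predicted, 2))
print(fit.genome_range(7, 0.09))         # genomes compatible with T = 7
```

prints

```
Genome-to-T allometric model (OLS on ln T vs ln G/G0, G0 = 1 kbp)
==================================================================
n records                  37
exponent a             0.7127  +/- 0.0203 (SE)
prefactor b            0.4878  (ln b = -0.7179)
R^2 (ln-ln space)      0.9724
MRE (30-train/7-test, 10,000 splits): 0.089
T=7 6.72
(37.2, 47.9)
```

The fitted exponent 0.71 sits just above the theoretical 2/3, the model
explains ~97% of the ln-space variance, and the held-out error is ~9%.
HK97's 39.7 kbp genome is predicted at T ≈ 6.7, whose 9% margin contains
only the valid lattice value T = 7 — matching its solved structure. The
inverse map says T = 7 capsids correspond to genomes of roughly 37–48 kbp.

The same pipeline runs from the shell:

```sh
capsid-arch fit-g2t --fixture --out fit.json
capsid-arch predict-t fit.json --genome 39.7
capsid-arch lattice --t-max 60 --out architectures.tsv
capsid-arch simulate mcps --n 300 --seed 1 --out mcps.tsv
capsid-arch rf-train mcps.tsv --fit fit.json --seed 1 --out model.bin
capsid-arch survey proteins.fasta --scores scores.tsv --model model.bin --out survey.tsv
```

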