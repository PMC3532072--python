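# micontact

Mutual-information coevolution scoring for **protein domain–domain
contact prediction**: a library (plus a thin CLI) for structural
bioinformaticians who want to score, filter and evaluate correlated
mutations between the columns of a paired-domain multiple sequence
alignment (MSA).

## The scores

For alignment columns *J*, *K* with empirical symbol frequencies
*P*(·) and Shannon entropies (natural log) *H*(*J*) = −Σ *p* log *p*:

- **MI** — `MI(J;K) = H(J) + H(K) − H(J;K)`, the plug-in mutual
  information of an inter-domain column pair.
- **MIp** — `MI − APC`, where the average product correction
  `APC(J;K) = M̄I(J)·M̄I(K) / M̄I` subtracts the background (entropic and
  phylogenetic) signal shared by whole columns.
- **MIc** — `MI − NCPS`, where the coevolutionary pattern similarity
  `CPS(J;K) = (1/(n−2)) Σ_L MI(J;L)·MI(K;L)` compares the two columns'
  MI profiles against third columns and is normalised by the square
  root of the mean CPS.
- **MI3D / MIp3D** — the total correlation
  `Σ P(j,k,l) log [P(j,k,l)/(P(j)P(k)P(l))]` of a domain-1 column with a
  *patch* pair of domain-2 columns whose reference residues lie < 4.5 Å
  apart, with a product-of-means correction `APC3D`.
- **…RA** — any of the above on a 7-category physiochemical reduced
  alphabet (Small; Hydrophobic; Negatively charged; Aromatic; Polar;
  favoured positive R/H; disfavoured positive K).

Columns with a gap or zero entropy are excluded, raw scores of exactly
0 are dropped, and every surviving table is z-scored over its own
entries so scores are comparable across alignments.  Around the scores
sit surface/contact residue annotation from a reference structure
(> 7 % relative accessibility ⇒ surface; surface ∧ < 4.5 Å from the
partner domain ∧ accessibility change upon complex formation ⇒
contact), precision–recall and MCC evaluation over percentile cutoffs,
subsampling stability, a binomial top-*k* enrichment test, and a
synthetic-data generator that plants covarying pairs/triples with
consistent structural annotations.

## Worked example

```python
from micontact import SyntheticSpec, build_mask, generate_msa, mi_table, mic_table, mip_table

spec = SyntheticSpec(n_sequences=500, len1=30, len2=30, seed=42,
                     coupled_pairs=((3, 40, 0.9), (10, 45, 0.8), (17, 52, 0.7)))
msa = generate_msa(spec)
table = mic_table(msa, build_mask(msa))
best = max(table.standardized, key=table.standardized.get)
print(best, round(table.standardized[best], 2))
```

Running `python examples/01_score_variants.py` (this exact setup)
prints:

```
alignment: 500 sequences x 60 columns, 60 eligible columns
planted pairs (domain1 col, domain2 col, coupling): ((3, 40, 0.9), (10, 45, 0.8), (17, 52, 0.7))

MI: 900 surviving pairs; top 3:
  columns ( 3,40)  raw +2.6035  z +20.41
  columns (10,45)  raw +2.1421  z +16.08
  columns (17,52)  raw +1.8203  z +13.05
MIp: 900 surviving pairs; top 3:
  columns ( 3,40)  raw +2.0168  z +19.70
  ...
```

The three planted covarying pairs head all three rankings, in coupling
order; a z-score of +20 means the pair covaries some twenty background
standard deviations more than the alignment's typical inter-domain
pair.  The other scripts in `examples/` walk through structure
annotation, contact evaluation (P-ROC / MCC), subsampling stability,
the binomial case-study test, and the reduced-alphabet / patch-triple
variants.

A CLI mirrors the workflows (`micontact score / evaluate / stability /
casestudy / fixtures`; see `micontact --help`).

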