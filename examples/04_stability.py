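"""Subsampling stability of the precision at 20% recall.

Draws repeated 70% sub-alignments (reference row always retained),
rescores each and recomputes the precision at 20% recall, reporting the
replicate mean and spread.  Stable variants keep their precision — and
their relative ranking — under such perturbations of the alignment.
"""

from micontact import SyntheticSpec, generate_annotations, generate_msa, stability_run
from micontact.structure import label_contacts

spec = SyntheticSpec(
    n_sequences=300, len1=20, len2=20, seed=5,
    coupled_pairs=((2, 25, 0.18), (6, 29, 0.14), (11, 34, 0.10)),
    contact_cols=(2, 6, 11, 25, 29, 34),
)
msa = generate_msa(spec)
anns, dmap, _ = generate_annotations(spec, msa)
anns = label_contacts(anns, dmap)

for variant in ("MI", "MIp", "MIc"):
    res = stability_run(msa, anns, variant, fraction=0.7, n_reps=20, seed=1)
    print(f"{variant:4s} precision at 20% recall over {len(res.precisions)} "
          f"replicates: {res.mean:.3f} (sd {res.sd:.3f}, "
          f"stderr {res.stderr:.3f})")
# A small sd relative to differences between variants means the variant
# ranking would be preserved across resampled alignments.
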