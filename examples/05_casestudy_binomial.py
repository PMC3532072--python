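"""Binomial top-k test: is a ranked contact prediction better than chance?

With 46 candidate residues of which 9 are contacts, a scorer with no
relationship to the contacts hits Binomial(9, 9/46) of its top 9 picks —
1.76 expected.  The upper-tail p-value asks how surprising the observed
hit count is under that null.
"""

from micontact import binomial_topk_test
from micontact.evaluate import ResidueScore


def pool(n_candidates, n_positives, k, hits):
    """Candidate pool whose top-k contains exactly `hits` contacts."""
    out = []
    for rank in range(n_candidates):
        contact = rank < hits or (k <= rank < k + n_positives - hits)
        out.append(ResidueScore(domain=1, resnum=rank + 1, column=rank,
                                score=float(n_candidates - rank),
                                variant="MI", surface=True, contact=contact))
    return out


for hits in (2, 3, 4, 6):
    res = binomial_topk_test(pool(46, 9, 9, hits), k=9)
    verdict = "significant at 5%" if res.p_value < 0.05 else "not significant"
    print(f"hits {res.hits}/9 (expected {res.expected:.2f}): "
          f"p = {res.p_value:.4f}  -> {verdict}")
# 3 or 4 hits out of 9 — the kind of count a seemingly "successful"
# prediction can produce — is entirely compatible with random guessing;
# only 6+ hits would reject the null at the 5% level.
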