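"""Pairwise prediction: a query reaction against a known reference.

The worked pair ships with all intermediates frozen: the 12 perturbation
operators (3 condition deltas + 9 descriptor deltas) and the published
pairwise model's output ee_R(ref) + sum(coef * delta) + intercept.
"""

import ptmlee as p
from ptmlee.ptml import PTO_NAMES

q, r, expected_pto, expected_pred = p.toy_worked_pair()

print(f"query     {q.rxn_id}: ee_R = {q.ee_R:+.1f}%  (T={q.record.T_C}, t={q.record.t_h}, load={q.record.load_pct})")
print(f"reference {r.rxn_id}: ee_R = {r.ee_R:+.1f}%  (T={r.record.T_C}, t={r.record.t_h}, load={r.record.load_pct})")

pto = p.pto_vector(q, r)
print("\nperturbation operators (query minus reference):")
for name in PTO_NAMES:
    print(f"  {name:22s} {getattr(pto, name):+12.6f}")

pred = p.predict_ee_from_reference(q, r)
print(f"\npredicted ee_R = {pred.ee_R:+.2f}%  (raw {pred.raw:+.4f}, clipped: {pred.clipped})")
print(f"predicted product configuration: ({pred.cip})")
print(f"frozen oracle value:             {expected_pred:+.4f}")

# The prediction is the reference's observed ee_R corrected linearly for
# how the query differs in conditions and molecular structure; its sign is
# the predicted CIP label of the new stereocenter.
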