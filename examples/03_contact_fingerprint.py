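"""Typed contact fingerprint and binding-mode features.

Computes per-(fragment, residue, type) contact frequencies over a synthetic
pool, the salt-bridge persistence, and the five general binding-mode
features (GF1-GF5) of the fentanyl pose.
"""

from fentsar.contacts import (
    contact_frequencies,
    evaluate_general_features,
    ionic_persistence,
)
from fentsar.synthetic import SyntheticSpec, generate_pool

sp = generate_pool(SyntheticSpec(seed=7, per_ns=10))
table = contact_frequencies(sp.pool, sp.scheme, sp.role_map)

print("top contacts (mean frequency +/- SEM over 3 replicas):")
top = table.sort_values("mean", ascending=False).head(8)
for _, r in top.iterrows():
    print(f"  {r['fragment']:17s} {r['residue']:5s} {r['type']:5s} "
          f"{r['mean']:.2f} +/- {r['sem']:.3f}")

ion = ionic_persistence(sp.pool, sp.role_map, sp.scheme)
print(f"\nsalt-bridge persistence (N+ ... D147): {ion:.3f} "
      "(fraction of frames; ~0.99 for well-anchored derivatives)")

gfs = evaluate_general_features(table, ion, sp.scheme)
print("\nbinding-mode features:")
for name, g in gfs.items():
    print(f"  {name}: {g.value}")
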