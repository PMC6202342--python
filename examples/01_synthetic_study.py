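"""Generate a synthetic study and inspect its planted network structure.

A study bundles an electrode layout, a baseline recording with planted
5-13 Hz coherence structure, the networks estimated from that baseline,
and stimulation sessions whose evoked power follows a known linear model
of connectivity and distance.
"""

import numpy as np

import stimnet as sn

study = sn.generate_study(n_electrodes=30, n_sites=2, n_trials=60, seed=42)

layout = study.layout
coords = layout.coordinates
d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
off = d[~np.eye(30, dtype=bool)]
print(f"electrodes: {layout.n_electrodes}, min spacing {off.min():.2f} mm "
      f"(contacts are never closer than 3.5 mm)")
print(f"clinically flagged (SOZ/spiking): {int((layout.soz | layout.spiking).sum())}")

coh = study.coherence.values[~np.eye(30, dtype=bool)]
print(f"estimated 5-13 Hz coherence: median {np.median(coh):.3f}, "
      f"max {coh.max():.3f}")
print("pairs sharing a planted narrowband source sit in the upper tail; "
      "unrelated pairs sit at the estimator's bias floor")

strengths = sn.node_strength(study.coherence)
hub = int(np.argmax(strengths))
print(f"strongest hub: {layout.labels[hub]} "
      f"(normalized node strength {strengths[hub]:.3f})")
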