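"""The three differential-coexpression edge rules on hand-picked pairs.

Each rule decides, from a pair's correlation in the normal and disease
conditions, whether the pair becomes an edge of the differential graph.
"""

import numpy as np

from bmkc import CorrelationMatrix, ThresholdConfig, binarize


def pair(r_normal, r_disease):
    ids = ["geneA", "geneB"]
    cn = np.array([[1.0, r_normal], [r_normal, 1.0]])
    cd = np.array([[1.0, r_disease], [r_disease, 1.0]])
    return CorrelationMatrix(cn, ids), CorrelationMatrix(cd, ids)


cases = [
    ("coexpression lost in disease", 0.92, 0.08),
    ("coexpression gained in disease", 0.05, 0.88),
    ("sign reversal", 0.90, -0.70),
    ("unchanged strong coexpression", 0.90, 0.85),
]

configs = {
    "gain   (T1=0.8, T2=0.4)": ThresholdConfig(mode="gain", t1=0.8, t2=0.4),
    "loss   (T1=0.2, T2=0.8)": ThresholdConfig(mode="loss", t1=0.2, t2=0.8),
    "absdiff (T3=1.3)": ThresholdConfig(mode="absdiff", t3=1.3),
}

for label, rn, rd in cases:
    cn, cd = pair(rn, rd)
    verdicts = ", ".join(
        f"{name}: {'edge' if binarize(cn, cd, cfg).values[0, 1] else '-'}"
        for name, cfg in configs.items()
    )
    print(f"{label:35s} rN={rn:+.2f} rD={rd:+.2f} -> {verdicts}")

print()
print("gain flags pairs correlated in normal but not disease; loss the")
print("reverse; absdiff flags large signed changes (including reversals)")
print("whose magnitude does not increase in disease.")
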