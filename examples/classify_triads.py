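"""Classify a handful of triads by hand-picked TPM values.

Each triad's (A, B, D) TPM vector is normalized to unit sum and assigned
the bias category whose centroid is nearest in Euclidean distance.
"""

from triadbias import classify_triad, normalize_triad, ternary_coordinates

triads = {
    "even":        (10.0, 10.0, 10.0),
    "A_high":      (80.0, 10.0, 10.0),
    "A_low":       (1.0, 48.0, 51.0),
    "leans_A":     (60.0, 20.0, 20.0),
    "silent":      (0.1, 0.1, 0.1),
}

print(f"{'triad':10} {'frac_A':>7} {'frac_B':>7} {'frac_D':>7} {'category':>13} {'dist':>7}")
for name, (a, b, d) in triads.items():
    point = normalize_triad(a, b, d, min_total=0.5)
    if point is None:
        print(f"{name:10} {'-':>7} {'-':>7} {'-':>7} {'not_expressed':>13}")
        continue
    category, dist = classify_triad(point)
    x, y = ternary_coordinates(point)
    print(
        f"{name:10} {point.frac_A:7.3f} {point.frac_B:7.3f} {point.frac_D:7.3f} "
        f"{category:>13} {dist:7.4f}"
    )

print(
    "\nDistance is to the winning centroid; 'leans_A' stays balanced because"
    "\n(0.6, 0.2, 0.2) is still closer to (1/3, 1/3, 1/3) than to the A-dominant"
    "\nvertex. 'silent' falls below the 0.5 TPM triad-total floor."
)
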