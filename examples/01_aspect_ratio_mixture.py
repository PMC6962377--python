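"""Sample aspect ratios for a compressed condition and decompose the
distribution into shifted-lognormal components.

The LN229-23Pa preset encodes the condition with the strongest elongation
response: a rounded primary population (peak AR ~1.37) plus an elongated
secondary population (peak AR ~2.63).  The fit below recovers both peaks
from a 2000-cell sample and reports the model-selection statistics.
"""

from mechanomir import (
    ar_histogram,
    fit_ar_pdf,
    flag_relevant_secondary,
    generate_ar_sample,
    percent_elongated,
    select_model,
)

ars = generate_ar_sample("LN229-23Pa", n=2000, seed=42)
hist = ar_histogram(ars, bin_width=0.1)
fit1 = fit_ar_pdf(hist, n_terms=1)
fit2 = fit_ar_pdf(hist, n_terms=2)
selected = select_model(fit1, fit2)

print(f"percent elongated (AR >= 2): {percent_elongated(ars):.1f}%")
print(f"selected model: {selected.n_terms}-term "
      f"(SSE {selected.sse:.4f} vs 1-term {fit1.sse:.4f}; R^2 {selected.r2:.3f})")
for i, comp in enumerate(selected.components, start=1):
    print(f"  component {i}: peak AR {comp.mode:.2f} "
          f"(a={comp.a:.2f}, mu={comp.mu:.3f}, sigma={comp.sigma:.3f})")
print(f"elongated secondary population present: "
      f"{flag_relevant_secondary(selected)}")
# The secondary peak near 2.63 with ~10% of the mass is the compression-
# induced elongated subpopulation; ~39% of single cells exceed AR = 2.
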