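"""Over-representation analysis with category summarization.

Tests a gene list against annotated term sets with the hypergeometric upper
tail, adjusts with Benjamini-Hochberg, and rolls significant terms up into
broad categories via a term-to-category dictionary.
"""

import numpy as np

from imgx import AnnotationSet, ora_test, summarize_categories

rng = np.random.default_rng(0)
universe = [f"G{i:03d}" for i in range(300)]
target = universe[:30]

# terms overlapping the target strongly, weakly, or not at all
annotations = AnnotationSet(
    sets={
        "dev:neurogenesis": set(universe[:20]) | set(universe[100:105]),
        "dev:axon_guidance": set(universe[10:35]),
        "metab:glycolysis": set(universe[150:180]),
        "transport:ion": set(universe[25:45]),
    }
)
result = ora_test(target, annotations, universe, alpha=0.05)
print(result.round(4))

dictionary = {
    "dev:neurogenesis": "development",
    "dev:axon_guidance": "development",
    "metab:glycolysis": "metabolism",
    "transport:ion": "transport",
}
summary = summarize_categories(list(result.index[result["significant"]]), dictionary)
print("\nsignificant terms per category:")
for cat, cnt in summary.counts.items():
    print(f"  {cat}: {cnt} ({100 * summary.proportions[cat]:.0f}%)")
print(
    "\nCategory proportions express which broad biological themes dominate"
    "\nthe significant terms."
)
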