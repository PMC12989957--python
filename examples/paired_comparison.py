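"""Compare two classifiers on paired cases with McNemar's exact test.

Emulates a reader-study comparison: an "AI" and a "pathologist" score the
same 100 cases; the exact McNemar test on the discordant pairs, Bonferroni
adjusted for four comparisons, decides whether the accuracy gap is real.
"""

import numpy as np

import spitzmil as sm

rng = np.random.default_rng(0)
n = 100
ai_correct = rng.random(n) < 0.89
reader_correct = rng.random(n) < 0.77

rec = sm.compare_paired(ai_correct, reader_correct, m=4)
print(f"AI accuracy {ai_correct.mean():.2f}, reader accuracy {reader_correct.mean():.2f}")
print(f"discordant pairs: AI-only correct b={rec.b}, reader-only correct c={rec.c}")
print(f"McNemar exact p={rec.p_raw:.4f}, Bonferroni-adjusted p={rec.p_adjusted:.4f}")
print("chance comparison: p =",
      f"{sm.binomial_vs_chance(int(ai_correct.sum()), n, 0.5):.2e}")
# A small adjusted p indicates the two raters' error patterns genuinely
# differ; the binomial p compares the AI accuracy against random guessing.
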