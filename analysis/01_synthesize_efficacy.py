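"""Evidence synthesis: mixed treatment comparison of the NSAID trials.

Fits the three Bayesian network meta-analyses on the bundled four-trial
evidence table -- BASFI and BASDAI change from baseline (normal likelihood,
identity link) and discontinuation for lack of efficacy (binomial, logit
link) -- and writes the posterior summaries and draws that the
cost-effectiveness model consumes.

Typical posterior means (fixed effect, 4 chains x 20,000 iterations):
etoricoxib 90 mg improves BASFI by ~17.9 points and BASDAI by ~28.6 points
versus an untreated background, with an annual discontinuation probability
of ~0.063 against ~0.15 for the nonselective NSAIDs.
"""

import pathlib
import sys

import numpy as np

from ascea import evidence_synthesis as ev
from ascea import reporting

OUT = pathlib.Path("results/01_mtc")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
ITERATIONS = 20_000

arms = ev.read_trials()
seeds = np.random.SeedSequence(SEED).generate_state(3) % (2**31 - 1)

fits = {
    "basfi_cfb": ev.mtc_continuous(arms, "basfi_cfb",
                                   iterations=ITERATIONS,
                                   seed=int(seeds[0])),
    "basdai_cfb": ev.mtc_continuous(arms, "basdai_cfb",
                                    iterations=ITERATIONS,
                                    seed=int(seeds[1])),
    "discontinuation": ev.mtc_binomial(arms, iterations=ITERATIONS,
                                       seed=int(seeds[2])),
}

for name, post in fits.items():
    summary = ev.posterior_summary(post)
    print(f"\n=== {name} (posterior mean, 95% CrI) ===")
    print(summary.round(3).to_string())
    worst = max(post.diagnostics["rhat"].values())
    print(f"worst split-chain diagnostic: {worst:.3f}")
    reporting.write_table(summary.reset_index(), "frame",
                          OUT / f"summary_{name}.csv")
    post.to_frame().to_csv(OUT / f"draws_{name}.csv", index=False)

reporting.write_manifest(OUT, "01_synthesize_efficacy", SEED, ITERATIONS,
                         {"trials": ev.default_trials_path()})
print(f"\nwritten to {OUT}/")
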