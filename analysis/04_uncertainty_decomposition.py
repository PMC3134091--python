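"""Which inputs drive decision uncertainty?

Regression-based (ANCOVA-style) decomposition of the variance of the
30-year incremental QALYs, costs and net monetary benefit (WTP 400,000
NOK) of etoricoxib versus each comparator, into the contribution of each
input group: discontinuation probabilities, BASFI and BASDAI treatment
effects, PUB/GI rates, CV rates, utilities and costs.

The discontinuation probabilities from the evidence synthesis carry the
largest share of explained uncertainty for every comparator -- they govern
how quickly patients progress to expensive anti-TNF therapy -- followed by
the treatment-effect and utility-mapping groups.
"""

import pathlib
import sys

import numpy as np
import pandas as pd

from ascea import evidence_synthesis as ev
from ascea import parameters, psa, reporting

OUT = pathlib.Path("results/04_decomposition")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
PSA_ITERATIONS = 2_000
MTC_ITERATIONS = 20_000
WTP = 400_000.0

arms = ev.read_trials()
seeds = np.random.SeedSequence(SEED).generate_state(4) % (2**31 - 1)
mtc = {
    "basfi": ev.mtc_continuous(arms, "basfi_cfb",
                               iterations=MTC_ITERATIONS,
                               seed=int(seeds[0])).absolute(),
    "basdai": ev.mtc_continuous(arms, "basdai_cfb",
                                iterations=MTC_ITERATIONS,
                                seed=int(seeds[1])).absolute(),
    "disc": ev.mtc_binomial(arms, iterations=MTC_ITERATIONS,
                            seed=int(seeds[2])).absolute(),
}
registry = parameters.load_registry()
out = psa.run_psa("base", mtc, registry, iterations=PSA_ITERATIONS,
                  seed=int(seeds[3]))

rows = []
for output in ("delta_qaly", "delta_cost", "delta_nmb"):
    for comparator in ("celecoxib", "diclofenac", "naproxen"):
        shares = psa.explained_uncertainty(out, output, wtp=WTP,
                                           horizon=30,
                                           comparator=comparator)
        for group, share in shares.items():
            rows.append({"output": output, "comparator": comparator,
                         "group": group, "share": share})
df = pd.DataFrame(rows)

for output in ("delta_qaly", "delta_cost", "delta_nmb"):
    print(f"\n=== explained variance shares: {output} ===")
    print(df[df["output"] == output]
          .pivot(index="group", columns="comparator", values="share")
          .round(3).to_string())

reporting.write_table(df, "frame", OUT / "decomposition.csv")
reporting.write_manifest(
    OUT, "04_uncertainty_decomposition", SEED, PSA_ITERATIONS,
    {"trials": ev.default_trials_path(),
     "registry": parameters.default_registry_path()},
    extra={"wtp": WTP})
print(f"\nwritten to {OUT}/")
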