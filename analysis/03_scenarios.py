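"""Scenario analyses around the base case.

Reruns the probabilistic analysis under the nine alternative
configurations: celecoxib 200 mg only; GI events only; CV events only; no
adverse events; 0% and 8% discounting; stable BASFI; start age 20; and
anti-TNF acquisition costs set to zero.

The qualitative conclusion is scenario-robust: etoricoxib stays dominant
(cheaper, more QALYs) at 5 and 30 years in every scenario except the one
that removes anti-TNF costs, where its incremental costs turn positive but
the cost per QALY stays moderate (roughly 11,000-107,000 NOK/QALY); with
celecoxib 200 mg as comparator the 1-year cost per QALY is ~18,000 NOK.
"""

import pathlib
import sys

import numpy as np

from ascea import evidence_synthesis as ev
from ascea import parameters, psa, reporting

OUT = pathlib.Path("results/03_scenarios")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
PSA_ITERATIONS = 2_000
MTC_ITERATIONS = 20_000

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

suite = psa.run_scenario_suite(registry, mtc, iterations=PSA_ITERATIONS,
                               seed=int(seeds[3]))

for name, out in suite.items():
    print(f"\n=== scenario: {name} ===")
    print(out.incremental_table().round(2).to_string(index=False))
    reporting.write_table(out, "incremental",
                          OUT / f"incremental_{name}.csv")

reporting.write_manifest(
    OUT, "03_scenarios", SEED, PSA_ITERATIONS,
    {"trials": ev.default_trials_path(),
     "registry": parameters.default_registry_path()})
print(f"\nwritten to {OUT}/")
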