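"""Run the whole pipeline (simulate -> QC -> fit -> reweight -> report)
through one config object and print the bundled report.

The same run is available from the shell:
    valueshift run config.yaml
"""

import tempfile
from pathlib import Path

from valueshift.mcmc import MCMCConfig
from valueshift.pipeline import RunConfig, report, run_pipeline

outdir = Path(tempfile.mkdtemp(prefix="valueshift_"))
config = RunConfig(
    weights_original="UK-1997",
    weights_updated="UK-2022",
    outdir=str(outdir),
    scenario={"country_style": "UK", "n_respondents": 150},
    mcmc=MCMCConfig(n_chains=2, n_burnin=300, n_total=900, seed=9),
    verbosity=1,
)

result = run_pipeline(config)
print()
print(report(result))
print(f"\nartifacts written to {outdir}:")
for p in sorted(outdir.iterdir()):
    print("  ", p.name)
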