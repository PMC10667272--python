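"""Run the full batch pipeline on a simulated fixture bundle.

`write_fixture_bundle` writes a (sensorgram CSV, sample sheet) pair;
`run_batch` then replays the production path — read, validate, align,
thin, down-select, fit — and writes estimates.csv, a multi-page PDF
report and a run log.  Equivalent shell command:

    titrofit fit --data DATA --samples SHEET --out OUTDIR
"""

import pathlib

from titrofit import SimSpec, write_fixture_bundle
from titrofit.report import run_batch

workdir = pathlib.Path("example_batch")
data, sheet = write_fixture_bundle(
    SimSpec(noise_sd=0.5, seed=42, regenerative=False,
            series_id="demo-surface"), workdir)

outcome = run_batch(data, sheet, workdir / "out")

print(f"exit status: {outcome.exit_status}")
print(f"estimates:   {outcome.estimates_path}")
print(f"report:      {outcome.report_path}")
print()
print(outcome.estimates_path.read_text())
# One CSV row per sheet entry: estimates, standard errors, KD with its
# propagated error, the selected concentrations and a convergence flag.
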