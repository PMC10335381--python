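"""Run the whole pipeline (simulate → proximity → morphometrics → pegs)
behind one configuration, then condense the run into a report.

Equivalent shell usage:
    nvuquant run-all -c config.yaml
    nvuquant report <out_dir>
"""

import tempfile
from pathlib import Path

from nvuquant import PhantomParams, RunConfig, report, run_all

with tempfile.TemporaryDirectory() as tmp:
    cfg = RunConfig(
        out_dir=str(Path(tmp) / "run"),
        phantom=PhantomParams(n_slices=4, pericyte_coverage_frac=0.35, seed=1),
        pairs=[
            ("pericyte", "endothelium"),
            ("endothelium", "pericyte"),
            ("pericyte", "macroglia"),
        ],
        seed=1,
    )
    manifest = run_all(cfg)
    print("stage status:", {k: v["status"] for k, v in manifest["stages"].items()})

    summary = report(cfg.out_dir)
    cov = summary["coverage"]
    print(f"ensheathment: {cov['mean_pct']:.1f} +/- {cov['sd_pct']:.1f} % at "
          f"{cov['coverage_nm']:.0f} nm")
    print("CDF readings (% within d):")
    for row in summary["cdf_readings"]:
        print("  ", row["pair"],
              {k: round(v, 1) for k, v in row.items() if k != "pair"})
    print("accepted pegs:", summary["n_accepted_pegs"],
          "(the plain phantom carries none — insert PegSpecs to add them)")
    print("outputs:", ", ".join(manifest["outputs"]))
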