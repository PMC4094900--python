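"""Goodness-of-fit diagnostics of the fitted joint model.

Individual weighted residuals (IWRES) versus time and a visual
predictive check (500 simulated replicates of the registry design,
5/50/95th percentiles per time bin).  Writes the residual table, the VPC
table and the 5-95% envelope coverage under results/diagnostics/.

Run 01 and 02 first.
"""

import json
from pathlib import Path

import yaml

from gaucher_ert.diagnostics import iwres, plot_iwres, plot_vpc, vpc
from gaucher_ert.population_model import model_from_config
from gaucher_ert.registry_io import apply_analysis_window, read_cohort

SEED = 617
BASE = Path(__file__).resolve().parent.parent / "results"
DATA = BASE / "synthetic_registry"
FIT = BASE / "joint_fit"
OUT = BASE / "diagnostics"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = apply_analysis_window(
        read_cohort(DATA / "observations.csv", DATA / "covariates.csv", DATA / "episodes.csv")
    )
    with open(FIT / "fitted_model.yaml") as fh:
        model = model_from_config(yaml.safe_load(fh))

    res = iwres(model, cohort, seed=SEED)
    plot_iwres(res, OUT / "iwres.png", OUT / "iwres.csv")
    print(
        f"IWRES: n = {len(res)}, mean = {res['iwres'].mean():.3f}, "
        f"SD = {res['iwres'].std():.3f}"
    )

    v = vpc(model, cohort, n_sim=500, seed=SEED)
    plot_vpc(v, OUT / "vpc.png", OUT / "vpc.csv")
    (OUT / "vpc_coverage.json").write_text(json.dumps(v.coverage_90, indent=2))
    print("VPC 5-95% envelope coverage per biomarker:")
    for b, c in v.coverage_90.items():
        print(f"  {b}: {100 * c:.1f}%")


if __name__ == "__main__":
    main()
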