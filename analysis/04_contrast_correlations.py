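"""Contrast correlations and the multiple-regression recipe.

For every life-history trait, correlates independent contrasts of the
log-transformed trait with contrasts of log piS and log piN/piS
(through the origin), then fits the scripted regression path: piS on
range + MSMR, the mass-vs-MSMR collinearity screen, and nested F tests
for adding age at maturity or latitude.
"""

import json
from pathlib import Path

from mitodiv.pipeline import AnalysisConfig, run_analysis
from mitodiv.synthetic_data import WorldConfig, simulate_world

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    world = simulate_world(WorldConfig(seed=1))
    traits = world.traits.copy()
    traits["bmr_ml_o2_h"] = traits["msmr"] * traits["mass_g"]
    result = run_analysis(world.alignments, traits, world.phylogeny,
                          AnalysisConfig())
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    result.correlations.to_csv(out / "correlations.tsv", sep="\t", index=False)
    (out / "regression.json").write_text(
        json.dumps(result.regression_report, indent=2, default=float)
    )
    print(result.correlations.to_string(index=False))
    screen = result.regression_report.get("mass_msmr_screen", {})
    if screen:
        print(f"\nmass-MSMR contrast correlation r = {screen['r']:.2f} "
              f"(VIFs {screen['vif']}) — never entered together")
    for extra, res in result.regression_report.get("nested_tests", {}).items():
        print(f"adding {extra}: nested F p = {res['p']:.3f}")


if __name__ == "__main__":
    main()
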