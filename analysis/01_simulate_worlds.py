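"""Generate the three benchmark survey worlds (one per outcome preset).

Each world mimics a single-state BRFSS-style design at reduced scale --
20 counties with 300 completed interviews each -- with a binary outcome
whose population prevalence sits near chronic obstructive pulmonary
disease (7.6%), binge drinking (17.6%) or arthritis (26.0%).  Writes the
survey, census and covariate tables plus the exact truths under
results/data/<preset>/.
"""

import sys
from pathlib import Path

from saeintervals.synthetic import GeneratorConfig, generate_world

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 20250923
COUNTIES, N_PER = 20, 300


def main() -> None:
    for preset in ("copd", "binge", "arthritis"):
        cfg = GeneratorConfig(n_counties=COUNTIES, n_per_county=N_PER,
                              prevalence_preset=preset, seed=SEED)
        world = generate_world(cfg)
        out = OUT / preset
        out.mkdir(parents=True, exist_ok=True)
        world.survey.to_csv(out / "survey.csv", index=False)
        world.census.to_csv(out / "census.csv", index=False)
        world.covariates.to_csv(out / "covariates.csv", index=False)
        world.truth.to_json(out / "truth.json")
        print(f"{preset:10s} {len(world.survey):5d} respondents, "
              f"sample prevalence {world.survey.outcome.mean():.3f}, "
              f"true state prevalence {world.truth.state_prevalence:.3f}")
    print(f"\nwrote data for 3 outcomes under {OUT}")


if __name__ == "__main__":
    sys.exit(main())
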