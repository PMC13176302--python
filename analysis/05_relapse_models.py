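"""Relapse analyses: prediction from pre-relapse rhythms, and the effect of
relapse on rhythms.

Model 1 (per variable): logistic regression of the binary relapse outcome on
pre-relapse circadian values with cluster-robust inference over repeated
measurements; reports odds ratios per unit.  Model 2 (per variable): linear
mixed model of the circadian value on a post-relapse indicator, adjusted for
discharge, with a participant random intercept.
"""

from pathlib import Path

from circact.pipeline import RunConfig, analyze_cohort, fit_all_models, load_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = load_cohort(RunConfig(output_dir=".", input_dir=str(RESULTS / "cohort")))
    res = analyze_cohort(cohort.series, cohort.diaries, cohort.manifest)
    table = fit_all_models(res, families=("relapse_probability", "relapse_effect"))
    prob = table[table["family"] == "relapse_probability"]
    eff = table[table["family"] == "relapse_effect"]
    prob.to_csv(RESULTS / "table_relapse_probability.csv", index=False)
    eff.to_csv(RESULTS / "table_relapse_effects.csv", index=False)

    print("probability of relapse per unit of each pre-relapse circadian variable:")
    print(prob[["variable", "beta", "odds_ratio", "se", "statistic", "p_value"]]
          .round(4).to_string(index=False))
    print("\neffect of relapse on each circadian variable (discharge-adjusted):")
    print(eff[["variable", "beta", "se", "df", "statistic", "p_value"]]
          .round(4).to_string(index=False))
    print("\nprogrammed truths: post-relapse wake_time +3190 s, IV -0.08."
          "\nNo direct association was programmed for the probability models;"
          "\nan apparent IV effect can still arise by composition: relapsers"
          "\nhave fewer pre-relapse outpatient weeks, so their high-IV"
          "\ninpatient weeks weigh more once discharge lowers IV.")


if __name__ == "__main__":
    main()
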