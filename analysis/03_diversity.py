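"""Per-population diversity of the synthetic transect.

Reports sample size, percent polymorphic loci, unbiased expected
heterozygosity and locally common / private band counts per site, plus the
diversity-vs-sample-size regression (degenerate here by design: sampling is
balanced, so the regression is reported undefined).
"""

from common import RESULTS, study_dataset
from provzone import diversity
from provzone.io import ValidationError


def main() -> None:
    markers, _, _, _ = study_dataset()
    res = diversity.population_diversity(markers)
    table = res.per_population.copy()
    table.loc["Mean"] = res.means
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "diversity.csv")
    print(table.round(3).to_string())
    try:
        fit = diversity.diversity_size_regression(
            res.per_population["n"], res.per_population["plp"])
        print(f"PLP ~ n: R^2={fit['r_squared']:.2f}, p={fit['p_value']:.3f}")
    except ValidationError as exc:
        print(f"PLP ~ n regression undefined: {exc}")


if __name__ == "__main__":
    main()
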