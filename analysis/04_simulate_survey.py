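"""Simulate the household survey for the selected households: one
respondent per household with sociodemographics at the study marginals,
per-scenario preference-item ratings from the five-factor model, and
provider choices from the multinomial-logit process.
"""

from pathlib import Path

import pandas as pd

from carecov.geojson import read_geojson
from carecov.synthetic.survey import gen_respondents

OUT = Path("results/analysis")


def main() -> None:
    households = read_geojson(OUT / "households.geojson")
    selected = pd.read_csv(OUT / "selected_households.csv")
    chosen = set(selected.household_id)
    feats = [f for f in households if f.properties["household_id"] in chosen]

    respondents = gen_respondents(feats, seed=11)
    respondents.to_csv(OUT / "survey.csv", index=False)

    print(f"simulated {len(respondents)} respondents "
          f"({respondents.shape[1]} columns)")
    print("habitual choice shares:",
          respondents.choice_actual.value_counts(normalize=True).round(3).to_dict())
    print(f"survey written to {OUT}/survey.csv")


if __name__ == "__main__":
    main()
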