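"""Choice models of the simulated survey: a binary logistic model of the
habitual provider choice and multinomial models per illness scenario
(reference category: partner providers), for sociodemographic covariates
and for the retained preference-component scores.
"""

from pathlib import Path

import pandas as pd

from carecov.choice_models import fit_multinomial_choice, preference_choice_models, render_table
from carecov.preference_pca import pca_preferences
from carecov.synthetic.survey import PREFERENCE_ITEMS

OUT = Path("results/analysis")

COVARIATES = ["age", "chronic_illness", "income", "education", "pbi", "other_insurance"]
ADJUST = ["gender", "mild_illness", "consultations", "ever_used_benefit"]


def main() -> None:
    df = pd.read_csv(OUT / "survey.csv")

    for sc in ("actual", "mild", "chronic", "serious"):
        try:
            res = fit_multinomial_choice(
                df, f"choice_{sc}", COVARIATES, adjust=ADJUST,
                reference_levels={"income": "low", "education": "primary"},
            )
        except ValueError as exc:
            print(f"{sc}: model not estimable ({exc})")
            continue
        res.table.assign(scenario=sc).to_csv(OUT / f"choice_{sc}.csv", index=False)
        print(render_table(res))
        print()

    print("preference-factor models (component scores per scenario):")
    for sc in ("mild", "chronic", "serious"):
        items = df[[f"pref_{sc}_{it}" for it in PREFERENCE_ITEMS]]
        complete = ~items.isna().any(axis=1)
        res = pca_preferences(items, item_labels=list(PREFERENCE_ITEMS))
        try:
            pres = preference_choice_models(res.scores, df.loc[complete], sc)
        except ValueError as exc:
            print(f"{sc}: model not estimable ({exc})")
            continue
        pres.table.assign(scenario=sc).to_csv(OUT / f"choice_pref_{sc}.csv", index=False)
        print(render_table(pres))
        print()


if __name__ == "__main__":
    main()
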