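"""Model-versus-cohort comparison and the headline scalars.

Reduces the coefficient tables of the model study (analysis/01) and the
synthetic cohort (analysis/02) to the study's headline numbers:

* per-lead/side similarity percentages and their mean;
* the front-versus-back mean percentage difference of each table;
* the same two headline statistics recomputed from the published
  reference tables of the original volunteer study (the 4.95 %
  front/back difference and the 87.88 % mean similarity).

Reads the CSV outputs of the earlier scripts when present, otherwise
recomputes them; writes results/comparison/headline.json.

Run from the repository root:  python analysis/03_compare_model_cohort.py
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import pandas as pd  # noqa: E402

from torsoecg import cohort_tables  # noqa: E402
from torsoecg.pipeline import (compare_tables,  # noqa: E402
                               reference_front_back_difference,
                               reference_mean_similarity)


def load_or_none(path):
    return pd.read_csv(path, index_col=0) if path.exists() else None


def main() -> None:
    model = load_or_none(ROOT / "results" / "model_study" /
                         "coefficients.csv")
    cohort = load_or_none(ROOT / "results" / "cohort_study" /
                          "coefficients.csv")
    if model is None:
        print("model table missing; run analysis/01_model_study.py first")
        return
    if cohort is None:
        print("cohort table missing; using the published reference table")
        cohort = cohort_tables.VOLUNTEER_COEFFS_MEAN

    out = compare_tables(model, cohort)
    out["reference_front_back_difference_pct"] = \
        reference_front_back_difference()
    out["reference_mean_similarity_pct"] = reference_mean_similarity()

    dest = ROOT / "results" / "comparison"
    dest.mkdir(parents=True, exist_ok=True)
    (dest / "headline.json").write_text(json.dumps(out, indent=1))

    print("similarity per lead x side (model vs cohort table, %):")
    for col, val in out["similarity_by_column"].items():
        print(f"  {col}: {val:.1f}")
    print(f"mean similarity: {out['mean_similarity']:.1f} %")
    print(f"front/back difference, model table: "
          f"{out['front_back_difference_model']:.2f} %")
    print(f"front/back difference, cohort table: "
          f"{out['front_back_difference_cohort']:.2f} %")
    print("\npublished-reference headline statistics, recomputed:")
    print(f"  front/back difference of the volunteer table: "
          f"{out['reference_front_back_difference_pct']:.2f} % "
          f"(reported: 4.95 %)")
    print(f"  mean model-vs-volunteer similarity: "
          f"{out['reference_mean_similarity_pct']:.2f} % "
          f"(reported: 87.88 %)")


if __name__ == "__main__":
    main()
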