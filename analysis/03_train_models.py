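"""Train the per-power temperature models and report their accuracy.

Reads the feature tables from 02_extract_features.py, trains one
random-forest model per power group (Gini ranking -> top-10 selection ->
validation-gridded fit), and writes:

- results/importance_<power>.csv  -- the top of the feature ranking
- results/model_metrics.csv       -- val/test MAE and RMSE, test Pearson r
- results/feature_correlations.csv-- Pearson r with temperature for the
                                     headline texture features
- scratch/model_<power>.joblib    -- the serialized model artifact
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from thermotex.features import FEATURE_NAMES
from thermotex.model import (
    ForestConfig,
    feature_temperature_correlation,
    mae,
    predict,
    rmse,
    train_temperature_model,
)

ROOT = Path(__file__).resolve().parents[1]

HEADLINE_FEATURES = (
    "glcm_ClusterProminence",
    "firstorder_Variance",
    "firstorder_MeanAbsoluteDeviation",
    "firstorder_Minimum",
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    metrics, correlations = [], []
    for power in ("P15", "P20"):
        path = ROOT / "scratch" / f"features_{power.lower()}.csv"
        if not path.exists():
            print(f"skipping {power}: {path} not found (run 02 first)")
            continue
        df = pd.read_csv(path)
        X = df[list(FEATURE_NAMES)].to_numpy()
        y = df["temperature_C"].to_numpy()
        labels = df["split"].to_numpy()
        model = train_temperature_model(
            X, y, labels, ForestConfig(seed=args.seed), power_group=power
        )
        model.save(ROOT / "scratch" / f"model_{power.lower()}.joblib")
        pd.DataFrame(
            model.metadata["ranking"], columns=["feature", "gini_importance"]
        ).to_csv(ROOT / "results" / f"importance_{power.lower()}.csv", index=False)

        test = labels == "test"
        y_hat = predict(model, X[test])
        metrics.append(
            {
                "power": power,
                "val_mae_C": round(model.metadata["val_mae_C"], 3),
                "test_mae_C": round(mae(y[test], y_hat), 3),
                "test_rmse_C": round(rmse(y[test], y_hat), 3),
                "test_pearson_r": round(pearsonr(y[test], y_hat)[0], 4),
                "n_test": int(test.sum()),
                "n_trees": model.metadata["n_trees"],
                "min_leaf": model.metadata["min_leaf"],
            }
        )
        print(f"{power}: selected {model.selected_features}")
        print(f"{power}: {metrics[-1]}")

        hottest = df.groupby("point_index")["temperature_C"].max().idxmax()
        sub = df[df["point_index"] == hottest]
        for feat in HEADLINE_FEATURES:
            correlations.append(
                {
                    "power": power,
                    "feature": feat,
                    "pearson_r": round(
                        feature_temperature_correlation(
                            sub[feat].to_numpy(), sub["temperature_C"].to_numpy()
                        ),
                        4,
                    ),
                }
            )

    pd.DataFrame(metrics).to_csv(ROOT / "results" / "model_metrics.csv", index=False)
    corr = pd.DataFrame(correlations)
    corr.to_csv(ROOT / "results" / "feature_correlations.csv", index=False)
    print(corr.to_string(index=False))


if __name__ == "__main__":
    main()
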