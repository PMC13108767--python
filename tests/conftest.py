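import numpy as np
import pandas as pd
import pytest

import pifc


@pytest.fixture(scope="session")
def study_bundle():
    """Synthetic inputs at the study's default conditions, fitted once."""
    panel, truth = pifc.generate_panel(seed=11)
    anchors = pifc.generate_anchors(seed=12)
    rr = pifc.generate_rr_table(seed=13)
    model = pifc.TobaccoPolicyModel(panel, anchors, rr)
    results = model.fit()
    return {"panel": panel, "truth": truth, "anchors": anchors, "rr": rr,
            "model": model, "results": results}


@pytest.fixture(scope="session")
def noiseless_panel():
    """Zero-noise panel: downstream estimators must recover truth exactly."""
    panel, truth = pifc.generate_panel(noise_sd=0.0, seed=7)
    assert truth.clipped_fraction == 0.0
    return panel, truth


def random_small_panel(seed: int) -> pd.DataFrame:
    """Arbitrary small unbalanced-ish panel frame for oracle-equivalence tests."""
    rng = np.random.default_rng(seed)
    # keep the three-predictor model identified: rows > n_c + n_y + 2 params
    while True:
        n_c = int(rng.integers(2, 7))
        n_y = int(rng.integers(2, 7))
        if n_c * n_y > n_c + n_y + 3:
            break
    rows = []
    for ci in range(n_c):
        for yi in range(n_y):
            rows.append({
                "country": f"C{ci}",
                "year": 2010 + 2 * yi,
                "gender": "men",
                "prevalence": float(rng.uniform(5, 60)),
                "mpower": int(rng.integers(20, 32)),
                "affordability": float(rng.uniform(0, 15)),
                "literacy": float(rng.uniform(30, 100)),
            })
    return pd.DataFrame(rows)


def dummy_ols_oracle(df: pd.DataFrame, predictors: list[str]) -> np.ndarray:
    """Independent least-squares route: indicator columns built by hand,
    solved with numpy.linalg.lstsq. Returns the slope coefficients."""
    countries = sorted(df["country"].unique())
    years = sorted(df["year"].unique())
    cols = [np.ones(len(df))]
    cols += [df[p].to_numpy(dtype=float) for p in predictors]
    for c in countries[1:]:
        cols.append((df["country"] == c).to_numpy(dtype=float))
    for t in years[1:]:
        cols.append((df["year"] == t).to_numpy(dtype=float))
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, df["prevalence"].to_numpy(dtype=float), rcond=None)
    return beta[1:1 + len(predictors)]
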