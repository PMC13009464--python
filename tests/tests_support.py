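"""Shared helpers for the test suite."""

import numpy as np
import pandas as pd

from lfmckit import synthetic


def make_gfun_rows(n: int, seed: int, noise_sd: float = 10.0,
                   n_sites: int = 8) -> pd.DataFrame:
    """Training rows drawn from the planted LFMC generating function g()
    over realistic predictor ranges, with Gaussian observation noise."""
    rng = np.random.default_rng(seed)
    truth = synthetic.SyntheticTruth(noise_sd=0.0, seed=seed)
    df = pd.DataFrame(
        {
            "site_id": rng.choice([f"s{i}" for i in range(n_sites)], n),
            "P90": rng.uniform(0, 400, n),
            "T90": rng.uniform(8, 25, n),
            "SW150": rng.uniform(150, 350, n),
            "NIRv": rng.uniform(0.05, 0.45, n),
            "DL": rng.uniform(9.8, 14.4, n),
            "SM7": rng.uniform(0.05, 0.45, n),
            "W30": rng.uniform(1, 6, n),
            "VPD30": rng.uniform(0, 3, n),
            "P30": rng.uniform(0, 150, n),
        }
    )
    df["lfmc_percent"] = truth.g(df) + rng.normal(0, noise_sd, n)
    return df
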