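import numpy as np
import pandas as pd


def make_feature_frame(n=4, p=3, seed=0, diagnosis=None):
    """Small hand-sized feature DataFrame in the canonical dialect."""
    rng = np.random.default_rng(seed)
    if diagnosis is None:
        diagnosis = ["CN", "CN", "AD", "AD"][:n] + ["AD"] * max(0, n - 4)
    df = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "diagnosis": diagnosis,
            "age": rng.uniform(60, 90, n),
            "sex": rng.choice(["F", "M"], n),
            "education": rng.uniform(8, 20, n),
            "icv": rng.uniform(1.2e6, 1.8e6, n),
        }
    )
    for j in range(p):
        df[f"roi_{j}"] = rng.normal(3.0, 0.2, n)
    return df
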