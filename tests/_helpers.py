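import numpy as np
import pandas as pd


def random_survival_frame(rng, n, beta=0.5, rate=0.2, cens=0.25, tie_days=None):
    """Small random right-censored dataset with one covariate."""
    x = rng.normal(size=n)
    t_ev = rng.exponential(1.0 / (rate * np.exp(beta * x)))
    t_c = rng.exponential(1.0 / cens, size=n)
    t = np.minimum(t_ev, t_c)
    if tie_days:
        t = np.ceil(t * tie_days) / tie_days  # induce ties
    return pd.DataFrame(
        {
            "time_years": t,
            "status": np.where(t_ev <= t_c, "event", "censored"),
            "composite": x,
        }
    )
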