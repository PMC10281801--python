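"""Independent oracles shared across test modules."""

import numpy as np
import pandas as pd


def anova_repeatability(panel: pd.DataFrame, trait: str) -> float:
    """One-way ANOVA intraclass correlation (balanced designs)."""
    g = panel.groupby("individual_id")[trait]
    k = g.size().mean()
    msb = g.mean().var(ddof=1) * k
    ssw = (panel[trait] - g.transform("mean")).pow(2).sum()
    msw = ssw / (len(panel) - g.ngroups)
    s2a = (msb - msw) / k
    return s2a / (s2a + msw)


def ar1_chain(phi: float, n: int, seed: int = 0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = eps[0] / np.sqrt(1 - phi**2)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i]
    return x
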