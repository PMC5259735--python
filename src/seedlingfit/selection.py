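"""Small-sample Akaike information criteria and multi-model comparison.

Candidate models (one per grouping hypothesis, fitted by maximum likelihood
on the same data) are ranked by AICc, the Akaike information criterion with
the second-order small-sample correction:

    AICc = -2 logL + 2k + 2k(k+1) / (n - k - 1)

Differences from the best model (dAICc) are converted into Akaike weights
w_i = exp(-d_i/2) / sum_j exp(-d_j/2), evidence ratios ER = exp(d/2)
(= w_best / w_i), and qualitative support bands: d < 2 strong, 2 <= d < 4
moderate, 4 <= d <= 10 substantial-to-weak, d > 10 discard.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "aicc",
    "akaike_weights",
    "evidence_ratio",
    "support_category",
    "selection_table",
    "compare_fits",
]

SELECTION_COLUMNS = ("scheme", "df", "logL", "AICc", "dAICc", "wAICc", "ER",
                     "support")


def aicc(logl: float, k: int, n: int) -> float:
    """AICc = -2 logL + 2k + 2k(k+1)/(n-k-1); requires n > k + 1."""
    if not np.isfinite(logl):
        raise ValueError("logL must be finite")
    if n <= k + 1:
        raise ValueError(
            f"AICc undefined for n={n} <= k+1={k + 1}: small-sample "
            "correction divides by n-k-1")
    return -2.0 * logl + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(deltas: Sequence[float]) -> np.ndarray:
    """Normalized relative likelihoods exp(-d/2) of a candidate set."""
    deltas = np.asarray(deltas, dtype=float)
    if deltas.size == 0:
        raise ValueError("empty candidate set")
    if np.any(deltas < 0) or not np.isclose(deltas.min(), 0.0):
        raise ValueError("deltas must be >= 0 with at least one zero")
    rel = np.exp(-deltas / 2.0)
    return rel / rel.sum()


def evidence_ratio(delta: float) -> float:
    """exp(d/2): how many times better the best model is supported."""
    if delta < 0:
        raise ValueError("delta must be >= 0")
    return float(np.exp(delta / 2.0))


def support_category(delta: float) -> str:
    """Qualitative support band for a dAICc value."""
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if delta < 2:
        return "strong"
    if delta < 4:
        return "moderate"
    if delta <= 10:
        return "substantial-to-weak"
    return "discard"


def selection_table(entries: Iterable[tuple], n: int) -> pd.DataFrame:
    """Rank candidate models by AICc.

    Parameters
    ----------
    entries : iterable of (scheme_name, df, logL)
        One row per candidate fitted on the same data.
    n : int
        Shared number of observations.

    Returns a DataFrame sorted ascending by AICc with columns
    scheme, df, logL, AICc, dAICc, wAICc, ER, support.
    """
    rows = [(str(s), int(k), float(ll)) for s, k, ll in entries]
    if not rows:
        raise ValueError("empty candidate set")
    tab = pd.DataFrame(rows, columns=["scheme", "df", "logL"])
    tab["AICc"] = [aicc(ll, k, n) for _, k, ll in rows]
    tab = tab.sort_values("AICc", kind="mergesort").reset_index(drop=True)
    tab["dAICc"] = tab["AICc"] - tab["AICc"].iloc[0]
    tab["wAICc"] = akaike_weights(tab["dAICc"].to_numpy())
    tab["ER"] = [evidence_ratio(d) for d in tab["dAICc"]]
    tab["support"] = [support_category(d) for d in tab["dAICc"]]
    return tab[list(SELECTION_COLUMNS)]


def compare_fits(fits: Mapping[str, "FitResult"]) -> pd.DataFrame:  # noqa: F821
    """Selection table from fitted models keyed by scheme name.

    All fits must be on identical data (same number of observations).
    """
    if not fits:
        raise ValueError("no fits to compare")
    ns = {f.n_obs for f in fits.values()}
    if len(ns) != 1:
        raise ValueError(f"fits disagree on n_obs: {sorted(ns)}; selection "
                         "requires a common data set")
    entries = [(name, f.n_params, f.loglik) for name, f in fits.items()]
    return selection_table(entries, ns.pop())
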