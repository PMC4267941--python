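"""Cross-species comparison of cycling between ortholog pairs.

Given a table of ortholog pairs with per-species cycling calls (and, for
cycling members, fitted amplitude and phase), tests whether cycling state
is associated between the species and how well amplitude and phase agree
among co-cycling pairs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "co_cycling_contingency_test",
    "cross_species_parameter_agreement",
    "circular_correlation",
]


def co_cycling_contingency_test(
    pairs: pd.DataFrame, continuity_correction: bool = False
) -> dict:
    """Chi-square test of association between the two species' cycling calls.

    Returns the 2x2 table (cyclingA x cyclingB), the 1-df chi-square
    statistic and p (no continuity correction by default), and observed vs
    independence-expected co-cycling percentages, rounded to one decimal.
    """
    a = pairs["cyclingA"].to_numpy(bool)
    b = pairs["cyclingB"].to_numpy(bool)
    table = pd.crosstab(a, b).reindex(index=[True, False], columns=[True, False],
                                      fill_value=0)
    arr = table.to_numpy()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("degenerate margins: a species has no variation")
    chi2, p, dof, expected = stats.chi2_contingency(
        arr, correction=continuity_correction
    )
    n = arr.sum()
    return {
        "table": table,
        "chi2": float(chi2),
        "p": float(p),
        "dof": int(dof),
        "n_pairs": int(n),
        "n_co_cycling": int(arr[0, 0]),
        "observed_pct": round(100 * arr[0, 0] / n, 1),
        "expected_pct": round(100 * expected[0, 0] / n, 1),
    }


def circular_correlation(theta1: np.ndarray, theta2: np.ndarray) -> float:
    """Jammalamadaka-SenGupta circular correlation of two angle samples."""
    t1 = np.asarray(theta1, dtype=float)
    t2 = np.asarray(theta2, dtype=float)
    s1 = np.sin(t1 - stats.circmean(t1))
    s2 = np.sin(t2 - stats.circmean(t2))
    denom = np.sqrt((s1**2).sum() * (s2**2).sum())
    if denom == 0:
        return np.nan
    return float((s1 * s2).sum() / denom)


def cross_species_parameter_agreement(
    pairs: pd.DataFrame, day_length: float = 24.0
) -> dict:
    """Amplitude and phase agreement among co-cycling ortholog pairs.

    Amplitudes are compared on a log scale (Pearson r-squared is then
    invariant to each species' expression units); phases are compared
    linearly on the raw ZT values, with the circular correlation
    coefficient reported alongside as the rotation-safe diagnostic.
    """
    cc = pairs[pairs["cyclingA"] & pairs["cyclingB"]]
    if len(cc) < 3:
        raise ValueError("need at least three co-cycling pairs")
    amp_a = np.log(cc["amplitudeA"].to_numpy(float))
    amp_b = np.log(cc["amplitudeB"].to_numpy(float))
    ph_a = cc["phaseA"].to_numpy(float)
    ph_b = cc["phaseB"].to_numpy(float)
    for v in (amp_a, amp_b, ph_a, ph_b):
        if np.std(v) == 0:
            raise ValueError("zero-variance input")
    amp = stats.pearsonr(amp_a, amp_b)
    ph = stats.pearsonr(ph_a, ph_b)
    circ = circular_correlation(
        2 * np.pi * ph_a / day_length, 2 * np.pi * ph_b / day_length
    )
    return {
        "n_co_cycling": len(cc),
        "amplitude_r2": float(amp.statistic**2),
        "amplitude_p": float(amp.pvalue),
        "phase_r2": float(ph.statistic**2),
        "phase_p": float(ph.pvalue),
        "phase_circular_r": circ,
    }
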