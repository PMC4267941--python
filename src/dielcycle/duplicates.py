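"""Evolution of cycling state between duplicate (paralog) genes.

Pairs are binned by synonymous substitution rate Ks (a proxy for
duplication age).  The divergence of cycling state is modelled with three
difference equations over the state frequencies f = (f_CC, f_NN, f_D):
both-cycling (CC), both-noncycling (NN) and diverged (D, one of each).  A
common per-step divergence rate ``d`` moves identical pairs (CC or NN) to D
and a common reversion rate ``s`` moves D pairs back to an identical state,
split between CC and NN by ``alpha`` (default: even split):

    f_CC' = f_CC (1 - d) + alpha s f_D
    f_NN' = f_NN (1 - d) + (1 - alpha) s f_D
    f_D'  = f_D (1 - s) + d (f_CC + f_NN)

One model step corresponds to one Ks bin (width 0.3).  The rates are
identified in closed form from the frequency change between two consecutive
bins, and randomization tests quantify how strongly real pairs retain state
and phase relative to random re-pairings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DivergenceModel",
    "state_frequencies_by_ks",
    "step_model",
    "iterate_model",
    "steady_state",
    "fit_divergence_rates",
    "random_pairing_test",
    "phase_shift_enrichment",
    "circular_phase_distance",
]

STATES = ("CC", "NN", "D")


@dataclass(frozen=True)
class DivergenceModel:
    """Per-Ks-bin transition probabilities of the three-state model."""

    d: float
    s: float
    alpha: float = 0.5
    f0: tuple[float, float, float] = (0.35, 0.45, 0.20)

    def __post_init__(self) -> None:
        if not (0 <= self.d <= 1 and 0 <= self.s <= 1 and 0 <= self.alpha <= 1):
            raise ValueError("d, s and alpha must lie in [0, 1]")
        if abs(sum(self.f0) - 1) > 1e-9:
            raise ValueError("initial frequencies must sum to 1")


def step_model(model: DivergenceModel, f: np.ndarray) -> np.ndarray:
    """One difference-equation update of the state frequencies (CC, NN, D)."""
    f = np.asarray(f, dtype=float)
    if abs(f.sum() - 1) > 1e-9:
        raise ValueError("frequencies must sum to 1")
    d, s, a = model.d, model.s, model.alpha
    f_cc, f_nn, f_d = f
    return np.array(
        [
            f_cc * (1 - d) + a * s * f_d,
            f_nn * (1 - d) + (1 - a) * s * f_d,
            f_d * (1 - s) + d * (f_cc + f_nn),
        ]
    )


def iterate_model(model: DivergenceModel, n_steps: int, f=None) -> np.ndarray:
    """Trajectory of state frequencies; row i is the state after i steps."""
    f = np.asarray(model.f0 if f is None else f, dtype=float)
    out = np.empty((n_steps + 1, 3))
    out[0] = f
    for i in range(n_steps):
        out[i + 1] = step_model(model, out[i])
    return out


def steady_state(model: DivergenceModel) -> np.ndarray:
    """Equilibrium frequencies; the diverged fraction is d / (d + s)."""
    d, s, a = model.d, model.s, model.alpha
    if d + s == 0:
        raise ValueError("d = s = 0: every distribution is stationary")
    f_d = d / (d + s)
    return np.array([a * (1 - f_d), (1 - a) * (1 - f_d), f_d])


def fit_divergence_rates(
    f_t: np.ndarray, f_t1: np.ndarray, alpha: float = 0.5
) -> tuple[float, float]:
    """Closed-form (d, s) from state frequencies at two consecutive bins.

    With an even reversion split the difference f_CC - f_NN decays by
    (1 - d) each step, giving d directly; s then follows from the update of
    f_D.  Exact inverse of :func:`step_model` wherever identifiable.
    """
    f_t = np.asarray(f_t, dtype=float)
    f_t1 = np.asarray(f_t1, dtype=float)
    if abs(alpha - 0.5) > 1e-12:
        raise NotImplementedError("closed form assumes an even reversion split")
    gap = f_t[0] - f_t[1]
    if abs(gap) < 1e-12:
        raise ValueError("f_CC = f_NN: d is unidentifiable from these bins")
    if f_t[2] <= 0:
        raise ValueError("f_D = 0: s is unidentifiable from these bins")
    d = 1.0 - (f_t1[0] - f_t1[1]) / gap
    s = (f_t[2] - f_t1[2] + d * (1 - f_t[2])) / f_t[2]
    clipped = (min(max(d, 0.0), 1.0), min(max(s, 0.0), 1.0))
    if clipped != (d, s):
        import warnings

        warnings.warn(f"fitted rates ({d:.3f}, {s:.3f}) clipped to [0, 1]")
    return clipped


def state_frequencies_by_ks(
    pairs: pd.DataFrame, bin_width: float = 0.3
) -> pd.DataFrame:
    """Per-Ks-bin frequencies of CC / NN / D states.

    Bins are half-open [i*w, (i+1)*w); a pair with Ks exactly on an edge
    belongs to the upper bin.  Returns one row per occupied bin with the
    bin start, counts, and frequencies summing to 1.
    """
    if (pairs["ks"] < 0).any():
        raise ValueError("negative Ks")
    idx = np.floor(pairs["ks"].to_numpy() / bin_width).astype(int)
    rows = []
    for b in sorted(set(idx)):
        sub = pairs.loc[idx == b, "state"]
        n = len(sub)
        counts = {st: int((sub == st).sum()) for st in STATES}
        rows.append(
            {
                "ks_bin": b * bin_width,
                "n_pairs": n,
                **{f"n_{st}": counts[st] for st in STATES},
                **{f"f_{st}": counts[st] / n for st in STATES},
            }
        )
    return pd.DataFrame(rows)


def circular_phase_distance(
    phase1: np.ndarray, phase2: np.ndarray, day_length: float = 24.0
) -> np.ndarray:
    """|delta phase| on the circular day; at most day_length / 2."""
    diff = np.abs(np.asarray(phase1) - np.asarray(phase2)) % day_length
    return np.minimum(diff, day_length - diff)


def random_pairing_test(
    pairs: pd.DataFrame,
    statistic: str = "state",
    n_resamples: int = 100_000,
    seed: int = 0,
) -> dict:
    """Randomization test of state or phase retention among duplicates.

    ``statistic='state'`` counts pairs whose members share cycling status
    (both cycling or both noncycling); ``statistic='phase'`` counts
    co-cycling pairs with identical phase (the null then shuffles phases
    among co-cycling pairs only).  The null is built by shuffling the
    second gene's attributes across pairs ``n_resamples`` times; reported
    are the observed count, null mean/SD, Z, and a two-sided add-one
    smoothed empirical p.
    """
    if len(pairs) < 2:
        raise ValueError("need at least two pairs")
    rng = np.random.default_rng(seed)
    if statistic == "state":
        a = pairs["cycling1"].to_numpy(bool)
        b = pairs["cycling2"].to_numpy(bool)
        observed = int((a == b).sum())
        nulls = np.empty(n_resamples)
        for i in range(n_resamples):
            nulls[i] = (a == rng.permutation(b)).sum()
    elif statistic == "phase":
        cc = pairs[(pairs["cycling1"]) & (pairs["cycling2"])]
        p1 = cc["phase1"].to_numpy(float)
        p2 = cc["phase2"].to_numpy(float)
        observed = int((circular_phase_distance(p1, p2) == 0).sum())
        nulls = np.empty(n_resamples)
        for i in range(n_resamples):
            nulls[i] = (circular_phase_distance(p1, rng.permutation(p2)) == 0).sum()
    else:
        raise ValueError("statistic must be 'state' or 'phase'")
    mean, sd = float(nulls.mean()), float(nulls.std())
    flagged = sd == 0
    z = 0.0 if flagged else (observed - mean) / sd
    extreme = int((np.abs(nulls - mean) >= abs(observed - mean)).sum())
    p = (extreme + 1) / (n_resamples + 1)
    return {
        "observed": observed,
        "null_mean": mean,
        "null_sd": sd,
        "z": z,
        "p": p,
        "degenerate_null": flagged,
    }


def phase_shift_enrichment(
    pairs: pd.DataFrame,
    n_resamples: int = 10_000,
    seed: int = 0,
    day_length: float = 24.0,
) -> dict:
    """Enrichment of phase-shift events between co-cycling duplicates.

    Builds the phase1 x phase2 observed/expected matrix (expected from
    random re-pairing of phases), aggregates enrichment by circular
    |delta phase|, and fits an ordinary least squares line of enrichment on
    |delta phase|.  A negative slope with high r-squared indicates that
    small shifts are preferred.
    """
    cc = pairs[(pairs["cycling1"]) & (pairs["cycling2"])]
    if len(cc) < 2:
        raise ValueError("need at least two co-cycling pairs with phases")
    rng = np.random.default_rng(seed)
    p1 = cc["phase1"].to_numpy(float)
    p2 = cc["phase2"].to_numpy(float)
    phases = np.unique(np.concatenate([p1, p2]))
    obs = pd.crosstab(pd.Categorical(p1, categories=phases),
                      pd.Categorical(p2, categories=phases), dropna=False)
    obs.index.name, obs.columns.name = "phase1", "phase2"

    expected = np.zeros_like(obs.to_numpy(), dtype=float)
    shifts = circular_phase_distance(p1, p2, day_length)
    uniq_shifts = np.unique(
        circular_phase_distance(phases[:, None], phases[None, :], day_length)
    )
    null_shift_counts = np.zeros((n_resamples, uniq_shifts.size))
    for i in range(n_resamples):
        perm = rng.permutation(p2)
        expected += pd.crosstab(
            pd.Categorical(p1, categories=phases),
            pd.Categorical(perm, categories=phases), dropna=False,
        ).to_numpy()
        ds = circular_phase_distance(p1, perm, day_length)
        for j, u in enumerate(uniq_shifts):
            null_shift_counts[i, j] = (ds == u).sum()
    expected /= n_resamples
    with np.errstate(divide="ignore", invalid="ignore"):
        enr_matrix = pd.DataFrame(
            np.where(expected > 0, obs.to_numpy() / expected, np.nan),
            index=obs.index, columns=obs.columns,
        )

    obs_shift = np.array([(shifts == u).sum() for u in uniq_shifts], dtype=float)
    exp_shift = null_shift_counts.mean(axis=0)
    ok = exp_shift > 0
    enr = obs_shift[ok] / exp_shift[ok]
    x = uniq_shifts[ok]
    if np.unique(x).size < 2:
        return {
            "matrix": enr_matrix, "shift_enrichment": pd.Series(enr, index=x),
            "slope": np.nan, "r2": np.nan, "degenerate": True,
        }
    fit = stats.linregress(x, enr)
    return {
        "matrix": enr_matrix,
        "shift_enrichment": pd.Series(enr, index=x, name="enrichment"),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r2": float(fit.rvalue**2),
        "degenerate": False,
    }
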