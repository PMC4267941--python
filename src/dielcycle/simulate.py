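"""Synthetic diel data with known ground truth.

Generators for every input the pipeline consumes: expression time courses,
promoter sequences with planted motif sites, duplicate-pair cohorts evolved
under the three-state divergence model, and gene->term annotation tables.
Each generator is deterministic given its seed, and each returns the truth
alongside the data so downstream stages can be scored against it.

The default expression configuration emulates a two-day diel RNA-seq design:
8 ZT points at 3-h intervals, two biological replicates appended as two
consecutive 24-h days, cyclic genes with amplitude half their mean, and a
bimodal phase distribution peaking near dawn (ZT 0) and dusk (ZT 12).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .layout import DEFAULT_LAYOUT, SamplingLayout

__all__ = [
    "ExpressionConfig",
    "generate_expression",
    "generate_promoters",
    "generate_duplicate_pairs",
    "generate_annotations",
    "DEFAULT_PHASE_MIXTURE",
    "DEFAULT_SHIFT_KERNEL",
]

# Mixture over true phases: mass near dawn, mass near dusk, rest uniform.
DEFAULT_PHASE_MIXTURE = {"zt0": 0.4, "zt12": 0.3, "uniform": 0.3}
# Spread (h) of the dawn/dusk phase modes (wrapped normal).
PHASE_MODE_SD_HOURS = 1.5


@dataclass
class ExpressionConfig:
    """Settings for :func:`generate_expression`.

    amplitude_ratio is the per-gene amplitude/mean ratio ``a`` of the cosine
    ``mean * (1 + a * cos(2*pi*(t - phase)/period))``; the default 0.5 makes
    every cycling gene's amplitude exactly half its mean.  noise_cv is the
    coefficient of variation of multiplicative lognormal noise applied
    independently to every observation (replicate days are independent noisy
    realizations of the same underlying curve).
    """

    n_cycling: int = 500
    n_flat: int = 500
    amplitude_ratio: float = 0.5
    noise_cv: float = 0.1
    mean_log10_mu: float = 1.0
    mean_log10_sigma: float = 0.5
    phase_mixture: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHASE_MIXTURE)
    )
    period_hours: float | None = None  # defaults to the layout day length
    flat_trend_sd: float = 0.0  # per-day linear drift of noncycling genes

    def __post_init__(self) -> None:
        if self.n_cycling + self.n_flat < 1:
            raise ValueError("need at least one gene")
        if not 0 <= self.amplitude_ratio <= 1:
            raise ValueError(
                "amplitude_ratio must be in [0, 1]: ratios above 1 would "
                "force negative expression"
            )
        if self.noise_cv < 0:
            raise ValueError("noise CV must be nonnegative")


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    sigma = np.sqrt(sigma2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=sigma, size=size)


def _draw_phases(
    rng: np.random.Generator, n: int, mixture: Mapping[str, float], day_length: float
) -> np.ndarray:
    w = np.array(
        [mixture.get("zt0", 0.0), mixture.get("zt12", 0.0), mixture.get("uniform", 0.0)]
    )
    if w.sum() <= 0:
        raise ValueError("phase mixture weights must sum to a positive value")
    w = w / w.sum()
    comp = rng.choice(3, size=n, p=w)
    phases = np.empty(n)
    dawn = rng.normal(0.0, PHASE_MODE_SD_HOURS, size=n)
    dusk = rng.normal(day_length / 2, PHASE_MODE_SD_HOURS, size=n)
    unif = rng.uniform(0, day_length, size=n)
    phases[comp == 0] = dawn[comp == 0]
    phases[comp == 1] = dusk[comp == 1]
    phases[comp == 2] = unif[comp == 2]
    return np.mod(phases, day_length)


def generate_expression(
    config: ExpressionConfig | None = None,
    layout: SamplingLayout = DEFAULT_LAYOUT,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a diel expression matrix plus its truth table.

    Cycling genes follow ``mean * (1 + a*cos(2*pi*(t - phase)/period))``
    with multiplicative lognormal noise; flat genes are ``mean`` plus the
    same noise.  Gene means are drawn log-normally (log10 mean/sd from the
    config), so with a fixed amplitude ratio the true amplitude is strongly
    correlated with the mean.

    Returns the matrix and a truth table indexed by gene id with columns
    ``is_cycling, true_period, true_phase, true_amplitude, true_mean``.
    """
    config = config or ExpressionConfig()
    rng = np.random.default_rng(seed)
    period = config.period_hours or layout.day_length_hours
    n = config.n_cycling + config.n_flat
    means = 10.0 ** rng.normal(config.mean_log10_mu, config.mean_log10_sigma, size=n)
    if (means <= 0).any():
        raise ValueError("gene means must be positive")
    is_cycling = np.zeros(n, dtype=bool)
    is_cycling[: config.n_cycling] = True
    phases = np.full(n, np.nan)
    phases[: config.n_cycling] = _draw_phases(
        rng, config.n_cycling, config.phase_mixture, layout.day_length_hours
    )
    amp = np.where(is_cycling, config.amplitude_ratio * means, 0.0)

    t = layout.sample_times()  # (N,)
    curve = np.ones((n, layout.n_points)) * means[:, None]
    cyc = slice(0, config.n_cycling)
    curve[cyc] = means[cyc, None] * (
        1.0
        + config.amplitude_ratio
        * np.cos(2 * np.pi * (t[None, :] - phases[cyc, None]) / period)
    )
    if config.flat_trend_sd > 0 and config.n_flat > 0:
        # optional slow drift across each day for noncycling genes
        slopes = rng.normal(0, config.flat_trend_sd, size=config.n_flat)
        frac = (t % layout.day_length_hours) / layout.day_length_hours
        curve[config.n_cycling :] *= 1.0 + slopes[:, None] * (frac[None, :] - 0.5)
        curve[config.n_cycling :] = np.clip(curve[config.n_cycling :], 0, None)

    noisy = curve * _lognormal_factors(rng, config.noise_cv, curve.shape)
    gene_ids = [f"g{i:05d}" for i in range(n)]
    df = pd.DataFrame(noisy, index=pd.Index(gene_ids, name="gene_id"),
                      columns=layout.column_labels())
    truth = pd.DataFrame(
        {
            "is_cycling": is_cycling,
            "true_period": np.where(is_cycling, period, np.nan),
            "true_phase": phases,
            "true_amplitude": amp,
            "true_mean": means,
        },
        index=df.index,
    )
    return ExpressionMatrix(df, layout), truth


# ---------------------------------------------------------------------------
# Promoters with planted motif sites
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _consensus_of(motif) -> str:
    """Accept a Motif object (with .consensus) or a plain consensus string."""
    if isinstance(motif, str):
        return motif.upper()
    return str(motif.consensus).upper()


def generate_promoters(
    gene_phases: Mapping[str, float | None],
    motif_plant_plan: Mapping[float, tuple[object, float]],
    length: int = 1000,
    gc_content: float = 0.5,
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Simulate promoter sequences with phase-specific planted motifs.

    ``gene_phases`` maps each gene id to its phase bin (or None for genes
    outside any phase set).  ``motif_plant_plan`` maps a phase bin to a
    ``(motif, plant_frequency)`` pair; with probability plant_frequency one
    exact consensus instance of that phase's motif is inserted at a uniform
    position of the gene's promoter.  Background sequence is i.i.d. with the
    given GC content.

    Returns (gene -> sequence, planted-site table with columns
    ``gene_id, motif, position, phase``).
    """
    rng = np.random.default_rng(seed)
    if not 0 <= gc_content <= 1:
        raise ValueError("gc_content must be a fraction")
    p = np.array(
        [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    )
    for phase, (motif, freq) in motif_plant_plan.items():
        if not 0 <= freq <= 1:
            raise ValueError("plant_frequency must be in [0, 1]")
        if len(_consensus_of(motif)) > length:
            raise ValueError("motif longer than promoter")
    seqs: dict[str, str] = {}
    planted = []
    for gene, phase in gene_phases.items():
        idx = rng.choice(4, size=length, p=p)
        seq = _BASES[idx]
        if phase is not None and phase in motif_plant_plan:
            motif, freq = motif_plant_plan[phase]
            if rng.random() < freq:
                cons = _consensus_of(motif)
                pos = int(rng.integers(0, length - len(cons) + 1))
                seq[pos : pos + len(cons)] = list(cons)
                planted.append(
                    {"gene_id": gene, "motif": cons, "position": pos, "phase": phase}
                )
        seqs[gene] = "".join(seq)
    truth = pd.DataFrame(planted, columns=["gene_id", "motif", "position", "phase"])
    return seqs, truth


# ---------------------------------------------------------------------------
# Duplicate pairs under the three-state divergence model
# ---------------------------------------------------------------------------

# Probability of each phase shift between co-cycling duplicates; the mass
# concentrates on no shift and +/- one sampling interval.
DEFAULT_SHIFT_KERNEL = {0.0: 0.4, 3.0: 0.2, -3.0: 0.2}

_STATES = ("CC", "NN", "D")


def _expand_kernel(
    kernel: Mapping[float, float], layout: SamplingLayout
) -> tuple[np.ndarray, np.ndarray]:
    """Spread any unassigned kernel mass uniformly over the remaining bins."""
    bins = np.array(layout.zt_bins())
    day = layout.day_length_hours
    shifts = np.array(sorted({float(b) for b in bins}))
    probs = np.zeros_like(shifts)
    known = {float(k) % day: float(v) for k, v in kernel.items()}
    total_known = sum(known.values())
    if total_known > 1 + 1e-9:
        raise ValueError("shift kernel probabilities exceed 1")
    rest = [i for i, s in enumerate(shifts) if s not in known]
    for i, s in enumerate(shifts):
        if s in known:
            probs[i] = known[s]
    if rest:
        probs[rest] = (1 - total_known) / len(rest)
    elif abs(total_known - 1) > 1e-9:
        raise ValueError("shift kernel probabilities must sum to 1")
    return shifts, probs


def generate_duplicate_pairs(
    d: float = 0.42,
    s: float = 0.53,
    alpha: float = 0.5,
    initial_freqs: Sequence[float] = (0.35, 0.45, 0.20),
    ks_bins: int = 6,
    pairs_per_bin: int = 200,
    phase_shift_kernel: Mapping[float, float] | None = None,
    bin_width: float = 0.3,
    layout: SamplingLayout = DEFAULT_LAYOUT,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate paralog pairs whose cycling state evolved under the model.

    Pairs in the i-th Ks bin are simulated by drawing an initial state from
    ``initial_freqs`` (ordered CC, NN, D) and applying i per-bin Markov steps
    with divergence rate ``d``, reversion rate ``s`` and reversion split
    ``alpha``; Ks is drawn uniformly inside the bin.  Phases of co-cycling
    pairs are coupled through ``phase_shift_kernel``.
    """
    if not (0 <= d <= 1 and 0 <= s <= 1):
        raise ValueError("d and s must be probabilities")
    f0 = np.asarray(initial_freqs, dtype=float)
    if abs(f0.sum() - 1) > 1e-9:
        raise ValueError("initial_freqs must sum to 1")
    rng = np.random.default_rng(seed)
    shifts, shift_p = _expand_kernel(phase_shift_kernel or DEFAULT_SHIFT_KERNEL, layout)
    zt_bins = np.array(layout.zt_bins())
    day = layout.day_length_hours

    rows = []
    pair_no = 0
    for b in range(ks_bins):
        states = rng.choice(3, size=pairs_per_bin, p=f0)
        for _ in range(b):  # one model step per Ks bin crossed
            u = rng.random(pairs_per_bin)
            new = states.copy()
            ident = states != 2
            new[ident & (u < d)] = 2
            div = states == 2
            rev = div & (u < s)
            v = rng.random(pairs_per_bin)
            new[rev & (v < alpha)] = 0
            new[rev & (v >= alpha)] = 1
            states = new
        ks = rng.uniform(b * bin_width, (b + 1) * bin_width, size=pairs_per_bin)
        for j in range(pairs_per_bin):
            st = _STATES[states[j]]
            phase1 = phase2 = np.nan
            cyc1 = cyc2 = False
            if st == "CC":
                phase1 = float(rng.choice(zt_bins))
                shift = float(rng.choice(shifts, p=shift_p))
                phase2 = (phase1 + shift) % day
                cyc1 = cyc2 = True
            elif st == "D":
                ph = float(rng.choice(zt_bins))
                if rng.random() < 0.5:
                    phase1, cyc1 = ph, True
                else:
                    phase2, cyc2 = ph, True
            rows.append(
                {
                    "gene1": f"p{pair_no:05d}a",
                    "gene2": f"p{pair_no:05d}b",
                    "ks": float(ks[j]),
                    "state": st,
                    "cycling1": cyc1,
                    "cycling2": cyc2,
                    "phase1": phase1,
                    "phase2": phase2,
                }
            )
            pair_no += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------


def generate_annotations(
    truth: pd.DataFrame,
    terms_per_phase: int = 1,
    genes_per_term: int = 30,
    background_terms: int = 5,
    purity: float = 0.9,
    layout: SamplingLayout = DEFAULT_LAYOUT,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a gene->term annotation table from an expression truth table.

    Phase-linked terms draw a ``purity`` fraction of their members from
    cycling genes whose true phase rounds to one ZT bin, the rest at random;
    background terms draw uniformly from all genes.

    Returns (annotation table with columns ``gene_id, term_id``, term truth
    with columns ``term_id, phase``; background terms have phase NaN).
    """
    if genes_per_term < 2:
        raise ValueError("genes_per_term must be >= 2")
    rng = np.random.default_rng(seed)
    all_genes = np.asarray(truth.index)
    day = layout.day_length_hours
    interval = layout.interval_hours
    cycling = truth[truth["is_cycling"]]
    phase_bin = (
        np.round(cycling["true_phase"] / interval).astype(int) * interval
    ) % day

    ann_rows, term_rows = [], []
    for zt in layout.zt_bins():
        pool = np.asarray(cycling.index[phase_bin == zt])
        for t in range(terms_per_phase):
            term = f"TERM_ZT{zt:g}_{t}"
            n_in = int(round(purity * genes_per_term))
            n_in = min(n_in, len(pool))
            if n_in + (genes_per_term - n_in) > len(all_genes):
                raise ValueError("requested term larger than available gene pool")
            members = list(rng.choice(pool, size=n_in, replace=False))
            others = np.setdiff1d(all_genes, members)
            members += list(
                rng.choice(others, size=genes_per_term - n_in, replace=False)
            )
            ann_rows += [{"gene_id": g, "term_id": term} for g in members]
            term_rows.append({"term_id": term, "phase": zt})
    for t in range(background_terms):
        term = f"TERM_BG_{t}"
        members = rng.choice(all_genes, size=min(genes_per_term, len(all_genes)),
                             replace=False)
        ann_rows += [{"gene_id": g, "term_id": term} for g in members]
        term_rows.append({"term_id": term, "phase": np.nan})
    annotation = pd.DataFrame(ann_rows, columns=["gene_id", "term_id"])
    term_truth = pd.DataFrame(term_rows, columns=["term_id", "phase"])
    return annotation, term_truth
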