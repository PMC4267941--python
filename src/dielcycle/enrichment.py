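"""Fisher-exact term enrichment with Benjamini-Hochberg correction.

Tests whether annotation terms (GO-like, or motif-presence gene sets) are
over- or under-represented in a foreground gene set against a background,
per phase cluster or genome-wide.  Adjustment is applied within the family
of all terms tested for one cluster.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

__all__ = [
    "fisher_enrichment",
    "enrich_per_phase",
    "phase_specificity_summary",
    "functional_group_aggregate",
]

_ALTERNATIVES = {"over": "greater", "under": "less", "two-sided": "two-sided"}


def fisher_enrichment(
    foreground: set[str],
    background: set[str],
    annotation: pd.DataFrame,
    alternative: str = "over",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-term hypergeometric enrichment of ``foreground`` in ``background``.

    ``annotation`` is a two-column table (gene_id, term_id).  For each term
    a 2x2 table is built from (in foreground / not) x (annotated / not) and
    tested with Fisher's exact test; p-values are BH-adjusted across all
    terms tested here.  Returns one row per term with the 2x2 counts, odds
    ratio, raw and adjusted p, and a significance flag at ``alpha``.
    """
    if not foreground:
        raise ValueError("empty foreground")
    foreground = set(foreground)
    background = set(background)
    if not foreground <= background:
        raise ValueError("foreground must be a subset of background")
    ann = annotation[annotation["gene_id"].isin(background)]
    n_fg = len(foreground)
    n_bg = len(background)
    rows = []
    for term, members in ann.groupby("term_id")["gene_id"]:
        genes = set(members)
        a = len(genes & foreground)          # fg, annotated
        b = n_fg - a                         # fg, not annotated
        c = len(genes) - a                   # non-fg, annotated
        d = (n_bg - n_fg) - c                # non-fg, not annotated
        odds, p = fisher_exact([[a, b], [c, d]], _ALTERNATIVES[alternative])
        rows.append(
            {
                "term_id": term,
                "fg_annotated": a,
                "fg_total": n_fg,
                "bg_annotated": len(genes),
                "bg_total": n_bg,
                "odds_ratio": odds,
                "p": p,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "term_id", "fg_annotated", "fg_total", "bg_annotated",
                "bg_total", "odds_ratio", "p", "p_adj", "significant",
                "direction",
            ]
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["p_adj"] < alpha
    out["direction"] = alternative
    return out.sort_values("p_adj", kind="stable").reset_index(drop=True)


def enrich_per_phase(
    phase_of_gene: pd.Series,
    annotation: pd.DataFrame,
    background: set[str] | None = None,
    alternative: str = "over",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Enrichment of every term within every phase cluster.

    ``phase_of_gene`` maps cycling gene ids to their phase-cluster label.
    The background defaults to all cycling genes, so each phase is tested
    against the rest of the cycling set; adjustment is per phase (one BH
    family per cluster).
    """
    background = set(background) if background is not None else set(phase_of_gene.index)
    frames = []
    for zt in sorted(phase_of_gene.unique()):
        fg = set(phase_of_gene.index[phase_of_gene == zt])
        res = fisher_enrichment(fg, background, annotation, alternative, alpha)
        res.insert(0, "phase", zt)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


def phase_specificity_summary(
    per_phase: pd.DataFrame, interval_hours: float = 3.0, day_length: float = 24.0
) -> pd.DataFrame:
    """Count, per term, in how many phases it is enriched.

    A multi-phase term is classified ``adjacent`` when all its enriched
    phases occupy consecutive ZT bins on the circular day (ZT 21 and ZT 0
    are adjacent under a 3-h grid).
    """
    sig = per_phase[per_phase["significant"]]
    rows = []
    n_bins = int(round(day_length / interval_hours))
    for term, grp in sig.groupby("term_id"):
        phases = sorted(grp["phase"].unique())
        bins = sorted({int(round(p / interval_hours)) % n_bins for p in phases})
        adjacent = None
        if len(bins) > 1:
            # consecutive on the circle iff some rotation makes them a run
            gaps = [(bins[(i + 1) % len(bins)] - bins[i]) % n_bins
                    for i in range(len(bins))]
            adjacent = max(gaps) == n_bins - (len(bins) - 1)
        rows.append(
            {
                "term_id": term,
                "n_phases": len(phases),
                "phases": ",".join(f"{p:g}" for p in phases),
                "adjacent_only": adjacent,
            }
        )
    return pd.DataFrame(rows, columns=["term_id", "n_phases", "phases", "adjacent_only"])


def functional_group_aggregate(
    term_groups: pd.DataFrame, per_phase: pd.DataFrame
) -> pd.DataFrame:
    """Average -log10(p) of each functional group's terms per phase.

    ``term_groups`` maps term_id -> group.  Returns a group x phase matrix
    of the arithmetic mean of -log10(raw p) across the group's terms.
    """
    merged = per_phase.merge(term_groups, on="term_id", how="inner")
    if merged.empty:
        raise ValueError("no tested terms map to any group")
    missing = set(term_groups["term_id"]) - set(per_phase["term_id"])
    if missing:
        raise ValueError(f"terms never tested: {sorted(missing)[:5]} ...")
    merged["neglogp"] = -np.log10(merged["p"])
    mat = merged.pivot_table(
        index="group", columns="phase", values="neglogp", aggfunc="mean"
    )
    return mat
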