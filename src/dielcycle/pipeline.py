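"""Orchestration of the analysis stages into one reproducible run.

``run_pipeline`` executes the configured stages in order — simulate ->
detect -> cluster -> enrich -> duplicates -> orthologs -> scan/classify —
writing each stage's table next to the others and finishing with a JSON
manifest of versions, seeds and thresholds.  Any stage can be skipped;
later stages read the earlier ones' outputs, so a stage can also be run
against files produced elsewhere.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .clustering import subcluster_phases
from .duplicates import (
    DivergenceModel, fit_divergence_rates, iterate_model,
    random_pairing_test, state_frequencies_by_ks, steady_state,
)
from .enrichment import enrich_per_phase, fisher_enrichment
from .layout import SamplingLayout
from .motifs import pwm_pvalue_threshold, read_meme_minimal, scan_promoters
from .orthologs import co_cycling_contingency_test, cross_species_parameter_agreement
from .rhythm import detect_cycling, upper_quartile_normalize
from .simulate import ExpressionConfig, generate_annotations, generate_expression

log = logging.getLogger("dielcycle")

DEFAULT_STAGES = ("simulate", "detect", "cluster", "enrich", "duplicates")


def run_pipeline(config: dict, outdir) -> dict:
    """Run the configured stages; returns a dict of result objects.

    ``config`` keys (all optional): ``seed``, ``stages``, ``layout``
    (interval_hours/day_length_hours/n_days), ``simulate`` (passed to
    :class:`ExpressionConfig`), ``detect`` (top_percentile,
    n_permutations, overlap, upper_quartile), ``cluster`` (size_min,
    size_max, restarts), ``enrich`` (annotation path), ``duplicates``
    (pairs path, bin_width), ``orthologs`` (pairs path), ``scan``
    (motifs/promoters paths, pvalue).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = list(config.get("stages", DEFAULT_STAGES))
    layout = SamplingLayout(**config.get("layout", {}))
    results: dict = {}
    manifest: dict = {"seed": seed, "stages": stages}

    if "simulate" in stages:
        sim_cfg = ExpressionConfig(**config.get("simulate", {}))
        matrix, truth = generate_expression(sim_cfg, layout, seed=seed)
        dio.write_expression_tsv(matrix, outdir / "expression.tsv")
        truth.to_csv(outdir / "truth.tsv", sep="\t")
        results["matrix"], results["truth"] = matrix, truth

    if "detect" in stages:
        det = dict(config.get("detect", {}))
        matrix = results.get("matrix")
        if matrix is None:
            matrix = dio.read_expression_tsv(det.pop("expression", outdir / "expression.tsv"))
        if det.pop("upper_quartile", True):
            matrix = upper_quartile_normalize(matrix)
        fits = detect_cycling(
            matrix,
            top_percentile=det.get("top_percentile", 2.0),
            n_permutations=det.get("n_permutations", 10_000),
            overlap=det.get("overlap", 1.0),
            seed=seed,
        )
        fits.to_csv(outdir / "fits.tsv", sep="\t")
        manifest["cyclic_score_threshold"] = fits.attrs["threshold"]
        manifest["n_cycling"] = int(fits["is_cycling"].sum())
        results["matrix"], results["fits"] = matrix, fits

    if "cluster" in stages:
        cl = config.get("cluster", {})
        fits = results.get("fits")
        if fits is None:
            fits = pd.read_csv(outdir / "fits.tsv", sep="\t", index_col=0)
        clusters = subcluster_phases(
            results["matrix"].values, fits,
            size_bounds=(cl.get("size_min", 10), cl.get("size_max", 90)),
            seed=seed, n_restarts=cl.get("restarts", 10),
        )
        clusters.to_csv(outdir / "clusters.tsv", sep="\t")
        results["clusters"] = clusters

    if "enrich" in stages:
        en = config.get("enrich", {})
        fits = results["fits"]
        if "annotation" in en:
            annotation = pd.read_csv(en["annotation"], sep="\t")
        else:
            annotation, _ = generate_annotations(results["truth"], layout=layout,
                                                 seed=seed)
        cycling = fits[fits["is_cycling"]]
        overall = fisher_enrichment(
            set(cycling.index), set(fits.index), annotation
        )
        overall.to_csv(outdir / "enrichment_overall.tsv", sep="\t", index=False)
        per_phase = enrich_per_phase(cycling["phase_cluster"], annotation)
        per_phase.to_csv(outdir / "enrichment_by_phase.tsv", sep="\t", index=False)
        results["enrichment"] = per_phase

    if "duplicates" in stages:
        du = config.get("duplicates", {})
        if "pairs" in du:
            pairs = dio.read_pairs_tsv(du["pairs"])
        else:
            from .simulate import generate_duplicate_pairs

            pairs = generate_duplicate_pairs(layout=layout, seed=seed)
        freqs = state_frequencies_by_ks(pairs, du.get("bin_width", 0.3))
        freqs.to_csv(outdir / "duplicate_state_frequencies.tsv", sep="\t",
                     index=False)
        fit_from = du.get("fit_bins", (-2, -1))
        f_t = freqs.iloc[fit_from[0]][["f_CC", "f_NN", "f_D"]].to_numpy(float)
        f_t1 = freqs.iloc[fit_from[1]][["f_CC", "f_NN", "f_D"]].to_numpy(float)
        d, s = fit_divergence_rates(f_t, f_t1)
        model = DivergenceModel(d, s, f0=tuple(
            freqs.iloc[0][["f_CC", "f_NN", "f_D"]].to_numpy(float)))
        traj = iterate_model(model, len(freqs) - 1)
        pd.DataFrame(traj, columns=["f_CC", "f_NN", "f_D"]).to_csv(
            outdir / "duplicate_model_trajectory.tsv", sep="\t", index=False
        )
        retention = random_pairing_test(
            pairs, "state", n_resamples=du.get("n_resamples", 1000), seed=seed
        )
        manifest["divergence_model"] = {
            "d": d, "s": s,
            "steady_state_diverged": float(steady_state(model)[2]),
            "state_retention_z": retention["z"],
        }
        results["duplicates"] = {"pairs": pairs, "frequencies": freqs,
                                 "model": model, "retention": retention}

    if "orthologs" in stages:
        orth = config.get("orthologs", {})
        pairs = dio.read_pairs_tsv(orth["pairs"])
        contingency = co_cycling_contingency_test(pairs)
        agreement = cross_species_parameter_agreement(pairs, layout.day_length_hours)
        summary = pd.DataFrame([
            {"n_pairs": contingency["n_pairs"],
             "n_co_cycling": contingency["n_co_cycling"],
             "observed_pct": contingency["observed_pct"],
             "expected_pct": contingency["expected_pct"],
             "chi2": contingency["chi2"], "chi2_p": contingency["p"],
             **{k: v for k, v in agreement.items() if k != "n_co_cycling"}}
        ])
        summary.to_csv(outdir / "ortholog_summary.tsv", sep="\t", index=False)
        results["orthologs"] = {"contingency": contingency, "agreement": agreement}

    if "scan" in stages:
        sc = config.get("scan", {})
        motifs = read_meme_minimal(sc["motifs"])
        promoters = dio.read_fasta(sc["promoters"])
        thresholds = [pwm_pvalue_threshold(m, p=sc.get("pvalue", 1e-5))
                      for m in motifs]
        presence, hits = scan_promoters(thresholds, promoters)
        presence.astype(int).to_csv(outdir / "presence.tsv", sep="\t")
        hits.to_csv(outdir / "hits.tsv", sep="\t", index=False)
        results["presence"], results["hits"] = presence, hits

    dio.write_manifest(outdir / "manifest.json", **manifest)
    return results
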