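"""End-to-end orchestration: cohort in, association report tables out.

``run_analysis`` chains the stages — (simulate or ingest) -> profile
deduplication -> outlier-array screening -> quantile normalization ->
batch adjustment -> metagene scoring -> subtype assignment -> response
coding -> regression tables — and writes the six report CSVs, a cohort
summary, the metagene Spearman matrix, a treatment-by-response chi-square
result and a run manifest whose sample-count chain is non-increasing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import code_response, summarize_cohort
from .expression import ExpressionMatrix
from .models import (adjusted_response_table, build_design, chisq_independence,
                     spearman_matrix, stepwise_select, stratified_analysis,
                     univariate_response_table)
from .preprocess import (combat_adjust, dedup_profiles, filter_outliers,
                         quantile_normalize)
from .signatures import SignatureSet, assign_tertiles, collapse_probes, score_all_metagenes
from .simulate import SimulationConfig, SyntheticCohort, simulate_cohort
from .subtype import SUBTYPES, CentroidSet, classify_subtype

__all__ = ["run_analysis", "group_treatment"]

log = logging.getLogger(__name__)

_ANTHRACYCLINE = {"FAC", "FEC"}
_COMBINATION = {"FAC+paclitaxel", "FAC+docetaxel", "FEC+paclitaxel"}
_TAXANE = {"paclitaxel", "docetaxel"}


def group_treatment(treatment: pd.Series) -> pd.Series:
    """Collapse treatment regimens into four groups for the chi-square test.

    anthracycline-only, anthracycline+taxane, taxane-only, unspecified.
    """
    def grp(t):
        if pd.isna(t) or t == "unspecified":
            return "unspecified"
        if t in _ANTHRACYCLINE:
            return "anthracycline"
        if t in _COMBINATION:
            return "anthracycline+taxane"
        if t in _TAXANE:
            return "taxane"
        return "unspecified"

    return treatment.map(grp)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_analysis(out_dir: str | Path,
                 cohort: SyntheticCohort | None = None,
                 sim_config: SimulationConfig | None = None,
                 seed: int | None = None,
                 matrix: ExpressionMatrix | None = None,
                 clinical: pd.DataFrame | None = None,
                 signatures: SignatureSet | None = None,
                 centroids: CentroidSet | pd.DataFrame | None = None,
                 panel_probes: pd.DataFrame | None = None,
                 skip_batch_adjust: bool = False) -> dict:
    """Run the full analysis and write the report bundle to ``out_dir``.

    Inputs are either a (simulated) :class:`SyntheticCohort`, a
    ``sim_config``/``seed`` pair to simulate one, or explicit
    matrix/clinical/signatures components. Returns a dict with every
    table plus the manifest; the same inputs and seed reproduce the
    bundle exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cohort is None and matrix is None:
        cohort = simulate_cohort(sim_config, seed=seed)
    if cohort is not None:
        matrix = cohort.matrix
        clinical = cohort.clinical
        signatures = cohort.signatures
        centroids = cohort.centroids
        panel_probes = cohort.panel_probes
    if matrix is None or clinical is None or signatures is None:
        raise ValueError("need a cohort or matrix+clinical+signatures inputs")

    counts = {"input": matrix.n_samples}

    stage = "dedup_profiles"
    try:
        matrix, dedup_report = dedup_profiles(matrix)
        counts["unique"] = matrix.n_samples
        stage = "filter_outliers"
        matrix, outlier_report = filter_outliers(matrix)
        counts["post_outlier"] = matrix.n_samples
        stage = "quantile_normalize"
        matrix = quantile_normalize(matrix)
        stage = "combat_adjust"
        if not skip_batch_adjust and matrix.batch is not None \
                and matrix.batch.nunique() > 1:
            matrix = combat_adjust(matrix)
        stage = "score_metagenes"
        scores = score_all_metagenes(matrix, signatures)
        counts["scored"] = len(scores)
        tertiles = assign_tertiles(scores["P"])
        stage = "classify_subtype"
        classified = None
        if centroids is not None:
            cset = centroids if isinstance(centroids, CentroidSet) \
                else CentroidSet(pd.DataFrame(centroids))
            gene_matrix = _panel_gene_matrix(matrix, panel_probes, cset)
            classified, _corr = classify_subtype(gene_matrix, cset)
        stage = "code_response"
        clin = code_response(clinical.set_index("sample_id")
                             if "sample_id" in clinical.columns else clinical)
        clin = clin.reindex(scores.index)
        subtype = clin["subtype"] if clin["subtype"].notna().any() else classified
        y = clin["response"]
        counts["response_annotated"] = int(y.notna().sum())

        stage = "association_tables"
        tables = _association_tables(scores, tertiles, subtype, clin, y)
        counts["complete_case_stepwise"] = int(tables["table5_stepwise_n"])
    except Exception as err:
        raise RuntimeError(
            f"pipeline failed at stage {stage!r}: {err}; counts so far {counts}"
        ) from err

    summary = summarize_cohort(clin.assign(response=y))
    rho = spearman_matrix(scores)

    grouped = group_treatment(clin["treatment"])
    ct = pd.crosstab(grouped[y.notna()], y.dropna())
    chi_stat, chi_df, chi_p = chisq_independence(ct)

    agreement = None
    if classified is not None and subtype is not None:
        both = pd.DataFrame({"a": classified, "b": subtype}).dropna()
        agreement = float((both["a"] == both["b"]).mean()) if len(both) else None

    manifest = {
        "tool": "immunomet",
        "version": __version__,
        "seed": seed if seed is not None
                else (cohort.config.seed if cohort is not None else None),
        "config": _config_snapshot(cohort),
        "sample_counts": counts,
        "chi_square_treatment_response": {"statistic": chi_stat, "df": chi_df,
                                          "p_value": chi_p},
        "subtype_classification_agreement": agreement,
        "score_unit": "one log2-intensity unit of the raw (uncentered) metagene score",
    }
    chain = list(counts.values())
    assert all(a >= b for a, b in zip(chain, chain[1:])), \
        "sample-count chain must be non-increasing"

    results = {
        "table2_univariate": tables["univariate"],
        "table2_adjusted": tables["adjusted"],
        "table3_tertiles": tables["tertiles"],
        "table4_subtypes": tables["subtypes"],
        "table5_stepwise": tables["step_categorical"],
        "table6_stepwise": tables["step_binary"],
        "summary_table1": summary,
        "spearman": rho,
        "manifest": manifest,
        "scores": scores,
        "tertiles": tertiles,
        "dedup_report": dedup_report,
        "outlier_report": outlier_report,
    }
    _write_bundle(out, results)
    return results


def _panel_gene_matrix(matrix: ExpressionMatrix, panel_probes: pd.DataFrame | None,
                       cset: CentroidSet) -> pd.DataFrame:
    """Gene-level matrix for the centroid panel.

    With a probe->gene map, panel probe rows are collapsed by mean; when
    the matrix rows already are gene symbols the overlap is used as-is.
    """
    if panel_probes is not None:
        present = panel_probes.loc[panel_probes["probe_id"].isin(matrix.values.index)]
        sub = matrix.values.loc[present["probe_id"]]
        sub.index = present["gene_symbol"].to_numpy()
        return sub.groupby(level=0, sort=True).mean()
    shared = [g for g in cset.panel_genes if g in matrix.values.index]
    return matrix.values.loc[shared]


def _association_tables(scores, tertiles, subtype, clin, y) -> dict:
    univariate = univariate_response_table(scores, subtype, y)
    adjusted = adjusted_response_table(scores, subtype, y)
    tert = stratified_analysis(scores, tertiles, y)
    tert["stratum"] = tert["stratum"].map(
        {"low": "P-low", "intermediate": "P-intermediate", "high": "P-high"})
    subs = stratified_analysis(scores, subtype, y)

    # stepwise: ER + P + three immune metagenes + subtype, two codings
    data = scores.copy()
    data["er_status"] = clin["er_status"]
    data["subtype"] = subtype
    design_cat, tmap_cat = build_design(
        data, continuous=tuple(scores.columns),
        categorical={"er_status": "positive", "subtype": "Normal-like"})
    step_cat = stepwise_select(design_cat, tmap_cat, y)

    design_bin, tmap_bin = build_design(
        data, continuous=tuple(scores.columns), categorical={"er_status": "positive"})
    for s in SUBTYPES:
        col = f"is_{s}"
        design_bin[col] = subtype.map(
            lambda v: np.nan if pd.isna(v) else float(v == s))
        tmap_bin[col] = [col]
    step_bin = stepwise_select(design_bin, tmap_bin, y)

    return {
        "univariate": univariate,
        "adjusted": adjusted,
        "tertiles": tert,
        "subtypes": subs,
        "step_categorical": _stepwise_table(step_cat),
        "step_binary": _stepwise_table(step_bin),
        "table5_stepwise_n": step_cat.final.n_used,
    }


def _stepwise_table(result) -> pd.DataFrame:
    rows = []
    fit = result.final
    for term in result.selected:
        cols = [c for c in fit.odds_ratios.index
                if c == term or c.startswith(f"{term}[") or c == f"is_{term}"]
        entry = result.steps.loc[(result.steps["term"] == term)
                                 & (result.steps["action"] == "enter"), "p_value"]
        p = float(entry.iloc[-1]) if len(entry) else np.nan
        for c in cols:
            r = fit.odds_ratios.loc[c]
            rows.append({"variable": c, "odds_ratio": float(r["odds_ratio"]),
                         "ci_low": float(r["ci_low"]), "ci_high": float(r["ci_high"]),
                         "p_value": p, "n": fit.n_used, "converged": fit.converged})
    return pd.DataFrame(rows, columns=["variable", "odds_ratio", "ci_low",
                                       "ci_high", "p_value", "n", "converged"])


def _config_snapshot(cohort: SyntheticCohort | None):
    if cohort is None:
        return None
    snap = dataclasses.asdict(cohort.config)
    snap["latent_spearman"] = np.asarray(snap["latent_spearman"]).tolist()
    return snap


def _write_bundle(out: Path, results: dict) -> None:
    for name in ("table2_univariate", "table2_adjusted", "table3_tertiles",
                 "table4_subtypes", "table5_stepwise", "table6_stepwise",
                 "summary_table1"):
        results[name].to_csv(out / f"{name}.csv", index=False)
    results["spearman"].to_csv(out / "spearman.csv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(results["manifest"], fh, indent=2, default=str)
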