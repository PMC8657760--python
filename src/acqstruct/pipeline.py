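"""End-to-end orchestration: responses -> ACQ -> indicators -> factors ->
congruence, for the raw and acquiescence-corrected branches.

Corrected branch: compute_acq -> center_responses -> key_orient ->
cluster_scores. Raw branch: reverse_raw -> cluster_scores. Both feed a
correlation matrix into five-factor extraction with oblique target
rotation, blueprint alignment, and idealized-target congruence. The
identity-only, self-efficacy-only and joint indicator sets are analyzed on
the corrected branch with principal components (unconstrained loadings),
mirroring how the two measurement approaches are compared in the field.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .acquiescence import (
    center_responses,
    compute_acq,
    key_orient,
    validate_responses,
)
from .blueprint import InstrumentBlueprint
from .congruence import (
    CongruenceReport,
    congruence_matrix,
    congruence_summary,
    ideal_target,
)
from .factor import (
    FactorSolution,
    FitStats,
    align_to_blueprint,
    blueprint_target_mask,
    correlation_matrix,
    extract,
    fit_statistics,
    rotate_to_target,
)
from .scoring import cluster_scores, reverse_raw

logger = logging.getLogger("acqstruct.pipeline")

_EFA_METHODS = {"efa-ml": "ml", "efa-minres": "minres", "pca": "pca"}


@dataclass
class PipelineConfig:
    """Analysis settings; defaults follow the package's reference analysis:
    oblique-target ML on the 54 triplet indicators for both branches, plus
    target-rotated principal components for the 18-identity, 18-self-efficacy
    and joint 36-indicator sets on corrected scores."""

    correct_acquiescence: bool = True
    raw_branch: bool = True
    n_factors: int = 5
    method: str = "efa-ml"  # efa-ml | efa-minres | pca  (triplet54 analyses)
    rotation: str = "target-oblique"  # target-oblique | target-orthogonal | none
    schemes: tuple = ("triplet54", "identity18", "se18", "joint36")
    pca_rotate: bool = True  # target-rotate the PCA variants too
    congruence_methods: tuple = ("tucker", "pearson")
    use: str = "listwise"
    seed: int = 0
    min_identity_items: int = 54
    max_incomplete_pair_frac: float = 0.25


@dataclass
class AnalysisReport:
    acq_summary: dict
    acq_table: pd.DataFrame | None
    solutions: dict  # (branch, scheme) -> aligned FactorSolution
    congruence: dict  # (branch, scheme, method) -> CongruenceReport
    fits: dict  # (branch, scheme) -> FitStats (ml solutions only)
    n_used: dict  # (branch, scheme) -> rows entering the correlation
    provenance: dict


def _analyze_indicators(
    ind: pd.DataFrame,
    bp: InstrumentBlueprint,
    cfg: PipelineConfig,
    branch: str,
    scheme: str,
    method: str,
) -> tuple[FactorSolution, FitStats | None, int]:
    R, n_used = correlation_matrix(ind, use=cfg.use)
    logger.info("[%s/%s] correlation over %d indicators, n=%d",
                branch, scheme, R.shape[0], n_used)
    sol = extract(R, cfg.n_factors, method=method)
    do_rotate = cfg.rotation != "none" and (method != "pca" or cfg.pca_rotate)
    if do_rotate:
        mask = blueprint_target_mask(bp, list(ind.columns))
        sol = rotate_to_target(
            sol, mask,
            oblique=(cfg.rotation == "target-oblique"),
            seed=cfg.seed,
        )
        if not sol.converged:
            logger.warning("[%s/%s] target rotation did not converge", branch, scheme)
    sol = align_to_blueprint(sol, bp)
    fit = None
    if method == "ml":
        fit = fit_statistics(R, sol, n_used)
        logger.info("[%s/%s] chi2=%.1f df=%d rmsea=%.3f srmr=%.3f",
                    branch, scheme, fit.chi_square, fit.df, fit.rmsea, fit.srmr)
    return sol, fit, n_used


def run_full_analysis(
    responses: pd.DataFrame,
    bp: InstrumentBlueprint,
    cfg: PipelineConfig | None = None,
) -> AnalysisReport:
    """Run the complete internal-structure analysis on a response matrix."""
    cfg = cfg or PipelineConfig()
    validate_responses(responses, bp)
    method = _EFA_METHODS.get(cfg.method)
    if method is None:
        raise ValueError(f"unknown method {cfg.method!r}")

    solutions: dict = {}
    congruence: dict = {}
    fits: dict = {}
    n_used: dict = {}
    acq_summary: dict = {}
    acq_table = None

    oriented = None
    if cfg.correct_acquiescence:
        logger.info("[acq] estimating acquiescence for %d respondents", len(responses))
        acq = compute_acq(
            responses, bp,
            min_identity_items=cfg.min_identity_items,
            max_incomplete_pair_frac=cfg.max_incomplete_pair_frac,
        )
        acq_table = acq.table
        acq_summary = {
            "mean": float(acq.acq.mean()),
            "sd": float(acq.acq.std(ddof=1)),
            "pct_flagged": float(100.0 * (~acq.table["balanced_flag"]).mean()),
            "n": int(len(acq.table)),
        }
        logger.info("[acq] mean=%.3f sd=%.3f flagged=%.1f%%",
                    acq_summary["mean"], acq_summary["sd"],
                    acq_summary["pct_flagged"])
        corrected = center_responses(responses, acq, bp)
        oriented = key_orient(corrected, bp)

    branches = []
    if cfg.raw_branch:
        branches.append(("raw", reverse_raw(responses, bp), ("triplet54",)))
    if oriented is not None:
        branches.append(("corrected", oriented, cfg.schemes))

    for branch, matrix, schemes in branches:
        for scheme in schemes:
            if scheme not in cfg.schemes:
                continue
            # non-triplet schemes use unconstrained principal components
            scheme_method = method if scheme == "triplet54" else "pca"
            ind = cluster_scores(matrix, bp, scheme)
            sol, fit, n = _analyze_indicators(ind, bp, cfg, branch, scheme,
                                              scheme_method)
            solutions[(branch, scheme)] = sol
            n_used[(branch, scheme)] = n
            if fit is not None:
                fits[(branch, scheme)] = fit
            target = ideal_target(bp, list(sol.loadings.index))
            for cm in cfg.congruence_methods:
                congruence[(branch, scheme, cm)] = congruence_matrix(
                    sol.loadings, target, method=cm
                )

    provenance = {
        "package_version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "n_respondents": int(len(responses)),
        "n_items": int(responses.shape[1]),
        "input_hash": hashlib.sha256(
            pd.util.hash_pandas_object(responses.fillna(-1), index=True)
            .to_numpy().tobytes()
        ).hexdigest(),
        "blueprint_hash": hashlib.sha256(
            bp.to_frame().to_csv(index=False).encode()
        ).hexdigest(),
    }
    return AnalysisReport(
        acq_summary=acq_summary,
        acq_table=acq_table,
        solutions=solutions,
        congruence=congruence,
        fits=fits,
        n_used=n_used,
        provenance=provenance,
    )


def write_report(report: AnalysisReport, out_dir) -> list[Path]:
    """Write the deterministic file set; identical inputs give byte-identical
    files. Pre-existing files from earlier runs with our naming patterns are
    removed first so a raw-only rerun leaves no stale corrected tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for old in out.glob("*.csv"):
        if old.name.startswith(("loadings_", "phi_", "congruence_", "fit_", "acq")):
            old.unlink()
    (out / "provenance.json").unlink(missing_ok=True)

    ff = "%.10g"
    written: list[Path] = []

    def _save(df: pd.DataFrame, name: str):
        p = out / name
        df.to_csv(p, float_format=ff)
        written.append(p)

    if report.acq_table is not None:
        _save(report.acq_table, "acq.csv")
    for (branch, scheme), sol in sorted(report.solutions.items()):
        tbl = sol.loadings.copy()
        tbl["uniqueness"] = report.solutions[(branch, scheme)].uniquenesses
        _save(tbl, f"loadings_{branch}_{scheme}.csv")
        _save(sol.phi, f"phi_{branch}_{scheme}.csv")
    for (branch, scheme, cm), rep in sorted(report.congruence.items()):
        tbl = rep.matrix.copy()
        summ = congruence_summary(rep)
        tbl.attrs = {}
        _save(tbl, f"congruence_{branch}_{scheme}_{cm}.csv")
    for (branch, scheme), fit in sorted(report.fits.items()):
        _save(fit.to_frame().set_index(pd.Index([scheme], name="scheme")),
              f"fit_{branch}_{scheme}.csv")

    prov_path = out / "provenance.json"
    prov = dict(report.provenance)
    prov["acq_summary"] = report.acq_summary
    prov["congruence_summaries"] = {
        f"{b}/{s}/{m}": congruence_summary(rep)
        for (b, s, m), rep in sorted(report.congruence.items())
    }
    prov_path.write_text(json.dumps(prov, indent=2, sort_keys=True) + "\n")
    written.append(prov_path)
    return written


def render_text_tables(report: AnalysisReport) -> str:
    """Plain-text summary tables (optional report renderer)."""
    lines = []
    if report.acq_summary:
        lines.append("Acquiescence index")
        lines.append(
            f"  mean={report.acq_summary['mean']:.3f} "
            f"sd={report.acq_summary['sd']:.3f} "
            f"flagged={report.acq_summary['pct_flagged']:.1f}% "
            f"(n={report.acq_summary['n']})"
        )
    for (branch, scheme, cm), rep in sorted(report.congruence.items()):
        summ = congruence_summary(rep)
        lines.append(f"Congruence [{branch}/{scheme}/{cm}]  "
                     f"diag_mean={summ['diag_mean']:.3f} "
                     f"diag_min={summ['diag_min']:.3f} "
                     f"off_max={summ['off_diag_max_abs']:.3f}")
        lines.append(rep.matrix.round(2).to_string())
    for (branch, scheme), fit in sorted(report.fits.items()):
        lines.append(
            f"Fit [{branch}/{scheme}]  chi2={fit.chi_square:.1f} df={fit.df} "
            f"CFI={fit.cfi:.2f} TLI={fit.tli:.2f} "
            f"RMSEA={fit.rmsea:.3f} SRMR={fit.srmr:.3f}"
        )
    return "\n".join(lines) + "\n"
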