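"""Idealized-target congruence: how closely does an empirical loading
matrix match the theoretical simple structure?

For each of the five domains, the theoretical target is a one-hot vector
over the indicators — 1 on indicators whose facet belongs to that domain,
0 elsewhere (deliberately ignoring known secondary loadings). Each
empirical factor column is then compared with each target column, by
Tucker's congruence coefficient (normalized inner product; the default) or
Pearson correlation over indicators. A perfectly recovered structure has a
diagonal of 1s and zero off-diagonal entries after the factors are aligned
to the blueprint.

Tucker is the default because it is what the published congruence table for
this instrument actually contains: recomputing from the published loading
matrices, Tucker reproduces every printed cell to within rounding (0.005),
whereas row-centered Pearson is systematically lower. Both are exposed and
the report writer emits both side by side.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .blueprint import InstrumentBlueprint
from .scoring import indicator_facet

_REFERENCE_PATH = Path(__file__).parent / "data" / "reference_loadings.csv"


@dataclass
class CongruenceReport:
    matrix: pd.DataFrame  # rows = empirical factors, columns = theoretical domains
    method: str  # pearson | tucker

    @property
    def diag_mean(self) -> float:
        return float(np.mean(np.diag(self.matrix.to_numpy())))

    @property
    def diag_min(self) -> float:
        return float(np.min(np.diag(self.matrix.to_numpy())))


def ideal_target(bp: InstrumentBlueprint, indicator_labels) -> pd.DataFrame:
    """One-hot theoretical loading matrix: rows = indicators, columns =
    domain codes; exactly one 1 per row, on the indicator's intended domain."""
    rows = []
    for label in indicator_labels:
        facet = indicator_facet(label)
        try:
            dom = bp.facet_domain(facet)
        except KeyError:
            raise ValueError(f"indicator label {label!r}: unknown facet {facet!r}")
        rows.append([1.0 if c == dom else 0.0 for c in bp.domain_codes])
    return pd.DataFrame(rows, index=list(indicator_labels),
                        columns=list(bp.domain_codes))


def _pearson_columns(L: np.ndarray, T: np.ndarray) -> np.ndarray:
    """C[f, d] = Pearson correlation over rows between empirical column f
    and target column d."""
    Lc = L - L.mean(axis=0)
    Tc = T - T.mean(axis=0)
    ln = np.linalg.norm(Lc, axis=0)
    tn = np.linalg.norm(Tc, axis=0)
    if np.any(ln == 0):
        raise ValueError("zero-variance empirical loading column")
    if np.any(tn == 0):
        raise ValueError("zero-variance target column")
    return (Lc.T @ Tc) / np.outer(ln, tn)


def _tucker_columns(L: np.ndarray, T: np.ndarray) -> np.ndarray:
    ln = np.linalg.norm(L, axis=0)
    tn = np.linalg.norm(T, axis=0)
    if np.any(ln == 0) or np.any(tn == 0):
        raise ValueError("zero column in loadings or target")
    return (L.T @ T) / np.outer(ln, tn)


def congruence_matrix(
    loadings: pd.DataFrame, target: pd.DataFrame, method: str = "tucker"
) -> CongruenceReport:
    """All pairwise congruence coefficients between empirical factor columns
    (rows of the report) and theoretical domain columns.

    Rows of ``loadings`` and ``target`` must be the same indicators in the
    same order. No re-alignment happens here; align the solution first if
    matched diagonal entries are wanted.
    """
    if loadings.shape[0] != target.shape[0]:
        raise ValueError("loadings and target must share row count")
    if not list(loadings.index) == list(target.index):
        raise ValueError("loadings and target must share row order")
    if method == "pearson":
        C = _pearson_columns(loadings.to_numpy(float), target.to_numpy(float))
    elif method == "tucker":
        C = _tucker_columns(loadings.to_numpy(float), target.to_numpy(float))
    else:
        raise ValueError(f"unknown method {method!r}")
    mat = pd.DataFrame(C, index=list(loadings.columns), columns=list(target.columns))
    return CongruenceReport(matrix=mat, method=method)


def congruence_summary(report: CongruenceReport) -> dict:
    """diag_mean, diag_min and the largest-magnitude off-diagonal entry."""
    C = report.matrix.to_numpy()
    if C.shape[0] != C.shape[1]:
        raise ValueError("summary requires a square congruence matrix")
    off = C[~np.eye(C.shape[0], dtype=bool)]
    return {
        "diag_mean": float(np.diag(C).mean()),
        "diag_min": float(np.diag(C).min()),
        "off_diag_max_abs": float(np.abs(off).max()),
    }


def load_reference_loadings(branch: str = "corrected") -> pd.DataFrame:
    """Published 54-indicator five-factor loading matrices from the
    large-scale field study (N = 50,209), transcribed from the printed
    report: ``branch`` is 'corrected' (acquiescence-corrected scores) or
    'raw'. Rows are in blueprint indicator order with labels
    ``facet/framing``; columns are domain codes O, C, E, A, N.

    The raw branch is kept exactly as printed — including a sign-reversed
    fourth factor — because the published congruence table was evidently
    computed on the printed columns without re-alignment.
    """
    if branch not in ("corrected", "raw"):
        raise ValueError("branch must be 'corrected' or 'raw'")
    df = pd.read_csv(_REFERENCE_PATH)
    labels = df["facet"] + "/" + df["framing"]
    cols = [f"{branch}_{c}" for c in ("O", "C", "E", "A", "N")]
    out = df[cols].copy()
    out.columns = ["O", "C", "E", "A", "N"]
    out.index = pd.Index(labels, name="indicator")
    return out
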