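"""Synthetic Likert responses with known five-factor structure.

Generative model (content first, response style second):

1. Domain scores ``theta_i ~ MVN(0, Phi)`` with ``Phi`` a unit-diagonal
   correlation matrix over the five domains.
2. Facet scores ``f = gamma * theta_domain + sqrt(1 - gamma^2) * u`` with
   ``u`` standard normal, so ``corr(f, theta) = gamma``.
3. Latent item value ``y_ij = key_j * (lambda_j * f_i + sum secondary) + eps``
   with ``eps`` scaled so ``var(y) = 1``. Secondary loadings attach extra
   domain content to selected items, emulating theoretically expected
   cross-loadings (non-simple structure).
4. Acquiescence enters BEFORE keying is undone and blind to content:
   ``z = y + a_i`` with ``a_i ~ N(acq_mean - midpoint, acq_sd)`` — an
   individual shift of the whole response scale.
5. ``response = discretize(z, thresholds)`` maps the latent value to 1..5
   through four increasing cut-points (half-open: a value exactly on a
   cut-point falls in the upper category).
6. A fraction ``ier_rate`` of respondents answer uniformly at random on
   {1..5} (insufficient-effort responding); missingness is completely at
   random at ``missing_rate``.

The additive-shift-then-threshold response process is a stated modeling
assumption: field data give no direct access to the latent response scale.
Because categories are bounded, the observable acquiescence index is a
slightly attenuated, mildly nonlinear image of the latent shift; tests bound
this attenuation empirically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .blueprint import InstrumentBlueprint, build_default_blueprint

SCALE_MIDPOINT = 3.0

#: Default cross-loading table: (facet, framing-or-None for all, domain, value).
#: Mirrors the secondary loadings reported for the field instrument
#: (responsibility is the interpersonal side of self-management -> Amity;
#: self-confidence reaches toward others -> Engaging; the enthusiasm and
#: respect self-efficacy items tap emotion regulation -> N).
DEFAULT_SECONDARY = (
    ("responsibility", None, "A", 0.25),
    ("self_confidence", None, "E", 0.25),
    ("enthusiasm", "self_efficacy", "N", 0.25),
    ("respect", "self_efficacy", "N", 0.25),
)


def _default_phi() -> np.ndarray:
    phi = np.full((5, 5), 0.3)
    np.fill_diagonal(phi, 1.0)
    return phi


@dataclass
class SimulationConfig:
    """Study-condition parameters for the generator.

    Defaults are calibrated to the field study the generator stands in for:
    an acquiescence index with mean about 2.95 and SD about 0.37 on the 1-5
    response scale, moderate positive domain intercorrelations, strong
    facet-domain links, and a small minority of careless responders.
    """

    n: int = 1000
    seed: int = 0
    factor_correlations: np.ndarray = field(default_factory=_default_phi)
    facet_domain_loading: float = 0.8  # gamma
    item_loading: float = 0.7  # lambda
    secondary_loadings: tuple = DEFAULT_SECONDARY
    acq_mean: float = 2.95  # on the response scale
    acq_sd: float = 0.37
    thresholds: tuple = (-1.5, -0.5, 0.5, 1.5)  # latent scale, centered
    ier_rate: float = 0.05
    missing_rate: float = 0.0

    def validate(self) -> None:
        if self.n <= 0:
            raise ValueError(f"n must be positive (got {self.n})")
        t = np.asarray(self.thresholds, float)
        if t.ndim != 1 or len(t) != 4 or np.any(np.diff(t) <= 0):
            raise ValueError("thresholds must be 4 strictly increasing cut-points")
        phi = np.asarray(self.factor_correlations, float)
        if phi.shape != (5, 5) or not np.allclose(phi, phi.T):
            raise ValueError("factor_correlations must be a symmetric 5x5 matrix")
        if not np.allclose(np.diag(phi), 1.0):
            raise ValueError("factor_correlations must have unit diagonal")
        if np.linalg.eigvalsh(phi).min() < -1e-10:
            raise ValueError("factor_correlations must be positive semidefinite")
        if not (0 < self.facet_domain_loading <= 1):
            raise ValueError("facet_domain_loading must be in (0, 1]")
        if not (0 < self.item_loading <= 1):
            raise ValueError("item_loading must be in (0, 1]")
        if not (0 <= self.ier_rate < 1):
            raise ValueError("ier_rate must be in [0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class TrueParams:
    """Latent truth written beside every simulated response matrix."""

    theta: pd.DataFrame  # n x 5 domain scores
    facet_scores: pd.DataFrame  # n x 18
    acq_true: pd.Series  # latent shift, response-scale units, centered at 0
    ier_flags: pd.Series  # True for uniform random responders
    population_loadings: pd.DataFrame  # 162 x 5, signed by key


def discretize(z, thresholds=(-1.5, -0.5, 0.5, 1.5)):
    """Map latent values to 1..5 categories through 4 increasing cut-points.

    Half-open convention: ``z`` exactly equal to a cut-point falls in the
    upper category. Monotone non-decreasing in ``z``.
    """
    t = np.asarray(thresholds, float)
    if t.ndim != 1 or len(t) != 4 or np.any(np.diff(t) <= 0):
        raise ValueError("thresholds must be 4 strictly increasing cut-points")
    return np.searchsorted(t, np.asarray(z, float), side="right") + 1


def population_loadings(
    bp: InstrumentBlueprint, config: SimulationConfig
) -> pd.DataFrame:
    """Population item-domain loading matrix Lambda (162 x 5, signed by key).

    Primary loading of item j on its facet's domain is
    ``key_j * lambda * gamma``; secondary entries are ``key_j * value``.
    """
    lam = np.zeros((len(bp.items), len(bp.domain_codes)))
    dcol = {c: i for i, c in enumerate(bp.domain_codes)}
    for r, it in enumerate(bp.items):
        dom = bp.facet_domain(it.facet)
        lam[r, dcol[dom]] = it.key * config.item_loading * config.facet_domain_loading
        for facet, framing, sdom, val in config.secondary_loadings:
            if it.facet == facet and (framing is None or it.framing == framing):
                lam[r, dcol[sdom]] += it.key * val
    return pd.DataFrame(lam, index=list(bp.item_ids), columns=list(bp.domain_codes))


def simulate(
    config: SimulationConfig, bp: InstrumentBlueprint | None = None
) -> tuple[TrueParams, pd.DataFrame]:
    """Draw a response matrix and its latent truth under ``config``.

    Returns ``(truth, responses)`` where ``responses`` is an n x 162 integer
    DataFrame (1-5, NaN for missing) indexed by respondent_id.
    """
    config.validate()
    if bp is None:
        bp = build_default_blueprint()
    rng = np.random.default_rng(config.seed)
    n = config.n
    phi = np.asarray(config.factor_correlations, float)
    gamma = config.facet_domain_loading
    lam = config.item_loading

    facet_ids = [f.facet_id for f in bp.facets]
    dcol = {c: i for i, c in enumerate(bp.domain_codes)}
    fcol = {f: i for i, f in enumerate(facet_ids)}

    theta = rng.multivariate_normal(np.zeros(5), phi, size=n, method="cholesky")
    facet_dom_idx = np.array([dcol[f.domain] for f in bp.facets])
    u = rng.standard_normal((n, len(facet_ids)))
    facets = gamma * theta[:, facet_dom_idx] + np.sqrt(1 - gamma**2) * u

    # per-item content: lambda * facet + secondary domain terms
    k = len(bp.items)
    content = np.zeros((n, k))
    content_var = np.zeros(k)
    sec_map: dict[int, list[tuple[int, float]]] = {}
    for r, it in enumerate(bp.items):
        sec = []
        for facet, framing, sdom, val in config.secondary_loadings:
            if it.facet == facet and (framing is None or it.framing == framing):
                sec.append((dcol[sdom], val))
        sec_map[r] = sec
        fi = fcol[it.facet]
        c = lam * facets[:, fi]
        var = lam**2
        dom_i = facet_dom_idx[fi]
        for sd, val in sec:
            c = c + val * theta[:, sd]
            # var contributions: val^2 + 2*lam*val*cov(facet, theta_sd)
            var += val**2 + 2 * lam * val * gamma * phi[dom_i, sd]
        content[:, r] = c
        content_var[r] = var

    eps_sd = np.sqrt(np.clip(1.0 - content_var, 0.05, None))
    keys = np.array([it.key for it in bp.items], float)
    y = keys * content + eps_sd * rng.standard_normal((n, k))

    acq_shift = rng.normal(config.acq_mean - SCALE_MIDPOINT, config.acq_sd, size=n)
    z = y + acq_shift[:, None]
    resp = discretize(z, config.thresholds).astype(float)

    ier = rng.random(n) < config.ier_rate
    if ier.any():
        resp[ier] = rng.integers(1, 6, size=(ier.sum(), k)).astype(float)
    if config.missing_rate > 0:
        resp[rng.random((n, k)) < config.missing_rate] = np.nan

    ids = [f"r{i:06d}" for i in range(n)]
    responses = pd.DataFrame(resp, index=pd.Index(ids, name="respondent_id"),
                             columns=list(bp.item_ids))
    truth = TrueParams(
        theta=pd.DataFrame(theta, index=responses.index,
                           columns=list(bp.domain_codes)),
        facet_scores=pd.DataFrame(facets, index=responses.index, columns=facet_ids),
        acq_true=pd.Series(acq_shift, index=responses.index, name="acq_true"),
        ier_flags=pd.Series(ier, index=responses.index, name="ier"),
        population_loadings=population_loadings(bp, config),
    )
    return truth, responses


def population_indicator_correlation(
    bp: InstrumentBlueprint, config: SimulationConfig, scheme: str = "triplet54"
) -> tuple[np.ndarray, pd.DataFrame]:
    """Exact population correlation matrix of the key-oriented cluster
    indicators implied by ``config`` (no sampling, no discretization, no
    acquiescence), together with the indicator-level population loadings.

    Used by structure-recovery tests as a noise-free oracle.
    """
    from .scoring import scheme_groups  # local import to avoid a cycle

    phi = np.asarray(config.factor_correlations, float)
    gamma = config.facet_domain_loading
    lam_pop = population_loadings(bp, config)
    dcol = {c: i for i, c in enumerate(bp.domain_codes)}
    groups = scheme_groups(bp, scheme)

    labels = [g[0] for g in groups]
    m = len(labels)
    # indicator value = mean over items of key*y; on the latent (pre-threshold)
    # scale each key-oriented item = content + key*eps with content
    # lam*facet + secondaries. Indicator loading vector on (theta_1..theta_5)
    # after integrating out facet residual:
    load = np.zeros((m, 5))
    resid = np.zeros(m)  # variance not explained by theta
    lam = config.item_loading
    for gi, (label, item_ids) in enumerate(groups):
        items = [bp.item(i) for i in item_ids]
        p = len(items)
        facet_of = {it.facet for it in items}
        # accumulate E[val | theta] coefficients and residual variance
        coef = np.zeros(5)
        var_resid = 0.0
        # facet residual sqrt(1-g^2)u is shared within a facet
        facet_u_coef: dict[str, float] = {}
        for it in items:
            dom_i = dcol[bp.facet_domain(it.facet)]
            coef[dom_i] += lam * gamma / p
            facet_u_coef[it.facet] = facet_u_coef.get(it.facet, 0.0) + lam * np.sqrt(
                1 - gamma**2
            ) / p
            for facet, framing, sdom, val in config.secondary_loadings:
                if it.facet == facet and (framing is None or it.framing == framing):
                    coef[dcol[sdom]] += val / p
            # item unique part
            c_var = lam**2
            for facet, framing, sdom, val in config.secondary_loadings:
                if it.facet == facet and (framing is None or it.framing == framing):
                    c_var += val**2 + 2 * lam * val * gamma * phi[dom_i, dcol[sdom]]
            var_resid += max(1.0 - c_var, 0.05) / p**2
        var_resid += sum(v**2 for v in facet_u_coef.values())
        load[gi] = coef
        resid[gi] = var_resid
    cov = load @ phi @ load.T + np.diag(resid)
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    ind_load = pd.DataFrame(load / d[:, None], index=labels,
                            columns=list(bp.domain_codes))
    return corr, ind_load


# ---------------------------------------------------------------------------
# flat key=value config files

def config_to_text(config: SimulationConfig) -> str:
    lines = []
    for k, v in asdict(config).items():
        if k == "factor_correlations":
            v = ",".join(f"{x:g}" for x in np.asarray(v).ravel())
        elif k == "secondary_loadings":
            v = ";".join(
                f"{f}:{fr or '*'}:{d}:{val:g}" for f, fr, d, val in v
            )
        elif k == "thresholds":
            v = ",".join(f"{x:g}" for x in v)
        lines.append(f"{k}={v}")
    return "\n".join(lines) + "\n"


def config_from_text(text: str) -> SimulationConfig:
    kv = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        kv[key.strip()] = val.strip()
    cfg = SimulationConfig()
    for key, val in kv.items():
        if key in ("n", "seed"):
            setattr(cfg, key, int(val))
        elif key in ("facet_domain_loading", "item_loading", "acq_mean",
                     "acq_sd", "ier_rate", "missing_rate"):
            setattr(cfg, key, float(val))
        elif key == "thresholds":
            cfg.thresholds = tuple(float(x) for x in val.split(","))
        elif key == "factor_correlations":
            cfg.factor_correlations = np.array(
                [float(x) for x in val.split(",")]
            ).reshape(5, 5)
        elif key == "secondary_loadings":
            entries = []
            if val:
                for part in val.split(";"):
                    f, fr, d, v = part.split(":")
                    entries.append((f, None if fr == "*" else fr, d, float(v)))
            cfg.secondary_loadings = tuple(entries)
        else:
            raise ValueError(f"unknown config key {key!r}")
    return cfg


def write_simulation(truth: TrueParams, responses: pd.DataFrame,
                     out: Path, truth_path: Path) -> None:
    """Responses CSV (wide) and truth CSV side by side, deterministically."""
    responses.to_csv(out)
    tdf = pd.concat(
        [truth.theta.add_prefix("theta_"), truth.facet_scores.add_prefix("facet_"),
         truth.acq_true, truth.ier_flags], axis=1
    )
    tdf.to_csv(truth_path)
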