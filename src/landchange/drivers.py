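"""Multinomial transition-risk modelling with subsample replication.

For each source category (forest, shrubland, agriculture/developed) a
three-outcome multinomial logit is fit with "stay" as the baseline outcome.
To blunt spatial autocorrelation the model is refit on repeated random 10%
subsamples; coefficient means, percentile confidence intervals and relative
risk ratios (exp of coefficients) are reported over the replicates.

Continuous covariates are z-scored on the full observation set (so all
replicates and any truth coefficients share one scale); categorical
covariates are one-hot encoded against their first level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .change import category_code
from .grids import CovariateStack, LandCoverGrid, assert_aligned
from .synthetic import ALT_OUTCOMES

__all__ = [
    "TransitionObservations",
    "DesignInfo",
    "TransitionModelFit",
    "assemble_observations",
    "build_design",
    "fit_multinomial",
    "fit_subsampled",
    "relative_risk_ratios",
    "predict_transition_probabilities",
]


@dataclass
class TransitionObservations:
    """One record per source-category cell valid in both epochs."""

    source: str
    outcome_names: tuple[str, str, str]  # (stay, alt1, alt2)
    outcome: np.ndarray  # 0 = stay, 1 = alt1, 2 = alt2
    table: dict[str, np.ndarray]  # covariate name -> per-record values
    categorical: frozenset[str]
    rows: np.ndarray
    cols: np.ndarray
    n_excluded: int = 0

    @property
    def n(self) -> int:
        return self.outcome.shape[0]


@dataclass
class DesignInfo:
    """Frozen encoding of the design matrix so replicates and prediction
    share the same columns and scaling."""

    column_names: tuple[str, ...]  # includes leading 'intercept'
    layer_order: tuple[str, ...]  # source layers in encoding order
    continuous_stats: dict[str, tuple[float, float]]
    categorical_levels: dict[str, tuple]


@dataclass
class TransitionModelFit:
    source: str
    outcome_names: tuple[str, str, str]
    design: DesignInfo
    replicates: np.ndarray  # (n_ok, 2, p) coefficient stacks
    mean_coefficients: np.ndarray  # (2, p)
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_replicates: int
    n_failed: int
    subsample_fraction: float
    seed: int
    loglike: float | None = None

    @property
    def rrr(self) -> np.ndarray:
        return np.exp(self.mean_coefficients)

    def coefficient_frame(self) -> pd.DataFrame:
        rows = []
        for k, alt in enumerate(self.outcome_names[1:]):
            for j, name in enumerate(self.design.column_names):
                rows.append(
                    {
                        "outcome": f"{self.outcome_names[0]}_to_{alt}",
                        "covariate": name,
                        "mean": self.mean_coefficients[k, j],
                        "ci_low": self.ci_low[k, j],
                        "ci_high": self.ci_high[k, j],
                    }
                )
        return pd.DataFrame(rows)


def assemble_observations(
    epoch1_cat: LandCoverGrid,
    epoch2_cat: LandCoverGrid,
    covariates: CovariateStack,
    source: str,
    covariate_names: tuple[str, ...] | None = None,
) -> TransitionObservations:
    """Extract per-cell outcome and covariates for one source category.

    Cells transitioning to categories outside the 3-outcome space (alpine,
    other) are excluded; their count is recorded.
    """
    if source not in ALT_OUTCOMES:
        raise ValueError(f"unsupported source category {source!r}")
    check = assert_aligned([epoch1_cat, epoch2_cat, covariates])
    if not check:
        raise ValueError(f"misaligned inputs: {check.message}")
    names = tuple(covariate_names) if covariate_names else covariates.names
    missing = set(names) - set(covariates.names)
    if missing:
        raise ValueError(f"missing covariate layers: {sorted(missing)}")

    alt1, alt2 = ALT_OUTCOMES[source]
    code = {cat: category_code(cat) for cat in (source, alt1, alt2)}
    valid = epoch1_cat.valid_mask & epoch2_cat.valid_mask
    src_mask = valid & (epoch1_cat.values == code[source])
    if not src_mask.any():
        raise ValueError(f"no {source} cells valid in both epochs")
    to = epoch2_cat.values[src_mask]
    outcome = np.full(to.shape, -1, dtype=np.int64)
    outcome[to == code[source]] = 0
    outcome[to == code[alt1]] = 1
    outcome[to == code[alt2]] = 2
    keep = outcome >= 0
    rows, cols = np.nonzero(src_mask)
    rows, cols, outcome = rows[keep], cols[keep], outcome[keep]
    table = {n: np.asarray(covariates.layers[n], dtype=float)[rows, cols] for n in names}
    bad = ~np.isfinite(np.column_stack(list(table.values()))).all(axis=1)
    if bad.any():
        rows, cols, outcome = rows[~bad], cols[~bad], outcome[~bad]
        table = {n: v[~bad] for n, v in table.items()}
    return TransitionObservations(
        source=source,
        outcome_names=(source, alt1, alt2),
        outcome=outcome,
        table=table,
        categorical=covariates.categorical & set(names),
        rows=rows,
        cols=cols,
        n_excluded=int((~keep).sum()),
    )


def build_design(
    table: dict[str, np.ndarray],
    categorical: frozenset[str],
    info: DesignInfo | None = None,
    n: int | None = None,
) -> tuple[np.ndarray, DesignInfo]:
    """Design matrix with intercept; z-scored continuous, one-hot categorical.

    Pass a previous :class:`DesignInfo` to re-encode new data identically.
    An empty *table* (with *n* given) yields an intercept-only design.
    """
    if table:
        n = len(next(iter(table.values())))
    elif n is None:
        raise ValueError("n required for an intercept-only design")
    columns = [np.ones(n)]
    names = ["intercept"]
    cont_stats: dict[str, tuple[float, float]] = {}
    cat_levels: dict[str, tuple] = {}
    layer_order = info.layer_order if info is not None else tuple(table)
    kept_order = []
    for name in layer_order:
        values = table[name]
        if name in categorical:
            if info is not None:
                levels = info.categorical_levels[name]
            else:
                levels = tuple(np.unique(values))
                if len(levels) < 2:  # single level carries no information
                    continue
            cat_levels[name] = levels
            kept_order.append(name)
            for lev in levels[1:]:  # first level is the reference
                columns.append((values == lev).astype(float))
                names.append(f"{name}[{lev:g}]" if isinstance(lev, float) else f"{name}[{lev}]")
        else:
            if info is not None:
                mean, sd = info.continuous_stats[name]
            else:
                mean, sd = float(values.mean()), float(values.std())
                if sd == 0:  # constant layer: no information, would be collinear
                    continue
            cont_stats[name] = (mean, sd)
            kept_order.append(name)
            columns.append((values - mean) / sd)
            names.append(name)
    out_info = info or DesignInfo(
        column_names=tuple(names),
        layer_order=tuple(kept_order),
        continuous_stats=cont_stats,
        categorical_levels=cat_levels,
    )
    return np.column_stack(columns), out_info


def _fit_once(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray | None, float | None]:
    """Single MNLogit fit; returns (coef (2, p), loglike) or (None, None)."""
    if np.unique(y).size < 3:
        return None, None  # a replicate can miss an outcome level entirely
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.MNLogit(y, X).fit(method="newton", maxiter=200, disp=0)
        except Exception:
            return None, None
    if not res.mle_retvals.get("converged", False):
        return None, None
    return np.asarray(res.params).T, float(res.llf)  # (2, p): rows alt1, alt2


def fit_multinomial(
    obs: TransitionObservations, covariate_names: tuple[str, ...] | None = None
) -> TransitionModelFit:
    """Maximum-likelihood fit on the full observation set (no subsampling)."""
    table = obs.table if covariate_names is None else {n: obs.table[n] for n in covariate_names}
    X, info = build_design(table, obs.categorical, n=obs.n)
    coef, llf = _fit_once(obs.outcome, X)
    if coef is None:
        raise RuntimeError("multinomial fit failed to converge (possible separation)")
    return TransitionModelFit(
        source=obs.source,
        outcome_names=obs.outcome_names,
        design=info,
        replicates=coef[None, ...],
        mean_coefficients=coef,
        ci_low=coef.copy(),
        ci_high=coef.copy(),
        n_replicates=1,
        n_failed=0,
        subsample_fraction=1.0,
        seed=0,
        loglike=llf,
    )


def fit_subsampled(
    obs: TransitionObservations,
    fraction: float = 0.10,
    replicates: int = 1000,
    seed: int = 0,
    covariate_names: tuple[str, ...] | None = None,
) -> TransitionModelFit:
    """Repeated fits on random subsamples drawn without replacement.

    Reports the elementwise mean and the 2.5/97.5 percentile band over the
    replicate coefficient estimates.  Non-convergent replicates are dropped
    and counted.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    table = obs.table if covariate_names is None else {n: obs.table[n] for n in covariate_names}
    X, info = build_design(table, obs.categorical, n=obs.n)
    n_sub = max(int(np.floor(fraction * obs.n)), len(info.column_names) + 3)
    n_sub = min(n_sub, obs.n)
    rng = np.random.default_rng(seed)
    kept: list[np.ndarray] = []
    lls: list[float] = []
    n_failed = 0
    for _ in range(replicates):
        idx = rng.choice(obs.n, size=n_sub, replace=False)
        coef, llf = _fit_once(obs.outcome[idx], X[idx])
        if coef is None:
            n_failed += 1
        else:
            kept.append(coef)
            lls.append(llf)
    if not kept:
        raise RuntimeError("all replicates failed to converge")
    if n_failed:
        warnings.warn(f"{n_failed}/{replicates} replicates failed to converge", stacklevel=2)
    stack = np.stack(kept)
    return TransitionModelFit(
        source=obs.source,
        outcome_names=obs.outcome_names,
        design=info,
        replicates=stack,
        mean_coefficients=stack.mean(axis=0),
        ci_low=np.percentile(stack, 2.5, axis=0),
        ci_high=np.percentile(stack, 97.5, axis=0),
        n_replicates=replicates,
        n_failed=n_failed,
        subsample_fraction=fraction,
        seed=seed,
        loglike=float(np.mean(lls)),
    )


def relative_risk_ratios(fit: TransitionModelFit) -> pd.DataFrame:
    """RRR table: exp of mean coefficients and of the CI bounds (no refit)."""
    frame = fit.coefficient_frame()
    frame["rrr"] = np.exp(frame["mean"])
    frame["rrr_low"] = np.exp(frame["ci_low"])
    frame["rrr_high"] = np.exp(frame["ci_high"])
    return frame


def predict_transition_probabilities(
    fit: TransitionModelFit, covariates: CovariateStack, source_mask: np.ndarray
) -> np.ndarray:
    """(3, rows, cols) softmax probabilities (stay, alt1, alt2) on source
    cells using the mean coefficients; NaN elsewhere."""
    source_mask = np.asarray(source_mask, dtype=bool)
    rows, cols = np.nonzero(source_mask)
    missing = set(fit.design.layer_order) - set(covariates.names)
    if missing:
        raise ValueError(f"missing covariate layers: {sorted(missing)}")
    table = {
        n: np.asarray(covariates.layers[n], dtype=float)[rows, cols]
        for n in fit.design.layer_order
    }
    X, _ = build_design(table, frozenset(fit.design.categorical_levels), info=fit.design,
                        n=rows.size)
    eta = X @ fit.mean_coefficients.T  # (n, 2)
    full = np.column_stack([np.zeros(eta.shape[0]), eta])
    full -= full.max(axis=1, keepdims=True)
    p = np.exp(full)
    p /= p.sum(axis=1, keepdims=True)
    out = np.full((3,) + source_mask.shape, np.nan)
    for k in range(3):
        out[k, rows, cols] = p[:, k]
    return out
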