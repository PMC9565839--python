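"""Exploratory factor analysis of pattern-cluster frequency histograms.

Principal-axis factoring with iterated communalities on the standardized
subjects x clusters matrix, varimax rotation (orthogonal, the default)
or promax, Thomson regression factor scores, salient-loading factor
association sets with bi-polarity flags, and the factor-vs-variable
correlation table (Pearson for continuous variables, point-biserial for
binary ones, entries with p >= 0.05 masked in the reported table).

A factor is *bi-polar* when it carries salient loadings of both signs:
its positive and negative pattern-cluster sets describe two opposite
tissue configurations contributing to the same latent trait.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.multivariate.factor_rotation import rotate_factors

__all__ = [
    "FactorModel",
    "fit_efa",
    "score_subjects",
    "factor_associations",
    "factor_variable_correlations",
    "parallel_analysis",
]

SALIENT_LOADING = 0.4


@dataclass
class FactorModel:
    loadings: np.ndarray              # columns-kept x k
    communalities: np.ndarray
    scores: np.ndarray                # subjects x k
    rotation: str
    n_factors: int
    columns: list[str]                # kept (non-constant) column names
    dropped_columns: list[str]
    col_means: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    col_sds: np.ndarray = field(repr=False, default=None)    # type: ignore[assignment]
    corr: np.ndarray = field(repr=False, default=None)       # type: ignore[assignment]
    n_iter: int = 0
    converged: bool = True

    def loadings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.loadings, index=self.columns,
            columns=[f"F{i}" for i in range(self.n_factors)],
        )


def _principal_axis(corr: np.ndarray, k: int, tol: float = 1e-4,
                    max_iter: int = 200) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """Iterated principal-axis factoring: start from squared multiple
    correlations, eigendecompose the reduced correlation matrix, update
    communalities until stable."""
    p = corr.shape[0]
    try:
        inv = np.linalg.inv(corr)
        h2 = 1.0 - 1.0 / np.diag(inv)          # SMC start
    except np.linalg.LinAlgError:
        h2 = np.full(p, 0.5)
    h2 = np.clip(h2, 0.0, 0.999)
    converged = False
    it = 0
    loadings = np.zeros((p, k))
    for it in range(1, max_iter + 1):
        reduced = corr.copy()
        np.fill_diagonal(reduced, h2)
        vals, vecs = np.linalg.eigh(reduced)
        idx = np.argsort(vals)[::-1][:k]
        lam = np.clip(vals[idx], 0.0, None)
        loadings = vecs[:, idx] * np.sqrt(lam)
        h2_new = np.clip((loadings ** 2).sum(axis=1), 0.0, 0.999)
        if np.max(np.abs(h2_new - h2)) < tol:
            h2 = h2_new
            converged = True
            break
        h2 = h2_new
    return loadings, h2, it, converged


def parallel_analysis(n_subjects: int, n_columns: int, n_reps: int = 50,
                      quantile: float = 0.95, seed: int = 0,
                      observed_eigs: np.ndarray | None = None) -> np.ndarray | int:
    """Horn-style parallel analysis: eigenvalue thresholds from
    correlation matrices of seeded standard-normal data of the same
    shape.  With ``observed_eigs`` given, returns the retained factor
    count; otherwise the threshold vector."""
    rng = np.random.default_rng(seed)
    eigs = np.empty((n_reps, n_columns))
    for r in range(n_reps):
        z = rng.standard_normal((n_subjects, n_columns))
        eigs[r] = np.sort(np.linalg.eigvalsh(np.corrcoef(z, rowvar=False)))[::-1]
    thresh = np.quantile(eigs, quantile, axis=0)
    if observed_eigs is None:
        return thresh
    return int(np.sum(observed_eigs > thresh))


def fit_efa(
    histograms: pd.DataFrame | np.ndarray,
    n_factors: int | str = "auto",
    rotation: str = "varimax",
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> FactorModel:
    """Fit the factor model to a subjects x clusters frequency matrix.

    Columns are standardized; zero-variance columns are dropped (and
    logged on the model).  ``n_factors="auto"`` retains factors by
    seeded parallel analysis.
    """
    if isinstance(histograms, pd.DataFrame):
        names = list(histograms.columns)
        x = histograms.to_numpy(dtype=float)
    else:
        x = np.asarray(histograms, dtype=float)
        names = [f"pc{i}" for i in range(x.shape[1])]
    n, p = x.shape
    sds = x.std(axis=0, ddof=1)
    keep = sds > 1e-12
    dropped = [names[i] for i in range(p) if not keep[i]]
    if dropped:
        warnings.warn(f"dropping zero-variance columns: {dropped}")
    x = x[:, keep]
    names = [nm for nm, k in zip(names, keep) if k]
    means, sds = x.mean(axis=0), x.std(axis=0, ddof=1)
    z = (x - means) / sds
    corr = np.corrcoef(z, rowvar=False)

    if n_factors == "auto":
        eigs = np.sort(np.linalg.eigvalsh(corr))[::-1]
        k = max(parallel_analysis(n, z.shape[1], seed=seed, observed_eigs=eigs), 1)
    else:
        k = int(n_factors)
    if k >= z.shape[1]:
        raise ValueError(f"n_factors={k} must be < number of usable columns {z.shape[1]}")
    if n <= k:
        raise ValueError("need more subjects than factors")

    loadings, h2, n_iter, converged = _principal_axis(corr, k, tol=tol, max_iter=max_iter)
    if not converged:
        warnings.warn(f"principal-axis iteration did not converge in {max_iter} steps")
    if k > 1:
        if rotation == "varimax":
            loadings, _ = rotate_factors(loadings, "varimax")
        elif rotation == "promax":
            loadings, _ = rotate_factors(loadings, "promax")
        elif rotation not in ("none", None):
            raise ValueError(f"unknown rotation {rotation!r}")
    # orient each factor so its largest-magnitude loading is positive
    for j in range(k):
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] *= -1.0

    model = FactorModel(
        loadings=loadings, communalities=(loadings ** 2).sum(axis=1),
        scores=None, rotation=rotation, n_factors=k, columns=names,
        dropped_columns=dropped, col_means=means, col_sds=sds, corr=corr,
        n_iter=n_iter, converged=converged,
    )
    model.scores = score_subjects(model, pd.DataFrame(x, columns=names))
    return model


def score_subjects(model: FactorModel, histograms: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Thomson regression factor scores, S = Z R^-1 L; zero mean per
    factor over the fitting sample by construction."""
    if isinstance(histograms, pd.DataFrame):
        if list(histograms.columns) != model.columns:
            raise ValueError("histogram columns do not match the fitted model")
        x = histograms.to_numpy(dtype=float)
    else:
        x = np.asarray(histograms, dtype=float)
        if x.shape[1] != len(model.columns):
            raise ValueError("column count does not match the fitted model")
    z = (x - model.col_means) / model.col_sds
    # pinv: frequency histograms are compositional (rows sum to 1), so
    # the correlation matrix can be exactly singular
    weights = np.linalg.pinv(model.corr) @ model.loadings
    return z @ weights


def factor_associations(model: FactorModel, threshold: float = SALIENT_LOADING) -> pd.DataFrame:
    """Salient pattern clusters per factor: positive set (loading >=
    threshold), negative set (<= -threshold), bi-polar when both are
    non-empty."""
    rows = []
    for j in range(model.n_factors):
        col = model.loadings[:, j]
        pos = [model.columns[i] for i in np.flatnonzero(col >= threshold)]
        neg = [model.columns[i] for i in np.flatnonzero(col <= -threshold)]
        rows.append(
            {
                "factor": f"F{j}",
                "positive": pos,
                "negative": neg,
                "bipolar": bool(pos and neg),
                "empty": not (pos or neg),
            }
        )
    return pd.DataFrame(rows).set_index("factor")


def factor_variable_correlations(
    scores: np.ndarray,
    variables: pd.DataFrame,
    binary: set[str] | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlate factor scores with clinical/imaging variables.

    Pearson for continuous variables, point-biserial for those named in
    ``binary``.  Returns ``(full, masked)`` tables of correlations with
    p-values; in ``masked``, entries with p >= alpha (or undefined, e.g.
    a constant variable) are NaN.
    """
    binary = binary or set()
    scores = np.asarray(scores, dtype=float)
    k = scores.shape[1]
    if len(variables) != len(scores):
        raise ValueError("variables and scores must have equal row counts")
    full_rows, mask_rows = [], []
    for var in variables.columns:
        v = variables[var].to_numpy(dtype=float)
        ok = np.isfinite(v)
        full, maskd = {}, {}
        for j in range(k):
            s = scores[ok, j]
            vv = v[ok]
            if ok.sum() < 3 or np.std(vv) == 0 or np.std(s) == 0:
                r, pval = np.nan, np.nan
            elif var in binary:
                r, pval = sps.pointbiserialr(vv, s)
            else:
                r, pval = sps.pearsonr(vv, s)
            full[f"F{j}_r"] = r
            full[f"F{j}_p"] = pval
            maskd[f"F{j}"] = r if (np.isfinite(pval) and pval < alpha) else np.nan
        full_rows.append(pd.Series(full, name=var))
        mask_rows.append(pd.Series(maskd, name=var))
    return pd.DataFrame(full_rows), pd.DataFrame(mask_rows)
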