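"""Source apportionment support: correlation screening and PCA.

Pearson correlations with two-sided significance stars flag element pairs
that accumulate together; principal component analysis of the standardized
concentration matrix (eigen-decomposition of the correlation matrix)
summarizes that joint structure into a few factors whose variance
contributions and loadings are the quantitative basis for source
interpretation.  Attaching source names to components is deliberately left
to the analyst.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .registry import ValidationError
from .samples import SampleSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation matrix with significance annotations."""

    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame          # "**" p<0.01, "*" p<0.05, "" otherwise
    p_holm: pd.DataFrame         # Holm-corrected p-values (upper info only)

    def annotated(self) -> pd.DataFrame:
        """Correlation coefficients with stars, as strings (survey-table style)."""
        return pd.DataFrame(
            np.where(
                np.isnan(self.r), "",
                np.char.add(
                    np.round(self.r.to_numpy().astype(float), 3).astype(str),
                    self.stars.to_numpy().astype(str),
                ),
            ),
            index=self.r.index, columns=self.r.columns,
        )


def pearson_matrix(samples: SampleSet) -> CorrelationResult:
    """Pairwise Pearson correlations with t-test p-values (n-2 df, two-sided).

    Constant columns have undefined correlation; their entries are NaN and a
    warning is emitted.  No multiple-testing correction is applied to the
    star annotations (the conventional survey-table display); a
    Holm-corrected matrix is returned alongside.
    """
    conc = samples.concentrations
    n = len(conc)
    if n < 3:
        raise ValidationError("pearson_matrix needs at least 3 samples")
    elements = list(conc.columns)
    constant = [e for e in elements if conc[e].nunique() == 1]
    if constant:
        logger.warning("constant columns, correlation undefined: %s", constant)

    r = conc.corr(method="pearson")  # NaN for constant columns
    rv = r.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rv * np.sqrt((n - 2) / (1.0 - rv**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(rv), 1.0), 0.0, p)
    np.fill_diagonal(p, 0.0)
    p = pd.DataFrame(p, index=elements, columns=elements)

    stars = p.map(lambda q: "**" if q < 0.01 else ("*" if q < 0.05 else ""))
    for e in elements:
        stars.loc[e, e] = ""

    iu = np.triu_indices(len(elements), k=1)
    raw = p.to_numpy()[iu]
    order = np.argsort(raw)
    m = raw.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * raw[idx])
        adj[idx] = min(1.0, running)
    holm = np.zeros_like(p.to_numpy())
    holm[iu] = adj
    holm = holm + holm.T
    p_holm = pd.DataFrame(holm, index=elements, columns=elements)

    return CorrelationResult(r=r, p=p, stars=stars, p_holm=p_holm)


@dataclass(frozen=True)
class PcaResult:
    """PCA of the standardized concentration matrix."""

    loadings: pd.DataFrame               # element x retained component
    eigenvalues: np.ndarray              # all components, descending
    variance_contribution: np.ndarray    # percent, all components
    cumulative_contribution: np.ndarray  # running sum, percent
    n_retained: int

    @property
    def retained_contribution(self) -> float:
        """Cumulative variance contribution (%) of the retained components."""
        return float(self.cumulative_contribution[self.n_retained - 1])

    def table(self) -> pd.DataFrame:
        """Loadings with contribution rows appended (survey-table layout)."""
        out = self.loadings.copy()
        out.loc["Variance contribution/%"] = self.variance_contribution[: self.n_retained]
        out.loc["Cumulative variance contribution/%"] = self.cumulative_contribution[
            : self.n_retained
        ]
        return out


def _varimax(loadings: np.ndarray, tol: float = 1e-8, max_iter: int = 200) -> np.ndarray:
    """Varimax rotation of a loadings matrix (Kaiser row normalization off)."""
    p, k = loadings.shape
    rotation = np.eye(k)
    var = 0.0
    for _ in range(max_iter):
        rotated = loadings @ rotation
        u, s, vt = np.linalg.svd(
            loadings.T
            @ (rotated**3 - rotated @ np.diag(np.sum(rotated**2, axis=0)) / p)
        )
        rotation = u @ vt
        new_var = s.sum()
        if new_var <= var * (1 + tol):
            break
        var = new_var
    return loadings @ rotation


def pca(
    samples: SampleSet,
    retention: str | int = "kaiser",
    rotate: str | None = None,
) -> PcaResult:
    """PCA on z-scored concentrations via the correlation-matrix eigenproblem.

    Parameters
    ----------
    retention
        ``"kaiser"`` keeps components with eigenvalue > 1 (at least one);
        an integer keeps exactly that many.
    rotate
        ``"varimax"`` applies varimax rotation to the retained loadings
        (variance contributions are then recomputed from the rotated
        loadings); default is unrotated.

    Loadings are eigenvectors scaled by sqrt(eigenvalue), so squared
    loadings of a component sum to its eigenvalue.  Sign convention: each
    component's largest-magnitude loading is positive.
    """
    conc = samples.concentrations
    n, p = conc.shape
    if n <= p:
        raise ValidationError(
            f"PCA needs more samples ({n}) than elements ({p}); add samples"
        )
    corr = np.corrcoef(conc.to_numpy(dtype=float), rowvar=False)
    if np.isnan(corr).any():
        raise ValidationError("constant column: correlation matrix undefined")
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]

    contribution = 100.0 * eigval / eigval.sum()
    cumulative = np.cumsum(contribution)

    if retention == "kaiser":
        n_retained = max(1, int(np.sum(eigval > 1.0)))
    else:
        n_retained = int(retention)
        if not 1 <= n_retained <= p:
            raise ValidationError(f"retention must be in [1, {p}]")

    loadings = eigvec[:, :n_retained] * np.sqrt(eigval[:n_retained])
    if rotate == "varimax" and n_retained > 1:
        loadings = _varimax(loadings)
        ssq = np.sum(loadings**2, axis=0)
        order2 = np.argsort(ssq)[::-1]
        loadings = loadings[:, order2]
        rotated_contrib = 100.0 * np.sort(ssq)[::-1] / p
        contribution = np.concatenate(
            [rotated_contrib, contribution[n_retained:]]
        )
        cumulative = np.cumsum(contribution)
    elif rotate not in (None, "varimax"):
        raise ValidationError(f"unknown rotation {rotate!r}")

    # Sign convention: dominant loading of each component is positive.
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(n_retained)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip

    loadings_df = pd.DataFrame(
        loadings,
        index=conc.columns,
        columns=[f"PC{i + 1}" for i in range(n_retained)],
    )
    return PcaResult(
        loadings=loadings_df,
        eigenvalues=eigval,
        variance_contribution=contribution,
        cumulative_contribution=cumulative,
        n_retained=n_retained,
    )
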